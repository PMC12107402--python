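# Monthly full-moon reference table, calendar year 2022.
# fullmoon_utc: published astronomical-almanac instants of full moon (UTC);
#   the May and November entries coincide with that year's total lunar
#   eclipses, pinning them independently to within minutes.
# culmination_* columns are SYNTHETIC reference values: computed once with
#   this package's analytic ephemeris at longitude 0 on the full-moon date
#   and frozen here as a regression reference (not an independent oracle).
# columns: month, fullmoon_utc, culmination_utc_lon0, alt_lat0, alt_lat50n, alt_lat50s
1,2022-01-17T23:48,2022-01-17T23:33:00,62.912,65.481,13.762
2,2022-02-16T16:56,2022-02-16T23:33:00,68.041,59.371,22.214
3,2022-03-18T07:18,2022-03-17T23:43:00,81.877,45.848,36.249
4,2022-04-16T18:55,2022-04-15T23:43:00,84.461,35.881,47.929
5,2022-05-16T04:14,2022-05-15T23:43:00,71.242,20.632,59.176
6,2022-06-14T11:52,2022-06-13T23:43:00,64.534,14.170,63.768
7,2022-07-13T18:38,2022-07-13T23:33:00,61.236,12.524,66.039
8,2022-08-12T01:36,2022-08-11T23:53:00,69.218,21.303,59.459
9,2022-09-10T09:59,2022-09-10T23:33:00,74.434,32.551,50.834
10,2022-10-09T20:55,2022-10-09T23:33:00,82.335,44.031,40.063
11,2022-11-08T11:02,2022-11-07T23:43:00,74.366,57.988,24.503
12,2022-12-08T04:08,2022-12-07T23:43:00,64.533,64.006,14.040
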