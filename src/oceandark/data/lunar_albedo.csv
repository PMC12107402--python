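# Synthetic stand-in lunar spectral albedo curve (smooth power law,
# ~0.085 at 490 nm, mild reddening toward long wavelengths).
# columns: wavelength_nm, albedo
350,0.056763
351,0.056958
352,0.057152
353,0.057347
354,0.057542
355,0.057737
356,0.057933
357,0.058128
358,0.058323
359,0.058519
360,0.058715
361,0.058910
362,0.059106
363,0.059302
364,0.059498
365,0.059695
366,0.059891
367,0.060087
368,0.060284
369,0.060480
370,0.060677
371,0.060874
372,0.061071
373,0.061268
374,0.061465
375,0.061663
376,0.061860
377,0.062057
378,0.062255
379,0.062453
380,0.062650
381,0.062848
382,0.063046
383,0.063244
384,0.063443
385,0.063641
386,0.063839
387,0.064038
388,0.064236
389,0.064435
390,0.064634
391,0.064833
392,0.065032
393,0.065231
394,0.065430
395,0.065630
396,0.065829
397,0.066029
398,0.066228
399,0.066428
400,0.066628
401,0.066828
402,0.067028
403,0.067228
404,0.067428
405,0.067628
406,0.067829
407,0.068029
408,0.068230
409,0.068431
410,0.068632
411,0.068833
412,0.069034
413,0.069235
414,0.069436
415,0.069637
416,0.069839
417,0.070040
418,0.070242
419,0.070443
420,0.070645
421,0.070847
422,0.071049
423,0.071251
424,0.071453
425,0.071656
426,0.071858
427,0.072060
428,0.072263
429,0.072466
430,0.072668
431,0.072871
432,0.073074
433,0.073277
434,0.073480
435,0.073684
436,0.073887
437,0.074090
438,0.074294
439,0.074497
440,0.074701
441,0.074905
442,0.075109
443,0.075313
444,0.075517
445,0.075721
446,0.075925
447,0.076129
448,0.076334
449,0.076538
450,0.076743
451,0.076948
452,0.077152
453,0.077357
454,0.077562
455,0.077767
456,0.077972
457,0.078178
458,0.078383
459,0.078588
460,0.078794
461,0.079000
462,0.079205
463,0.079411
464,0.079617
465,0.079823
466,0.080029
467,0.080235
468,0.080441
469,0.080648
470,0.080854
471,0.081060
472,0.081267
473,0.081474
474,0.081680
475,0.081887
476,0.082094
477,0.082301
478,0.082508
479,0.082715
480,0.082923
481,0.083130
482,0.083337
483,0.083545
484,0.083753
485,0.083960
486,0.084168
487,0.084376
488,0.084584
489,0.084792
490,0.085000
491,0.085208
492,0.085416
493,0.085625
494,0.085833
495,0.086042
496,0.086251
497,0.086459
498,0.086668
499,0.086877
500,0.087086
501,0.087295
502,0.087504
503,0.087713
504,0.087923
505,0.088132
506,0.088341
507,0.088551
508,0.088761
509,0.088970
510,0.089180
511,0.089390
512,0.089600
513,0.089810
514,0.090020
515,0.090230
516,0.090441
517,0.090651
518,0.090861
519,0.091072
520,0.091283
521,0.091493
522,0.091704
523,0.091915
524,0.092126
525,0.092337
526,0.092548
527,0.092759
528,0.092970
529,0.093182
530,0.093393
531,0.093605
532,0.093816
533,0.094028
534,0.094240
535,0.094451
536,0.094663
537,0.094875
538,0.095087
539,0.095299
540,0.095512
541,0.095724
542,0.095936
543,0.096149
544,0.096361
545,0.096574
546,0.096787
547,0.096999
548,0.097212
549,0.097425
550,0.097638
551,0.097851
552,0.098064
553,0.098277
554,0.098491
555,0.098704
556,0.098918
557,0.099131
558,0.099345
559,0.099558
560,0.099772
561,0.099986
562,0.100200
563,0.100414
564,0.100628
565,0.100842
566,0.101056
567,0.101271
568,0.101485
569,0.101699
570,0.101914
571,0.102129
572,0.102343
573,0.102558
574,0.102773
575,0.102988
576,0.103203
577,0.103418
578,0.103633
579,0.103848
580,0.104063
581,0.104279
582,0.104494
583,0.104709
584,0.104925
585,0.105141
586,0.105356
587,0.105572
588,0.105788
589,0.106004
590,0.106220
591,0.106436
592,0.106652
593,0.106868
594,0.107085
595,0.107301
596,0.107517
597,0.107734
598,0.107951
599,0.108167
600,0.108384
601,0.108601
602,0.108818
603,0.109035
604,0.109252
605,0.109469
606,0.109686
607,0.109903
608,0.110120
609,0.110338
610,0.110555
611,0.110773
612,0.110990
613,0.111208
614,0.111426
615,0.111644
616,0.111861
617,0.112079
618,0.112297
619,0.112516
620,0.112734
621,0.112952
622,0.113170
623,0.113389
624,0.113607
625,0.113826
626,0.114044
627,0.114263
628,0.114481
629,0.114700
630,0.114919
631,0.115138
632,0.115357
633,0.115576
634,0.115795
635,0.116014
636,0.116234
637,0.116453
638,0.116672
639,0.116892
640,0.117112
641,0.117331
642,0.117551
643,0.117771
644,0.117990
645,0.118210
646,0.118430
647,0.118650
648,0.118870
649,0.119091
650,0.119311
651,0.119531
652,0.119751
653,0.119972
654,0.120192
655,0.120413
656,0.120634
657,0.120854
658,0.121075
659,0.121296
660,0.121517
661,0.121738
662,0.121959
663,0.122180
664,0.122401
665,0.122622
666,0.122844
667,0.123065
668,0.123286
669,0.123508
670,0.123730
671,0.123951
672,0.124173
673,0.124395
674,0.124616
675,0.124838
676,0.125060
677,0.125282
678,0.125504
679,0.125727
680,0.125949
681,0.126171
682,0.126394
683,0.126616
684,0.126838
685,0.127061
686,0.127284
687,0.127506
688,0.127729
689,0.127952
690,0.128175
691,0.128398
692,0.128621
693,0.128844
694,0.129067
695,0.129290
696,0.129513
697,0.129737
698,0.129960
699,0.130184
700,0.130407
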