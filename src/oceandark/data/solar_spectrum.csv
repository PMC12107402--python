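# Synthetic stand-in for a tabulated extraterrestrial solar spectrum
# (blackbody at T_eff=5772 K scaled by the solid angle of the Sun at 1 AU;
#  total irradiance ~1361 W m^-2). Smooth approximation for band work near 490 nm.
# columns: wavelength_nm, irradiance_W_m2_nm
350,1.244676e+00
351,1.252218e+00
352,1.259713e+00
353,1.267159e+00
354,1.274556e+00
355,1.281904e+00
356,1.289202e+00
357,1.296449e+00
358,1.303646e+00
359,1.310792e+00
360,1.317887e+00
361,1.324929e+00
362,1.331920e+00
363,1.338859e+00
364,1.345744e+00
365,1.352577e+00
366,1.359357e+00
367,1.366082e+00
368,1.372754e+00
369,1.379372e+00
370,1.385936e+00
371,1.392445e+00
372,1.398899e+00
373,1.405298e+00
374,1.411642e+00
375,1.417931e+00
376,1.424164e+00
377,1.430341e+00
378,1.436462e+00
379,1.442527e+00
380,1.448537e+00
381,1.454489e+00
382,1.460386e+00
383,1.466225e+00
384,1.472008e+00
385,1.477735e+00
386,1.483404e+00
387,1.489017e+00
388,1.494572e+00
389,1.500071e+00
390,1.505513e+00
391,1.510897e+00
392,1.516224e+00
393,1.521494e+00
394,1.526707e+00
395,1.531863e+00
396,1.536962e+00
397,1.542003e+00
398,1.546988e+00
399,1.551915e+00
400,1.556785e+00
401,1.561598e+00
402,1.566354e+00
403,1.571053e+00
404,1.575695e+00
405,1.580280e+00
406,1.584809e+00
407,1.589281e+00
408,1.593696e+00
409,1.598055e+00
410,1.602357e+00
411,1.606604e+00
412,1.610793e+00
413,1.614927e+00
414,1.619005e+00
415,1.623027e+00
416,1.626994e+00
417,1.630904e+00
418,1.634760e+00
419,1.638560e+00
420,1.642305e+00
421,1.645995e+00
422,1.649630e+00
423,1.653211e+00
424,1.656737e+00
425,1.660209e+00
426,1.663626e+00
427,1.666990e+00
428,1.670300e+00
429,1.673557e+00
430,1.676760e+00
431,1.679910e+00
432,1.683007e+00
433,1.686051e+00
434,1.689042e+00
435,1.691982e+00
436,1.694869e+00
437,1.697704e+00
438,1.700488e+00
439,1.703220e+00
440,1.705901e+00
441,1.708531e+00
442,1.711110e+00
443,1.713638e+00
444,1.716116e+00
445,1.718545e+00
446,1.720923e+00
447,1.723252e+00
448,1.725531e+00
449,1.727762e+00
450,1.729943e+00
451,1.732076e+00
452,1.734161e+00
453,1.736197e+00
454,1.738186e+00
455,1.740127e+00
456,1.742021e+00
457,1.743868e+00
458,1.745669e+00
459,1.747422e+00
460,1.749130e+00
461,1.750791e+00
462,1.752407e+00
463,1.753978e+00
464,1.755503e+00
465,1.756984e+00
466,1.758420e+00
467,1.759811e+00
468,1.761159e+00
469,1.762463e+00
470,1.763723e+00
471,1.764940e+00
472,1.766114e+00
473,1.767246e+00
474,1.768335e+00
475,1.769382e+00
476,1.770388e+00
477,1.771352e+00
478,1.772274e+00
479,1.773156e+00
480,1.773997e+00
481,1.774798e+00
482,1.775558e+00
483,1.776279e+00
484,1.776961e+00
485,1.777603e+00
486,1.778206e+00
487,1.778770e+00
488,1.779296e+00
489,1.779784e+00
490,1.780234e+00
491,1.780647e+00
492,1.781022e+00
493,1.781361e+00
494,1.781662e+00
495,1.781928e+00
496,1.782157e+00
497,1.782350e+00
498,1.782508e+00
499,1.782631e+00
500,1.782718e+00
501,1.782771e+00
502,1.782790e+00
503,1.782774e+00
504,1.782724e+00
505,1.782641e+00
506,1.782525e+00
507,1.782375e+00
508,1.782193e+00
509,1.781979e+00
510,1.781732e+00
511,1.781453e+00
512,1.781142e+00
513,1.780800e+00
514,1.780427e+00
515,1.780024e+00
516,1.779589e+00
517,1.779125e+00
518,1.778630e+00
519,1.778105e+00
520,1.777551e+00
521,1.776968e+00
522,1.776356e+00
523,1.775715e+00
524,1.775046e+00
525,1.774348e+00
526,1.773623e+00
527,1.772870e+00
528,1.772090e+00
529,1.771282e+00
530,1.770448e+00
531,1.769587e+00
532,1.768699e+00
533,1.767786e+00
534,1.766846e+00
535,1.765881e+00
536,1.764891e+00
537,1.763875e+00
538,1.762835e+00
539,1.761770e+00
540,1.760681e+00
541,1.759567e+00
542,1.758430e+00
543,1.757269e+00
544,1.756085e+00
545,1.754877e+00
546,1.753647e+00
547,1.752394e+00
548,1.751118e+00
549,1.749820e+00
550,1.748501e+00
551,1.747159e+00
552,1.745796e+00
553,1.744412e+00
554,1.743007e+00
555,1.741580e+00
556,1.740134e+00
557,1.738666e+00
558,1.737179e+00
559,1.735672e+00
560,1.734145e+00
561,1.732599e+00
562,1.731033e+00
563,1.729448e+00
564,1.727845e+00
565,1.726222e+00
566,1.724582e+00
567,1.722923e+00
568,1.721246e+00
569,1.719551e+00
570,1.717839e+00
571,1.716110e+00
572,1.714363e+00
573,1.712599e+00
574,1.710819e+00
575,1.709022e+00
576,1.707209e+00
577,1.705379e+00
578,1.703534e+00
579,1.701673e+00
580,1.699796e+00
581,1.697904e+00
582,1.695996e+00
583,1.694074e+00
584,1.692137e+00
585,1.690185e+00
586,1.688219e+00
587,1.686239e+00
588,1.684244e+00
589,1.682236e+00
590,1.680214e+00
591,1.678178e+00
592,1.676130e+00
593,1.674068e+00
594,1.671993e+00
595,1.669905e+00
596,1.667804e+00
597,1.665692e+00
598,1.663566e+00
599,1.661429e+00
600,1.659280e+00
601,1.657119e+00
602,1.654947e+00
603,1.652763e+00
604,1.650567e+00
605,1.648361e+00
606,1.646144e+00
607,1.643915e+00
608,1.641677e+00
609,1.639427e+00
610,1.637168e+00
611,1.634898e+00
612,1.632618e+00
613,1.630329e+00
614,1.628029e+00
615,1.625721e+00
616,1.623402e+00
617,1.621075e+00
618,1.618738e+00
619,1.616392e+00
620,1.614038e+00
621,1.611675e+00
622,1.609303e+00
623,1.606923e+00
624,1.604535e+00
625,1.602139e+00
626,1.599734e+00
627,1.597322e+00
628,1.594902e+00
629,1.592475e+00
630,1.590040e+00
631,1.587598e+00
632,1.585148e+00
633,1.582692e+00
634,1.580228e+00
635,1.577758e+00
636,1.575282e+00
637,1.572798e+00
638,1.570309e+00
639,1.567813e+00
640,1.565310e+00
641,1.562802e+00
642,1.560288e+00
643,1.557768e+00
644,1.555243e+00
645,1.552711e+00
646,1.550175e+00
647,1.547633e+00
648,1.545086e+00
649,1.542533e+00
650,1.539976e+00
651,1.537414e+00
652,1.534847e+00
653,1.532275e+00
654,1.529699e+00
655,1.527119e+00
656,1.524534e+00
657,1.521944e+00
658,1.519351e+00
659,1.516754e+00
660,1.514153e+00
661,1.511547e+00
662,1.508939e+00
663,1.506326e+00
664,1.503710e+00
665,1.501091e+00
666,1.498468e+00
667,1.495842e+00
668,1.493213e+00
669,1.490581e+00
670,1.487945e+00
671,1.485307e+00
672,1.482667e+00
673,1.480023e+00
674,1.477377e+00
675,1.474729e+00
676,1.472078e+00
677,1.469424e+00
678,1.466769e+00
679,1.464111e+00
680,1.461451e+00
681,1.458790e+00
682,1.456126e+00
683,1.453460e+00
684,1.450793e+00
685,1.448124e+00
686,1.445454e+00
687,1.442782e+00
688,1.440108e+00
689,1.437434e+00
690,1.434758e+00
691,1.432081e+00
692,1.429402e+00
693,1.426723e+00
694,1.424042e+00
695,1.421361e+00
696,1.418679e+00
697,1.415996e+00
698,1.413313e+00
699,1.410629e+00
700,1.407944e+00
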