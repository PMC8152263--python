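wavelength_nm,a_water_m-1
400,0.00663
405,0.00530
410,0.00473
415,0.00444
420,0.00454
425,0.00478
430,0.00495
435,0.00530
440,0.00635
445,0.00751
450,0.00922
455,0.00962
460,0.00979
465,0.01011
470,0.0106
475,0.0114
480,0.0127
485,0.0136
490,0.0150
495,0.0173
500,0.0204
505,0.0256
510,0.0325
515,0.0396
520,0.0409
525,0.0417
530,0.0434
535,0.0452
540,0.0474
545,0.0511
550,0.0565
555,0.0596
560,0.0619
565,0.0642
570,0.0695
575,0.0772
580,0.0896
585,0.1100
590,0.1351
595,0.1672
600,0.2224
605,0.2577
610,0.2644
615,0.2678
620,0.2755
625,0.2834
630,0.2916
635,0.3012
640,0.3108
645,0.325
650,0.340
655,0.371
660,0.410
665,0.429
670,0.439
675,0.448
680,0.465
685,0.486
690,0.516
695,0.559
700,0.624
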