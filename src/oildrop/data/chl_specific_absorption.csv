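wavelength_nm,A_m-1,E
400,0.04122,0.65
410,0.04968,0.65
420,0.05478,0.65
430,0.05838,0.65
440,0.06000,0.65
450,0.05664,0.65
460,0.05502,0.65
470,0.05220,0.65
480,0.04788,0.65
490,0.04500,0.65
500,0.04008,0.65
510,0.03708,0.65
520,0.03168,0.65
530,0.02844,0.65
540,0.02496,0.65
550,0.02142,0.65
560,0.01764,0.65
570,0.01656,0.65
580,0.01746,0.65
590,0.01692,0.65
600,0.01416,0.65
610,0.01512,0.65
620,0.01656,0.65
630,0.01902,0.65
640,0.02004,0.65
650,0.02136,0.65
660,0.02646,0.65
670,0.03570,0.65
680,0.03012,0.65
690,0.01974,0.65
700,0.01290,0.65
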