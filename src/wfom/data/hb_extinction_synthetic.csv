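# Synthetic HbO/HbR molar extinction table (decadic, cm^-1 M^-1).
# Generated by scripts/make_extinction_fixture.py; see its docstring.
wavelength_nm,xi_hbo,xi_hbr
450,62816.0,70000.0
451,60366.9,66992.1
452,58075.8,64178.9
453,55928.7,61554.9
454,53912.9,59114.2
455,52017.0,56851.0
456,50230.4,54759.4
457,48543.6,52833.8
458,46948.2,51068.7
459,45436.0,49459.0
460,44000.0,48000.0
461,42636.3,46668.5
462,41342.1,45436.1
463,40112.9,44291.7
464,38944.3,43225.3
465,37832.3,42227.7
466,36773.2,41290.5
467,35763.5,40406.0
468,34800.0,39567.0
469,33879.8,38767.0
470,33000.0,38000.0
471,32159.6,37263.6
472,31357.2,36559.0
473,30590.0,35885.6
474,29855.3,35242.8
475,29150.5,34630.2
476,28473.3,34047.0
477,27821.6,33492.9
478,27193.4,32967.3
479,26586.8,32469.8
480,26000.0,32000.0
481,25401.0,31576.4
482,24779.1,31204.1
483,24163.0,30863.3
484,23578.5,30535.1
485,23049.2,30201.4
486,22596.4,29845.1
487,22240.1,29449.8
488,22000.0,29000.0
489,21828.9,28411.6
490,21667.4,27649.4
491,21516.5,26771.4
492,21377.1,25831.6
493,21250.4,24878.8
494,21137.2,23955.7
495,21038.6,23098.7
496,20955.6,22339.3
497,20889.2,21704.9
498,20840.4,21220.3
499,20810.3,20909.9
500,20800.0,20800.0
501,20850.8,20815.2
502,20994.4,20859.4
503,21218.6,20930.2
504,21511.4,21025.7
505,21861.0,21143.7
506,22255.1,21282.2
507,22680.6,21439.2
508,23123.5,21612.5
509,23568.8,21800.2
510,24000.0,22000.0
511,24438.7,22281.4
512,24917.0,22704.1
513,25433.8,23251.8
514,25987.7,23908.2
515,26577.3,24656.3
516,27201.1,25476.9
517,27857.4,26348.4
518,28544.2,27245.8
519,29259.2,28140.4
520,30000.0,29000.0
521,30790.1,29877.5
522,31650.5,30839.4
523,32574.0,31869.3
524,33552.4,32948.6
525,34576.5,34055.7
526,35635.6,35165.9
527,36717.5,36251.4
528,37808.8,37281.1
529,38893.9,38221.3
530,39956.0,39036.0
531,41074.7,39748.9
532,42323.6,40412.0
533,43673.1,41031.7
534,45089.6,41615.1
535,46534.7,42169.6
536,47965.0,42703.7
537,49331.6,43225.9
538,50581.1,43745.6
539,51655.8,44272.5
540,52496.2,44816.6
541,53042.1,45388.7
542,53236.0,46000.0
543,52954.0,46662.7
544,52218.7,47364.2
545,51198.2,48077.8
546,50055.8,48775.2
547,48943.3,49426.4
548,48000.0,50000.0
549,47214.3,50546.0
550,46474.2,51117.6
551,45760.6,51686.3
552,45055.5,52222.4
553,44342.1,52694.9
554,43604.6,53072.1
555,42828.4,53321.8
556,42000.0,53412.0
557,40937.8,53304.6
558,39627.9,53014.7
559,38292.8,52591.2
560,37129.0,52082.8
561,36310.2,51537.1
562,36000.0,51000.0
563,36198.0,50444.8
564,36749.1,49819.8
565,37593.7,49132.3
566,38673.7,48389.3
567,39927.7,47597.7
568,41287.3,46764.6
569,42674.4,45896.5
570,44000.0,45000.0
571,45520.9,43970.2
572,47448.5,42763.0
573,49598.9,41471.1
574,51754.6,40178.6
575,53658.5,38960.0
576,55021.0,37880.8
577,55540.0,37000.0
578,54597.1,36304.7
579,52088.4,35715.8
580,48544.9,35191.9
581,44483.6,34693.9
582,40339.6,34185.2
583,36438.6,33631.3
584,33000.0,33000.0
585,29703.4,32302.6
586,26304.9,31562.9
587,23019.3,30770.4
588,19992.2,29916.7
589,17307.4,28994.8
590,15000.0,28000.0
591,12931.6,26832.5
592,11016.0,25456.8
593,9309.5,23960.9
594,7835.9,22422.2
595,6595.3,20904.8
596,5573.0,19459.2
597,4746.6,18123.0
598,4091.1,16923.2
599,3582.5,15878.0
600,3200.0,15000.0
601,2901.1,14243.0
602,2647.8,13548.7
603,2431.4,12909.5
604,2244.8,12318.6
605,2082.3,11770.0
606,1939.5,11258.5
607,1812.6,10779.6
608,1698.7,10329.2
609,1595.1,9903.7
610,1500.0,9500.0
611,1413.0,9112.9
612,1334.2,8740.8
613,1262.7,8386.1
614,1197.4,8050.5
615,1137.7,7735.5
616,1082.7,7442.2
617,1032.0,7171.4
618,984.9,6923.8
619,941.0,6699.9
620,900.0,6500.0
621,861.5,6318.1
622,825.4,6147.6
623,791.6,5988.1
624,760.0,5839.1
625,730.4,5700.3
626,702.8,5571.4
627,677.0,5452.1
628,653.0,5342.1
629,630.7,5241.0
630,610.0,5148.8
631,590.5,5066.0
632,571.9,4992.1
633,554.2,4925.1
634,537.5,4862.9
635,521.9,4804.0
636,507.3,4746.5
637,493.8,4688.9
638,481.4,4629.5
639,470.2,4567.0
640,460.0,4500.0
641,450.9,4427.8
642,442.8,4351.7
643,435.4,4272.9
644,428.5,4192.9
645,422.1,4112.9
646,415.8,4034.1
647,409.6,3957.4
648,403.3,3883.9
649,396.8,3814.5
650,390.0,3750.0
651,382.6,3689.7
652,374.8,3632.1
653,366.7,3576.8
654,358.6,3523.4
655,350.7,3471.7
656,343.1,3421.3
657,336.1,3371.8
658,329.8,3323.2
659,324.4,3275.0
660,320.0,3227.0
661,316.2,3179.5
662,312.4,3132.8
663,308.7,3086.9
664,305.1,3041.7
665,301.6,2997.3
666,298.2,2953.6
667,294.9,2910.7
668,291.9,2868.4
669,289.0,2826.7
670,286.2,2785.8
671,283.7,2745.4
672,281.4,2705.6
673,279.3,2666.4
674,277.5,2627.8
675,275.9,2589.7
676,274.5,2552.2
677,273.4,2515.1
678,272.6,2478.6
679,272.2,2442.6
680,272.0,2407.0
681,272.1,2371.7
682,272.2,2336.5
683,272.5,2301.5
684,272.9,2266.8
685,273.4,2232.4
686,274.0,2198.4
687,274.7,2164.9
688,275.5,2131.9
689,276.3,2099.5
690,277.3,2067.7
691,278.3,2036.6
692,279.4,2006.3
693,280.5,1976.7
694,281.7,1947.9
695,283.0,1920.0
696,284.3,1892.9
697,285.7,1866.8
698,287.1,1841.5
699,288.5,1817.3
700,290.0,1794.0
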