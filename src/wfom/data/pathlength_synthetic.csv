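# Mean differential pathlength X(lambda), mm, of detected diffuse reflectance.
# Generated by scripts/make_pathlength_fixture.py: Monte Carlo, 200000 photons
# per wavelength, seed 20160360; mu_a from 2 mM blood Hb / 3% blood volume / 75% SO2,
# mu_s = 21 mm^-1 (530 nm) * (lambda/530)^-1.3, g = 0.85, n_rel = 1.37, NA = 0.2.
wavelength_nm,x_mm
450,0.903119
460,1.13541
470,1.39186
480,1.59418
490,1.79497
500,1.96188
510,1.76993
520,1.59349
530,1.33919
540,1.14423
550,1.18814
560,1.31612
570,1.29133
580,1.26942
590,2.23605
600,4.34508
610,6.09434
620,7.89828
630,9.29071
640,10.1307
650,11.1526
660,12.5588
670,13.2278
680,14.2967
690,14.9224
700,15.4429
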