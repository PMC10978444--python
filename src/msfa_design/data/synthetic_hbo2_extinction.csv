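# Synthetic approximation of the oxyhemoglobin (HbO2) molar extinction
# spectrum (arbitrary units proportional to cm^-1/M). Hand-tabulated anchor
# points reproducing the canonical shape: Q-band double peak near 542 and
# 577 nm with the 560 nm trough, green-window minimum near 510 nm, and a
# near-zero red tail with a shallow minimum around 690 nm. Not a published
# measurement table.
wavelength_nm,value
450,63000
460,45000
470,33500
480,27000
490,23500
500,21000
510,20200
520,24500
530,40000
540,53200
544,53500
548,49000
552,42000
556,36500
560,33000
564,33500
568,40000
572,50000
576,54500
580,50000
584,42000
588,27000
592,14000
596,7500
600,3200
610,1200
620,700
630,500
640,420
650,370
660,320
680,290
700,290
720,330
730,390
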