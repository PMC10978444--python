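# Synthetic approximation of the deoxyhemoglobin (Hb) molar extinction
# spectrum (arbitrary units proportional to cm^-1/M). Hand-tabulated anchor
# points reproducing the canonical shape: single Q-band peak near 555 nm,
# steep Soret tail below 500 nm, monotone decline through the red with
# Hb > HbO2 above 600 nm. Not a published measurement table.
wavelength_nm,value
450,103000
460,84000
470,65000
480,50000
490,34000
500,24000
510,21000
520,22500
530,28000
540,40000
548,48000
555,53400
560,52000
565,47000
570,42000
576,35000
584,29000
590,21000
600,14700
610,9000
620,6500
630,5100
640,4400
650,3750
660,3200
670,2800
680,2400
690,2100
700,1800
710,1600
720,1450
730,1300
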