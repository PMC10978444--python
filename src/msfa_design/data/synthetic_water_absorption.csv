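# Synthetic approximation of the pure-water absorption coefficient spectrum
# (arbitrary units proportional to 1/m) over the visible range: very weak
# absorption in the blue-green rising steeply toward 720 nm. Hand-tabulated
# anchors; not a published measurement table.
wavelength_nm,value
450,0.0092
470,0.0106
490,0.0150
500,0.0204
510,0.0325
520,0.0409
530,0.0434
540,0.0474
550,0.0565
560,0.0619
570,0.0695
580,0.0896
590,0.1351
600,0.2224
610,0.2644
620,0.2755
630,0.2916
640,0.3108
650,0.3400
660,0.4100
670,0.4390
680,0.4650
690,0.5160
700,0.6240
710,0.8270
720,1.0420
730,1.2300
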