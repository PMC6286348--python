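construct,subtype,is_wild_type,k05_sugar_mM,k05_sugar_sem,k05_na_mM,k05_na_sem,ki_phlorizin_uM,ki_phlorizin_sem,ki_phloretin_uM,ki_phloretin_sem,ki_dapagliflozin_uM,ki_dapagliflozin_sem,ki_dapa_aglycon_uM,ki_dapa_aglycon_sem,provenance
hSGLT1 wild-type,hSGLT1,True,0.9,0.1,36,1,0.22,0.04,55,12,0.45,0.02,425,50,this study
hSGLT1 F101C,hSGLT1,False,1.1,0.2,9,1,37,12,,,,,,,literature
hSGLT1 D268H,hSGLT1,False,1.2,0.1,17,1.2,0.3,0.1,,,0.035,0.011,,,this study
hSGLT1 T287C,hSGLT1,False,1.4,0.2,6,0.2,0.2,0.1,,,,,,,literature
hSGLT1 Y290C,hSGLT1,False,,,46,5,36,6,,,,,,,literature; sugar K_0.5 reported only as >100 mM
hSGLT1 Y290F,hSGLT1,False,35,10,20,1,1.8,0.4,,,,,,,literature (K_0.5) / this study (K_i)
hSGLT1 S392A/C,hSGLT1,False,,,122,12,4,1,,,,,,,literature; sugar K_0.5 reported only as >100 mM
hSGLT1 S393A/C,hSGLT1,False,4,1,32,3,0.5,0.2,,,,,,,literature
hSGLT1 T395A,hSGLT1,False,34,4,104,50,0.35,0.10,20,7,0.4,0.1,187,80,this study
hSGLT1 Q457C,hSGLT1,False,13,2,34,2,6,1,,,,,,,literature
hSGLT1 F453C,hSGLT1,False,1.8,0.2,21,1,1,0.3,,,,,,,literature
hSGLT2 wild-type,hSGLT2,True,4.4,0.1,22,1,0.03,0.01,27,3,0.004,0.001,110,30,this study
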