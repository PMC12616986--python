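trait,Base,LimitBW,LimitDMI,LimitBoth,ReduceBW,EFF
BWcalv1,0,-20,0,-5,-28,0
Milk,55,46,46,41,28,0
DMI,0,0,-22,-25,0,0
IFC,-45,-34,-32,-29,-34,-50
Lact_Eff,0,0,0,0,10,50
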