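trait,BasAcq,LactAcq,f_prio_GS,LactAll,Milk_HS,DMI_HS,IFC_HS,Milk_MS,DMI_MS,IFC_MS
BasAcq,0.35,0.00,0.00,0.00,0.40,0.57,-0.09,0.12,0.64,-0.02
LactAcq,0.00,0.35,0.00,0.00,0.43,0.58,-0.11,0.09,0.49,0.01
f_prio_GS,0.00,0.00,0.35,0.00,0.05,-0.06,-0.44,0.20,-0.02,-0.49
LactAll,0.00,0.00,0.00,0.35,0.60,0.01,0.54,0.79,-0.02,0.56
Milk_HS,0.45,0.48,0.06,0.71,0.33,0.51,0.31,0.67,0.57,0.33
DMI_HS,0.66,0.66,-0.03,0.05,0.65,0.34,-0.09,0.13,0.79,0.04
IFC_HS,-0.01,-0.02,-0.10,0.09,0.11,-0.05,0.01,0.63,0.00,0.68
Milk_MS,0.15,0.16,0.17,0.91,0.78,0.24,0.03,0.29,0.15,0.52
DMI_MS,0.59,0.44,-0.01,0.02,0.53,0.61,-0.05,0.24,0.26,0.00
IFC_MS,0.02,0.00,-0.13,0.13,0.08,-0.02,0.02,0.24,-0.08,0.01
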