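group,treatment,dl,se,p,call
OSCC,PDT (50 uM) + Nimo (50 ug/ml),0.2348,0.03336,0.0009,Synergistic
OSCC,PDT (100 uM) + Nimo (100 ug/ml),0.2882,0.03500,0.0004,Synergistic
OSCC,PDT (50 uM) + Cetuximab (50 ug/ml),0.3003,0.01797,<0.0001,Synergistic
OSCC,PDT (100 uM) + Cetuximab (100 ug/ml),0.5812,0.03609,<0.0001,Synergistic
HSC-3,PDT (50 uM) + Nimo (50 ug/ml),0.5535,0.01455,<0.0001,Synergistic
HSC-3,PDT (100 uM) + Nimo (100 ug/ml),0.5865,0.2002,0.0428,Synergistic
HSC-3,PDT (50 uM) + Cetuximab (50 ug/ml),0.7602,0.1864,0.0151,Synergistic
HSC-3,PDT (100 uM) + Cetuximab (100 ug/ml),0.4358,0.04715,0.0008,Synergistic
SCC-25,PDT (50 uM) + Nimo (50 ug/ml),0.3321,0.05054,0.0012,Synergistic
SCC-25,PDT (100 uM) + Nimo (100 ug/ml),1.475,0.1226,<0.0001,Synergistic
SCC-25,PDT (50 uM) + Cetuximab (50 ug/ml),1.187,0.3539,0.0202,Synergistic
SCC-25,PDT (100 uM) + Cetuximab (100 ug/ml),1.663,0.03313,<0.0001,Synergistic
HUVEC,PDT (50 uM) + Nimo (50 ug/ml),0.3881,<0.0001,<0.0001,Synergistic
HUVEC,PDT (100 uM) + Nimo (100 ug/ml),0.3240,0.0136,0.0136,Synergistic
HUVEC,PDT (50 uM) + Cetuximab (50 ug/ml),0.5184,<0.0001,<0.0001,Synergistic
HUVEC,PDT (100 uM) + Cetuximab (100 ug/ml),0.4599,<0.0001,<0.0001,Synergistic
in vivo OSCC,PDT (10 mg/kg) + Nimo (10 mg/kg),0.4840,0.1290,0.0199,Synergistic
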