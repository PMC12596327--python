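name,E,S,A,B,V
chloroform,0.425,0.49,0.15,0.02,0.6167
"(E)-1,2-dichloroethene",0.425,0.41,0.09,0.05,0.5922
"(Z)-1,2-dichloroethene",0.436,0.61,0.11,0.05,0.5922
dichloromethane,0.387,0.57,0.1,0.05,0.4943
tetrahydrofuran,0.289,0.52,0.0,0.48,0.6223
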