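name,delta_d,delta_p,delta_h
chloroform,17.8,3.1,5.7
"1,1,2-trichloroethane",18.2,5.3,6.8
cyclopentyl methyl ether,16.7,4.3,4.3
2-methyltetrahydrofuran,16.9,5.0,4.3
dichloromethane,18.2,6.3,6.1
thiophene,18.9,2.4,7.8
tetrahydrofuran,16.8,5.7,8.0
toluene,18.0,1.4,2.0
fluorobenzene,18.1,6.1,2.0
pyrrolidine,17.9,6.5,7.4
methylcyclohexane,16.0,0.0,1.0
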