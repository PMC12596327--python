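model,rank,name,score
hsp,1,"1,1,2-trichloroethane",2.59
hsp,2,cyclopentyl methyl ether,2.87
hsp,3,2-methyltetrahydrofuran,2.97
hsp,4,piperidine,3.03
hsp,5,thiophene,3.12
hsp,6,dichloromethane,3.32
hsp,7,pyrrolidine,3.81
hsp,8,tetrahydrothiophene,3.95
hsp,9,tetrahydrofuran,4.01
hsp,10,toluene,4.09
hsp,11,fluorobenzene,4.8
hsp,12,iso-butyl acetate,4.81
asp,1,"(E)-1,2-dichloroethene",0.039
asp,2,"(Z)-1,2-dichloroethene",0.051
asp,3,"1,1-dichloroethane",0.091
asp,4,fluorobenzene,0.14
asp,5,perfluorobenzene,0.143
asp,6,dichloromethane,0.147
asp,7,tetrahydrofuran,0.165
asp,8,thiophene,0.173
asp,9,propyl formate,0.18
asp,10,iso-butanol,0.181
asp,11,nitroethane,0.182
asp,12,methyl propionate,0.187
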