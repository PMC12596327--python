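lipid_id,method,recovery_pct,sd_pct
LPC 18:1-d7,chloroform,95,2
LPC 18:1-d7,cpme,101,1
LPC 18:1-d7,ibuac,99,1
LPC 18:1-d7,2-methf,95,2
LPC 18:1-d7,dcm,93,10
LPC 18:1-d7,dce,89,9
LPC 18:1-d7,mecyhex,66,0
LPC 18:1-d7,tame,57,3
LPE 18:1-d7,chloroform,95,1
LPE 18:1-d7,cpme,102,3
LPE 18:1-d7,ibuac,95,2
LPE 18:1-d7,2-methf,93,3
LPE 18:1-d7,dcm,92,8
LPE 18:1-d7,dce,87,14
LPE 18:1-d7,mecyhex,56,0
LPE 18:1-d7,tame,55,3
PC 15:0_18:1-d7,chloroform,96,2
PC 15:0_18:1-d7,cpme,99,1
PC 15:0_18:1-d7,ibuac,98,1
PC 15:0_18:1-d7,2-methf,97,3
PC 15:0_18:1-d7,dcm,92,4
PC 15:0_18:1-d7,dce,91,5
PC 15:0_18:1-d7,mecyhex,65,4
PC 15:0_18:1-d7,tame,56,4
PE 15:0_18:1-d7,chloroform,98,3
PE 15:0_18:1-d7,cpme,100,2
PE 15:0_18:1-d7,ibuac,106,13
PE 15:0_18:1-d7,2-methf,97,6
PE 15:0_18:1-d7,dcm,92,5
PE 15:0_18:1-d7,dce,91,9
PE 15:0_18:1-d7,mecyhex,57,0
PE 15:0_18:1-d7,tame,56,3
PI 15:0_18:1-d7,chloroform,99,7
PI 15:0_18:1-d7,cpme,110,13
PI 15:0_18:1-d7,ibuac,93,10
PI 15:0_18:1-d7,2-methf,94,3
PI 15:0_18:1-d7,dcm,91,1
PI 15:0_18:1-d7,dce,83,10
PI 15:0_18:1-d7,mecyhex,71,1
PI 15:0_18:1-d7,tame,61,3
PS 15:0_18:1-d7,chloroform,96,6
PS 15:0_18:1-d7,cpme,96,11
PS 15:0_18:1-d7,ibuac,101,6
PS 15:0_18:1-d7,2-methf,97,2
PS 15:0_18:1-d7,dcm,93,8
PS 15:0_18:1-d7,dce,89,5
PS 15:0_18:1-d7,mecyhex,64,3
PS 15:0_18:1-d7,tame,58,5
PG 15:0_18:1-d7,chloroform,99,5
PG 15:0_18:1-d7,cpme,103,8
PG 15:0_18:1-d7,ibuac,98,2
PG 15:0_18:1-d7,2-methf,95,4
PG 15:0_18:1-d7,dcm,97,11
PG 15:0_18:1-d7,dce,88,5
PG 15:0_18:1-d7,mecyhex,66,4
PG 15:0_18:1-d7,tame,56,7
SM 18:1-d9,chloroform,96,1
SM 18:1-d9,cpme,100,2
SM 18:1-d9,ibuac,97,3
SM 18:1-d9,2-methf,94,1
SM 18:1-d9,dcm,93,5
SM 18:1-d9,dce,93,11
SM 18:1-d9,mecyhex,66,1
SM 18:1-d9,tame,57,3
Cer 18:1-d7,chloroform,97,1
Cer 18:1-d7,cpme,100,4
Cer 18:1-d7,ibuac,98,3
Cer 18:1-d7,2-methf,95,4
Cer 18:1-d7,dcm,97,3
Cer 18:1-d7,dce,94,8
Cer 18:1-d7,mecyhex,74,3
Cer 18:1-d7,tame,64,5
MG 18:1-d7,chloroform,97,0
MG 18:1-d7,cpme,100,3
MG 18:1-d7,ibuac,97,3
MG 18:1-d7,2-methf,92,5
MG 18:1-d7,dcm,95,5
MG 18:1-d7,dce,91,8
MG 18:1-d7,mecyhex,72,4
MG 18:1-d7,tame,66,3
DG 15:0_18:1-d7,chloroform,96,4
DG 15:0_18:1-d7,cpme,99,1
DG 15:0_18:1-d7,ibuac,97,1
DG 15:0_18:1-d7,2-methf,101,5
DG 15:0_18:1-d7,dcm,93,6
DG 15:0_18:1-d7,dce,87,4
DG 15:0_18:1-d7,mecyhex,76,5
DG 15:0_18:1-d7,tame,66,5
TG 15:0_18:1-d7,chloroform,95,6
TG 15:0_18:1-d7,cpme,97,5
TG 15:0_18:1-d7,ibuac,97,4
TG 15:0_18:1-d7,2-methf,97,1
TG 15:0_18:1-d7,dcm,91,6
TG 15:0_18:1-d7,dce,92,3
TG 15:0_18:1-d7,mecyhex,68,4
TG 15:0_18:1-d7,tame,62,2
CE 18:1-d7,chloroform,93,8
CE 18:1-d7,cpme,98,5
CE 18:1-d7,ibuac,99,3
CE 18:1-d7,2-methf,101,20
CE 18:1-d7,dcm,90,9
CE 18:1-d7,dce,92,6
CE 18:1-d7,mecyhex,56,16
CE 18:1-d7,tame,53,7
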