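lipid_id,method,recovery_pct,sd_pct
LPC 18:1-d7,folch_chloroform,98,1
LPC 18:1-d7,folch_cpme,51,5
LPC 18:1-d7,folch_ibuac,41,8
LPC 18:1-d7,mtbe,61,1
LPC 18:1-d7,mmc_chloroform,114,1
LPC 18:1-d7,mmc_cpme,99,6
LPC 18:1-d7,mmc_ibuac,90,1
LPC 18:1-d7,mmc_2methf,88,8
LPE 18:1-d7,folch_chloroform,99,1
LPE 18:1-d7,folch_cpme,58,1
LPE 18:1-d7,folch_ibuac,50,1
LPE 18:1-d7,mtbe,64,1
LPE 18:1-d7,mmc_chloroform,100,1
LPE 18:1-d7,mmc_cpme,92,1
LPE 18:1-d7,mmc_ibuac,90,1
LPE 18:1-d7,mmc_2methf,77,1
PC 15:0_18:1-d7,folch_chloroform,100,1
PC 15:0_18:1-d7,folch_cpme,77,1
PC 15:0_18:1-d7,folch_ibuac,74,3
PC 15:0_18:1-d7,mtbe,82,1
PC 15:0_18:1-d7,mmc_chloroform,111,1
PC 15:0_18:1-d7,mmc_cpme,92,8
PC 15:0_18:1-d7,mmc_ibuac,91,2
PC 15:0_18:1-d7,mmc_2methf,92,5
PE 15:0_18:1-d7,folch_chloroform,102,1
PE 15:0_18:1-d7,folch_cpme,74,3
PE 15:0_18:1-d7,folch_ibuac,75,7
PE 15:0_18:1-d7,mtbe,79,1
PE 15:0_18:1-d7,mmc_chloroform,104,1
PE 15:0_18:1-d7,mmc_cpme,91,1
PE 15:0_18:1-d7,mmc_ibuac,95,4
PE 15:0_18:1-d7,mmc_2methf,82,5
PA 15:0_18:1-d7,folch_chloroform,78,4
PA 15:0_18:1-d7,folch_cpme,83,14
PA 15:0_18:1-d7,folch_ibuac,84,6
PA 15:0_18:1-d7,mtbe,82,2
PA 15:0_18:1-d7,mmc_chloroform,96,8
PA 15:0_18:1-d7,mmc_cpme,105,6
PA 15:0_18:1-d7,mmc_ibuac,99,21
PA 15:0_18:1-d7,mmc_2methf,94,3
PI 15:0_18:1-d7,folch_chloroform,86,1
PI 15:0_18:1-d7,folch_cpme,61,2
PI 15:0_18:1-d7,folch_ibuac,60,8
PI 15:0_18:1-d7,mtbe,75,4
PI 15:0_18:1-d7,mmc_chloroform,99,9
PI 15:0_18:1-d7,mmc_cpme,81,2
PI 15:0_18:1-d7,mmc_ibuac,104,7
PI 15:0_18:1-d7,mmc_2methf,78,2
PS 15:0_18:1-d7,folch_chloroform,83,2
PS 15:0_18:1-d7,folch_cpme,86,14
PS 15:0_18:1-d7,folch_ibuac,76,5
PS 15:0_18:1-d7,mtbe,81,2
PS 15:0_18:1-d7,mmc_chloroform,85,6
PS 15:0_18:1-d7,mmc_cpme,85,1
PS 15:0_18:1-d7,mmc_ibuac,78,1
PS 15:0_18:1-d7,mmc_2methf,62,1
PG 15:0_18:1-d7,folch_chloroform,99,1
PG 15:0_18:1-d7,folch_cpme,71,3
PG 15:0_18:1-d7,folch_ibuac,68,4
PG 15:0_18:1-d7,mtbe,78,1
PG 15:0_18:1-d7,mmc_chloroform,108,1
PG 15:0_18:1-d7,mmc_cpme,91,2
PG 15:0_18:1-d7,mmc_ibuac,89,1
PG 15:0_18:1-d7,mmc_2methf,89,2
SM 18:1-d9,folch_chloroform,97,1
SM 18:1-d9,folch_cpme,73,1
SM 18:1-d9,folch_ibuac,68,1
SM 18:1-d9,mtbe,79,1
SM 18:1-d9,mmc_chloroform,108,1
SM 18:1-d9,mmc_cpme,95,1
SM 18:1-d9,mmc_ibuac,89,1
SM 18:1-d9,mmc_2methf,91,1
Cholesterol-d7,folch_chloroform,85,2
Cholesterol-d7,folch_cpme,105,1
Cholesterol-d7,folch_ibuac,108,1
Cholesterol-d7,mtbe,95,12
Cholesterol-d7,mmc_chloroform,84,11
Cholesterol-d7,mmc_cpme,82,1
Cholesterol-d7,mmc_ibuac,94,1
Cholesterol-d7,mmc_2methf,92,1
MG 18:1-d7,folch_chloroform,87,2
MG 18:1-d7,folch_cpme,73,1
MG 18:1-d7,folch_ibuac,73,1
MG 18:1-d7,mtbe,77,3
MG 18:1-d7,mmc_chloroform,102,2
MG 18:1-d7,mmc_cpme,103,1
MG 18:1-d7,mmc_ibuac,82,1
MG 18:1-d7,mmc_2methf,90,1
DG 15:0_18:1-d7,folch_chloroform,93,1
DG 15:0_18:1-d7,folch_cpme,81,8
DG 15:0_18:1-d7,folch_ibuac,84,10
DG 15:0_18:1-d7,mtbe,82,3
DG 15:0_18:1-d7,mmc_chloroform,113,2
DG 15:0_18:1-d7,mmc_cpme,95,4
DG 15:0_18:1-d7,mmc_ibuac,89,5
DG 15:0_18:1-d7,mmc_2methf,88,5
TG 15:0_18:1-d7,folch_chloroform,99,2
TG 15:0_18:1-d7,folch_cpme,89,7
TG 15:0_18:1-d7,folch_ibuac,94,11
TG 15:0_18:1-d7,mtbe,97,3
TG 15:0_18:1-d7,mmc_chloroform,111,1
TG 15:0_18:1-d7,mmc_cpme,101,2
TG 15:0_18:1-d7,mmc_ibuac,94,3
TG 15:0_18:1-d7,mmc_2methf,96,3
CE 18:1-d7,folch_chloroform,102,4
CE 18:1-d7,folch_cpme,86,7
CE 18:1-d7,folch_ibuac,83,8
CE 18:1-d7,mtbe,78,4
CE 18:1-d7,mmc_chloroform,106,4
CE 18:1-d7,mmc_cpme,102,8
CE 18:1-d7,mmc_ibuac,94,6
CE 18:1-d7,mmc_2methf,90,6
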