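name,smiles,mw,logp,rb,ps,hbd,hba,ar,mc_printed,msc_printed
Acetylsalicylic acid,CC(=O)Oc1ccccc1C(=O)O,180.16,1.24,2,63.60,1,3,1,30,5
Alpha-tocopherol acetate,CC(=O)Oc1c(C)c(C)c2c(c1C)CCC(C)(CCCC(C)CCCC(C)CCCC(C)C)O2,472.74,10.42,13,35.53,0,3,1,53,9
4-Aminopyridine,Nc1ccncc1,94.12,-0.07,1,38.91,1,2,1,24,4
"3,4-Diaminopyridine",Nc1ccncc1N,109.13,-0.9,0,64.93,1,2,1,25,5
Amiodarone Hydrochloride,CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1.Cl,681.78,7.64,11,42.68,1,4,3,52,9
Amoxicillin trihydrate,CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O.O.O.O,365.41,-2.31,4,132.96,4,6,1,28,8
Atenolol,CC(C)NCC(O)COc1ccc(CC(N)=O)cc1,266.34,0.43,6,84.58,2,5,1,30,7
Captopril,CC(CS)C(=O)N1CCCC1C(=O)O,217.29,0.28,3,95.00,2,4,0,29,6
Carbidopa,CC(Cc1ccc(O)c(O)c1)(NN)C(=O)O,244.24,-1.21,4,115.81,5,5,1,27,7
Cholecalciferol,CC(C)CCCC(C)C1CCC2C1(C)CCCC2=CC=C1CC(O)CCC1=C,384.64,7.13,6,20.53,1,1,0,45,6
Cholic acid,CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C,408.57,2.48,4,97.99,3,5,0,37,7
Clonidine hydrochloride,Clc1cccc(Cl)c1NC1=NCCN1.Cl,266.56,2.49,1,36.42,2,3,1,33,5
Cyclophosphamide,O=P1(N(CCCl)CCCl)NCCCO1,261.09,0.10,5,41.57,1,2,0,29,5
Erythromycin,CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)C(=O)C(C)C(O)C1(C)O,733.94,2.60,7,193.91,5,14,0,46,11
Fludrocortisone acetate,CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3(F)C(O)CC12C,422.49,1.76,3,110.90,2,6,0,37,7
Hydrocortisone,OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C,362.47,1.61,0,94.00,3,5,1,35,6
Melatonin,CC(=O)NCCc1c[nH]c2ccc(OC)cc12,232.28,1.15,4,54.12,2,4,2,31,6
Menadione,CC1=CC(=O)c2ccccc2C1=O,172.18,1.89,0,34.14,0,2,1,30,4
Midazolam Hydrochloride,Cc1ncc2CN=C(c3ccccc3F)c3cc(Cl)ccc3-n12.Cl,362.20,3.97,1,30.18,0,3,3,38,6
Naltrexone,O=C1CCC2(O)C3Cc4ccc(O)c5c4C2(CCN3CC2CC2)C1O5,341.42,1.36,2,70.00,2,5,1,33,5
Nifedipine,COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-],346.34,2.56,4,107.00,1,6,1,37,7
Retinyl acetate,CC(=O)OCC=C(C)C=CC=C(C)C=CC1=C(C)CCCC1(C)C,328.50,5.14,6,26.30,0,2,0,40,6
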