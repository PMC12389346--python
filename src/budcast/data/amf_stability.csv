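api_name,main_excipient,other_excipient,packaging,dose_mg,content_pct,temperature_c,bud_days
Acetylsalicylic acid,Lactose,-,ND,4,4,25,365
Acetylsalicylic acid,Lactose,-,ND,19,4,25,365
Acetylsalicylic acid,Lactose,-,ND,56,4,25,365
Acetylsalicylic acid,Lactose,-,ND,76,4,25,365
Alpha-tocopherol acetate,Lactose,-,G,100,56,8,60
Alpha-tocopherol acetate,Lactose,-,G,100,56,25,60
4-Aminopyridine,Lactose,Silica,Pl,5,2,25,180
4-Aminopyridine,Lactose,Silica,Pl,5,2,40,30
"3,4-Diaminopyridine",Lactose,Silica,Pl,5,2,4,180
"3,4-Diaminopyridine",Lactose,Silica,Pl,5,2,25,180
Amiodarone Hydrochloride,Cellulose,-,ND,5,2,25,30
Amiodarone Hydrochloride,Cellulose,-,ND,20,10,25,30
Amiodarone Hydrochloride,Cellulose,-,ND,50,25,25,30
Amiodarone Hydrochloride,Mannitol,-,G,10,4,25,365
Amiodarone Hydrochloride,Mannitol,-,G,60,25,25,365
Amiodarone Hydrochloride,Mannitol,-,G,100,50,25,365
Amoxicillin trihydrate,-,-,Pl,125,100,25,90
Amoxicillin trihydrate,-,-,Pl,250,100,25,56
Amoxicillin trihydrate,-,-,Pl,250,100,40,56
Amoxicillin trihydrate,-,-,Pl,500,100,25,90
Atenolol,Cellulose,-,Pl,25,50,30,120
Captopril,Lactose,-,P,2,2,25,84
Carbidopa,Cellulose,-,ND,200,30,25,336
Cholecalciferol,Lactose,-,G,0.025,0.008,8,60
Cholecalciferol,Lactose,-,G,0.025,0.008,25,60
Cholic acid,Silica,Lactose,Pl,25,95,25,365
Cholic acid,Silica,-,Pl,250,97,25,365
Cholic acid,Silica,Lactose,Pl,25,100,40,180
Cholic acid,Silica,-,Pl,250,100,40,180
Clonidine hydrochloride,Cellulose,-,ND,0.02,1,25,365
Cyclophosphamide,Lactose,-,ND,10,-,4,70
Cyclophosphamide,Lactose,-,ND,25,-,4,70
Erythromycin,Cellulose,-,ND,20,46,25,365
Fludrocortisone acetate,Lactose,-,ND,0.01,-,25,180
Fludrocortisone acetate,Cellulose,-,ND,0.01,-,25,180
Fludrocortisone acetate,Sucrose,-,ND,0.01,-,25,180
Hydrocortisone,Lactose,-,P,20,0.4,25,12
Melatonin,Lactose,HPMC,G,3,0.7,25,90
Melatonin,Lactose,HPMC,G,3,0.7,40,90
Melatonin,Cellulose,-,ND,0.5,0.65,25,547
Melatonin,Cellulose,-,ND,2,2.6,25,547
Melatonin,Cellulose,-,ND,6,8.4,25,547
Melatonin,Lactose,-,P,18,0.7,25,90
Melatonin,Lactose,-,P,18,0.7,40,90
Melatonin,Lactose,-,P,18,2,-20,168
Menadione,Lactose,-,G,1,0.5,8,60
Menadione,Lactose,-,G,1,0.5,25,60
Midazolam Hydrochloride,Cellulose,-,ND,1,1,25,365
Naltrexone,Cellulose,-,G,1.5,10,25,360
Nifedipine,Lactose,-,P,1,0.2,6,365
Nifedipine,Lactose,-,P,1,0.2,22,365
Retinyl acetate,Lactose,-,G,5.5,1,8,60
Retinyl acetate,Lactose,-,G,5.5,1,25,60
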