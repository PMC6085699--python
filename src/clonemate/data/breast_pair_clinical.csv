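patient_id,laterality,interval_days,histology_1,er_1,her2_1,subtype_1,histology_2,er_2,her2_2,subtype_2
BM1,bilateral,346,Invasive carcinoma NST,pos,neg,ND,ND,pos,neg,ND
BM2,bilateral,1694,Invasive carcinoma NST,pos,neg,Luminal B,Invasive lobular carcinoma,pos,neg,ND
BM3,bilateral,1652,ND,pos,neg,ND,Invasive carcinoma NST,pos,neg,ND
BM4,bilateral,581,Invasive carcinoma NST,neg,neg,Basal-like,Invasive carcinoma NST,neg,neg,ND
BM5,bilateral,1954,Invasive carcinoma NST,pos,neg,ND,Invasive lobular carcinoma,pos,neg,ND
BM6,bilateral,1417,Invasive lobular carcinoma,pos,neg,ND,Invasive carcinoma NST,neg,neg,HER2/ER-
BM7,bilateral,456,Invasive carcinoma NST,pos,pos,ND,Invasive carcinoma NST,neg,pos,ND
BM8,bilateral,1152,Invasive lobular carcinoma,pos,neg,ND,Invasive lobular carcinoma,pos,neg,ND
BM9,bilateral,972,Invasive carcinoma NST,neg,neg,ND,Invasive carcinoma NST,neg,neg,ND
BS1,bilateral,0,Invasive carcinoma NST,pos,neg,ND,Invasive carcinoma NST,pos,neg,Luminal B
BS2,bilateral,0,Invasive lobular carcinoma,pos,neg,ND,Invasive carcinoma NST,pos,neg,Luminal B
BS3,bilateral,14,Invasive carcinoma NST,pos,neg,ND,Invasive carcinoma NST,pos,neg,ND
BS4,bilateral,0,ND,pos,neg,ND,ND,pos,neg,ND
BS5,bilateral,6,Invasive carcinoma NST,pos,neg,ND,Invasive carcinoma NST,ND,neg,ND
BS6,bilateral,0,ND,neg,neg,ND,ND,neg,neg,ND
BS7,bilateral,0,Invasive carcinoma NOS,pos,neg,Luminal B,Invasive lobular carcinoma,neg,neg,ND
BS8,bilateral,0,Invasive carcinoma NST,pos,neg,ND,Invasive carcinoma NST,pos,neg,ND
IM1,ipsilateral,1855,ND,pos,neg,ND,ND,pos,neg,Luminal B
IM2,ipsilateral,448,ND,neg,neg,ND,ND,neg,neg,ND
IM3,ipsilateral,1944,Invasive carcinoma NST,pos,pos,Luminal B,ND,pos,pos,Luminal B
IM4,ipsilateral,567,Invasive carcinoma NST,pos,neg,Luminal B,ND,pos,neg,HER2/ER-
IM5,ipsilateral,712,Invasive carcinoma NST,neg,neg,Basal-like,ND,neg,neg,ND
IM6,ipsilateral,664,ND,pos,neg,ND,ND,pos,neg,ND
IM7,ipsilateral,2454,ND,pos,neg,ND,ND,pos,neg,ND
IM8,ipsilateral,563,Invasive carcinoma NST,pos,neg,ND,Invasive lobular carcinoma,pos,neg,Luminal B
IM9,ipsilateral,2142,Invasive carcinoma NOS,ND,neg,Luminal B,Invasive carcinoma NOS,pos,neg,Luminal B
IS1,ipsilateral,0,Invasive carcinoma NST,neg,neg,Basal-like,Invasive carcinoma NST,neg,pos,Luminal B
IS2,ipsilateral,0,Invasive carcinoma NST,pos,neg,ND,ND,pos,neg,Luminal B
IS3,ipsilateral,0,ND,neg,neg,Basal-like,ND,neg,pos,Basal-like
IS4,ipsilateral,50,ND,neg,neg,ND,ND,pos,neg,Luminal B
IS5,ipsilateral,0,Invasive carcinoma NST,pos,neg,Luminal B,Invasive carcinoma NST,pos,neg,Luminal B
IS6,ipsilateral,0,Invasive carcinoma NST,pos,neg,ND,ND,pos,neg,ND
IS7,ipsilateral,0,Invasive carcinoma NOS,pos,neg,ND,ND,pos,neg,ND
IS8,ipsilateral,0,Invasive carcinoma NST,pos,neg,Luminal B,ND,pos,neg,ND
IS9,ipsilateral,0,ND,neg,pos,Basal-like,ND,neg,neg,ND
IS10,ipsilateral,0,Invasive carcinoma NST,pos,neg,Luminal B,ND,pos,neg,Luminal B
IS11,ipsilateral,0,Invasive carcinoma NOS,neg,pos,HER2/ER-,ND,neg,pos,HER2/ER-
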