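range_start,range_end,chapter,label
A00,B99,I,Certain infectious and parasitic diseases
C00,D48,II,Neoplasms
D50,D89,III,Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism
E00,E90,IV,"Endocrine, nutritional and metabolic diseases"
F00,F99,V,Mental and behavioural disorders
G00,G99,VI,Diseases of the nervous system
H00,H59,VII,Diseases of the eye and adnexa
H60,H95,VIII,Diseases of the ear and mastoid process
I00,I99,IX,Diseases of the circulatory system
J00,J99,X,Diseases of the respiratory system
K00,K93,XI,Diseases of the digestive system
L00,L99,XII,Diseases of the skin and subcutaneous tissue
M00,M99,XIII,Diseases of the musculoskeletal system and connective tissue
N00,N99,XIV,Diseases of the genitourinary system
O00,O99,XV,"Pregnancy, childbirth and the puerperium"
P00,P96,XVI,Certain conditions originating in the perinatal period
Q00,Q99,XVII,"Congenital malformations, deformations and chromosomal abnormalities"
R00,R99,XVIII,"Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified"
S00,T98,XIX,"Injury, poisoning and certain other consequences of external causes"
U00,U99,XXII,Codes for special purposes
V01,Y98,XX,External causes of morbidity and mortality
Z00,Z99,XXI,Factors influencing health status and contact with health services
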