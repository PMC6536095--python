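dmu_id,name,region,is_region,ei_mean,se,ci_low,ci_high
N,North,North,1,0.7837,0.0352,0.7147,0.8527
TO,Tocantins,North,0,0.6788,0.0281,0.6237,0.7338
AC,Acre,North,0,0.7411,0.0407,0.6613,0.821
AM,Amazonas,North,0,0.7512,0.0418,0.6692,0.8332
PA,Pará,North,0,0.753,0.0326,0.6892,0.8169
AP,Amapá,North,0,0.7587,0.0396,0.6811,0.8364
RO,Rondônia,North,0,0.8348,0.0227,0.7903,0.8792
RR,Roraima,North,0,0.968,0.0183,0.9322,1.0038
NE,Northeast,Northeast,1,0.7289,0.0283,0.6735,0.7843
PI,Piauí,Northeast,0,0.6197,0.023,0.5747,0.6647
PE,Pernambuco,Northeast,0,0.657,0.0255,0.6069,0.7071
SE,Sergipe,Northeast,0,0.6808,0.0302,0.6216,0.7399
AL,Alagoas,Northeast,0,0.6969,0.0299,0.6383,0.7555
MA,Maranhão,Northeast,0,0.697,0.0376,0.6233,0.7706
CE,Ceará,Northeast,0,0.702,0.0295,0.6443,0.7598
BA,Bahia,Northeast,0,0.8142,0.0322,0.7511,0.8774
RN,Rio Grande do Norte,Northeast,0,0.8295,0.0184,0.7935,0.8654
PB,Paraíba,Northeast,0,0.8629,0.0206,0.8225,0.9032
SO,Southeast,Southeast,1,0.928,0.0382,0.8531,1.003
ES,Espírito Santo,Southeast,0,0.8319,0.0225,0.7879,0.876
RJ,Rio de Janeiro,Southeast,0,0.9024,0.0114,0.88,0.9248
MG,Minas Gerais,Southeast,0,0.9778,0.0072,0.9637,0.9918
SP,São Paulo,Southeast,0,1,0,1.00,1.00
S,South,South,1,0.9054,0.0426,0.7808,0.9479
SC,Santa Catarina,South,0,0.8733,0.0186,0.8368,0.9097
PR,Paraná,South,0,0.9162,0.0149,0.887,0.9454
RS,Rio Grande do Sul,South,0,0.9267,0.0151,0.8971,0.9563
MW,Midwest,Midwest,1,0.7889,0.0512,0.7046,0.9051
MT,Mato Grosso,Midwest,0,0.7128,0.0263,0.6613,0.7643
MS,Mato Grosso do Sul,Midwest,0,0.7412,0.0237,0.6947,0.7876
DF,Distrito Federal,Midwest,0,0.812,0.0241,0.7649,0.8592
GO,Goiás,Midwest,0,0.8896,0.0175,0.8553,0.9239
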