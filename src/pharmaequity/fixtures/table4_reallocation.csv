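dmu_id,name,region,is_region,comp_coef_bppp,comp_coef_bcpa,comp_value_bppp,comp_value_bcpa,sub_coef_bppp,sub_coef_bcpa,sub_value_bppp,sub_value_bcpa
N,North,North,1,,,109.38,322.68,,,94.11,402.7
TO,Tocantins,North,0,0.008,0.013,14.31,13.35,0.004,0.006,12.31,16.66
AC,Acre,North,0,0.004,0.041,7.63,41.68,0.002,0.018,6.57,52.01
AM,Amazonas,North,0,0.007,0.116,13.14,118.47,0.004,0.052,11.3,147.86
PA,Pará,North,0,0.021,0.04,38.75,40.53,0.012,0.018,33.34,50.58
AP,Amapá,North,0,0.004,0.09,7.53,92.08,0.002,0.04,6.48,114.91
RO,Rondônia,North,0,0.01,0.009,19.03,9.4,0.006,0.004,16.37,11.73
RR,Roraima,North,0,0.005,0.007,8.99,7.17,0.003,0.003,7.74,8.95
NE,Northeast,Northeast,1,,,369.07,303.35,,,317.58,378.59
PI,Piauí,Northeast,0,0.015,0.02,26.37,20.55,0.008,0.009,22.7,25.65
PE,Pernambuco,Northeast,0,0.04,0.046,73.06,47.29,0.022,0.021,62.87,59.02
SE,Sergipe,Northeast,0,0.009,0.016,16.69,16.46,0.005,0.007,14.36,20.54
AL,Alagoas,Northeast,0,0.012,0.022,21.83,22.05,0.007,0.01,18.78,27.52
MA,Maranhão,Northeast,0,0.016,0.047,29.2,47.72,0.009,0.021,25.12,59.55
CE,Ceará,Northeast,0,0.03,0.046,55.36,47.58,0.017,0.021,47.64,59.39
BA,Bahia,Northeast,0,0.038,0.068,68.95,69.26,0.021,0.03,59.33,86.44
RN,Rio Grande do Norte,Northeast,0,0.023,0.015,41.16,15.37,0.012,0.007,35.42,19.18
PB,Paraíba,Northeast,0,0.02,0.017,36.45,17.07,0.011,0.008,31.36,21.3
SO,Southeast,Southeast,1,,,791.77,239.87,,,681.33,299.37
ES,Espírito Santo,Southeast,0,0.033,0.015,59.96,15.16,0.018,0.007,51.6,18.92
RJ,Rio de Janeiro,Southeast,0,0.105,0.051,192.18,51.24,0.058,0.022,165.37,63.95
MG,Minas Gerais,Southeast,0,0.128,0.057,232.65,80.07,0.07,0.025,200.16,72.39
SP,São Paulo,Southeast,0,0.168,0.113,307.03,115.47,0.093,0.051,264.2,144.11
S,South,South,1,,,266.04,80.75,,,330.34,116.34
SC,Santa Catarina,South,0,0.041,0.022,74.84,22.88,0.023,0.01,64.4,28.56
PR,Paraná,South,0,0.064,0.034,116.36,34.99,0.035,0.015,100.13,43.66
RS,Rio Grande do Sul,South,0,0.106,0.035,196.69,35.35,0.058,0.016,165.81,44.12
MW,Midwest,Midwest,1,,,170.25,66.93,,,146.49,83.54
MT,Mato Grosso,Midwest,0,0.015,0.018,26.57,18.53,0.008,0.008,22.86,23.13
MS,Mato Grosso do Sul,Midwest,0,0.014,0.014,26.14,13.94,0.008,0.006,22.49,17.4
DF,Distrito Federal,Midwest,0,0.018,0.012,32.74,12.64,0.01,0.006,28.17,15.77
GO,Goiás,Midwest,0,0.047,0.021,84.8,21.82,0.026,0.01,72.97,27.24
TOTAL,Total,Total,1,,,1706.51,1013.58,,,1569.85,1280.54
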