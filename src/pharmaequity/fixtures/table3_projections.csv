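dmu_id,name,region,is_region,effective_bppp,effective_bcpa,effective_total,projected_bppp,projected_bcpa,projected_total
N,North,North,1,44.76,86.11,130.87,141.51,605.46,746.97
TO,Tocantins,North,0,5.1,8.19,13.29,18.51,25.05,43.56
AC,Acre,North,0,0.29,4.04,4.33,9.87,78.2,88.07
AM,Amazonas,North,0,0.98,18.47,19.45,17,222.3,239.3
PA,Pará,North,0,25.63,41.2,66.83,50.13,76.05,126.18
AP,Amapá,North,0,0.11,3.49,3.6,9.75,172.77,182.52
RO,Rondônia,North,0,11.05,8.3,19.35,24.62,17.64,42.26
RR,Roraima,North,0,1.6,2.42,4.02,11.63,13.45,25.08
NE,Northeast,Northeast,1,247.36,292.64,540,477.51,569.19,1046.7
PI,Piauí,Northeast,0,13.73,16.69,30.42,34.12,38.56,72.68
PE,Pernambuco,Northeast,0,49.24,47.32,96.56,94.52,88.73,183.25
SE,Sergipe,Northeast,0,6.68,11.02,17.7,21.6,30.88,52.48
AL,Alagoas,Northeast,0,10.82,17.64,28.46,28.24,41.37,69.61
MA,Maranhão,Northeast,0,12.64,34.21,46.85,37.77,89.54,127.31
CE,Ceará,Northeast,0,36.64,47.58,84.22,71.63,89.29,160.92
BA,Bahia,Northeast,0,51.3,77.59,128.89,89.21,129.96,219.17
RN,Rio Grande do Norte,Northeast,0,35,18.91,53.91,53.26,28.84,82.1
PB,Paraíba,Northeast,0,31.31,21.68,52.99,47.16,32.02,79.18
SO,Southeast,Southeast,1,961.16,424.44,1385.6,1024.36,450.09,1474.45
ES,Espírito Santo,Southeast,0,52.5,18.66,71.16,77.58,28.45,106.03
RJ,Rio de Janeiro,Southeast,0,219.59,84.35,303.94,248.63,96.15,344.78
MG,Minas Gerais,Southeast,0,291.85,104.77,396.62,300.93,108.83,409.76
SP,São Paulo,Southeast,0,397.22,216.66,613.88,397.22,216.66,613.88
S,South,South,1,426.96,146.81,573.77,496.66,174.92,671.58
SC,Santa Catarina,South,0,75.05,32.93,107.98,96.82,42.94,139.76
PR,Paraná,South,0,130.81,56.62,187.43,150.55,65.65,216.2
RS,Rio Grande do Sul,South,0,221.1,57.26,278.36,249.29,66.33,315.62
MW,Midwest,Midwest,1,144.1,76,220.1,220.26,125.6,345.86
MT,Mato Grosso,Midwest,0,15.8,17.09,32.89,34.37,34.78,69.15
MS,Mato Grosso do Sul,Midwest,0,16.43,13.25,29.68,33.82,26.16,59.98
DF,Distrito Federal,Midwest,0,24.03,13.49,37.52,42.35,23.71,66.06
GO,Goiás,Midwest,0,87.84,32.17,120.01,109.72,40.95,150.67
TOTAL,Total,Total,1,1824.34,1026.00,2850.00,2360.30,1925.26,4285.56
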