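peptide,protein,kd_uM,kd_err_uM,n,n_err,dh_kcal,dh_err_kcal,tds_kcal,tds_err_kcal,dg_kcal,dg_err_kcal,note
ARTK,BAZ2A PHD,100,4,1.57,0.03,-6.1,0.2,-0.6,0.2,-5.46,0.02,
ARTA,BAZ2A PHD,56,2,1.44,0.01,-4.7,0.1,1.1,0.1,-5.81,0.02,
ARTKQ,BAZ2A PHD,210,30,1.6,0.1,-3.7,0.4,1.3,0.4,-5.0,0.1,
ARTKQTARKS,BAZ2A PHD,51,2,1.35,0.01,-5.8,0.1,0.1,0.1,-5.86,0.02,
AATKQTARKS,BAZ2A PHD,>1000,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,
ARAKQTARKS,BAZ2A PHD,,,,,,,,,,,no binding
ARTAQTARKS,BAZ2A PHD,42,2,1.03,0.02,-6.1,0.2,-0.1,0.2,-6.00,0.03,
ARTKATARKS,BAZ2A PHD,9.3,0.2,1.21,0.01,-6.13,0.02,0.74,0.02,-6.87,0.01,
ARTKQAARKS,BAZ2A PHD,55,2,0.90,0.01,-5.6,0.1,0.2,0.1,-5.82,0.02,
ARTAATARKS,BAZ2A PHD,12.1,0.3,1.32,0.01,-7.01,0.04,-0.30,0.04,-6.71,0.02,
ARTGGTARKS,BAZ2A PHD,143,7,1.28,0.04,-7.4,0.3,-2.2,0.3,-5.25,0.03,
ARTKQ,BAZ2B PHD,190,25,1.0,0.1,-4.7,0.8,0.4,0.8,-5.1,0.1,
ARTKQTARKS,BAZ2B PHD,40.0,0.5,1.45,0.04,-5.43,0.02,0.58,0.02,-6.01,0.01,
AATKQTARKS,BAZ2B PHD,>1000,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,
ARAKQTARKS,BAZ2B PHD,>5000,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,
ARTAQTARKS,BAZ2B PHD,8.5,0.2,0.88,0.01,-6.62,0.04,0.30,0.05,-6.92,0.01,
ARTKATARKS,BAZ2B PHD,7.0,0.2,1.20,0.03,-6.18,0.02,0.86,0.03,-7.04,0.02,
ARTKQAARKS,BAZ2B PHD,44.6,0.8,1.01,0.01,-5.3,0.1,0.68,0.06,-5.94,0.01,
ARTAATARKS,BAZ2B PHD,2.6,0.1,1.13,0.01,-7.12,0.02,0.50,0.03,-7.63,0.02,
ARTGGTARKS,BAZ2B PHD,166,8,1.3,0.1,-8.4,0.5,-3.3,0.5,-5.16,0.03,
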