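peptide,protein,kd_uM,kd_err_uM,n,n_err,dh_kcal,dh_err_kcal,tds_kcal,tds_err_kcal,dg_kcal,dg_err_kcal,note
ARTKQTARKS,BAZ2A PHD wt,48,2,1.29,0.01,-7.9,0.1,-2.0,0.1,-5.90,0.02,
ARTKQTARKS,BAZ2A PHD E1689Q,83,7,1.02,0.03,-9.6,0.7,-4.0,0.8,-5.57,0.05,
ARTKQTARKS,BAZ2A PHD E1689K,116,6,1.1,0.4,-7.6,2.5,-2.2,0.4,-5.37,0.03,duplicate titration
ARTKQTARKS,BAZ2A PHD D1688N/E1689Q,810,50,1,,-9.0,1.2,-4.8,1.2,-4.22,0.04,N fixed to 1
ARTKQTARKS,BAZ2B PHD wt,47,2,1.17,0.02,-8.3,0.2,-2.4,0.2,-5.90,0.03,
ARTKQTARKS,BAZ2B PHD E1944Q,660,60,1,,-8.5,1.1,-4.1,1.1,-4.34,0.06,N fixed to 1
ARTKQTARKS,BAZ2B PHD E1944K,>1000,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,N.D.,
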