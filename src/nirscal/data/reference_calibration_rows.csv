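table,trait,n,terms,dt,scm,range_nm,mean,sd,sec,r2,secv,r2cv,rpd
wall_polymers,cellulose,140,3,"2,4,4,2",SNVD,408-2492,25.11,4.45,1.55,0.88,1.59,0.87,2.79
wall_polymers,ara,145,5,"1,4,4,1",SNV,408-2492,13.22,1.37,0.75,0.70,0.79,0.66,1.73
wall_polymers,xyl,139,9,"1,4,4,1",SNV,1108-2492,75.08,2.63,1.07,0.84,1.20,0.79,2.18
wall_polymers,xa,142,5,"1,4,4,1",SNV,408-2492,5.75,0.77,0.37,0.77,0.39,0.75,1.98
wall_polymers,asl,141,9,"1,4,4,1",MSC,1108-2492,3.13,0.41,0.12,0.91,0.15,0.87,2.78
wall_polymers,ail,140,5,"1,4,4,1",SNV,408-2492,8.20,1.40,0.71,0.74,0.76,0.70,1.82
wall_polymers,lignin_total,140,9,"0,0,1,1",WMSC,408-2492,11.33,1.55,0.69,0.80,0.75,0.77,2.07
saccharification,pent_pre,140,8,"2,5,5,2",DET,1108-2492,9.64,1.26,0.37,0.91,0.42,0.89,2.97
saccharification,hex_pre,142,10,"1,4,4,1",SNV,780-2492,19.34,7.95,1.16,0.98,1.35,0.97,5.89
saccharification,total_pre,141,10,"2,4,4,2",SNVD,780-2492,29.26,6.81,1.00,0.98,1.38,0.96,4.95
saccharification,pent_enz,138,9,"2,5,5,2",NONE,780-2492,23.90,4.01,0.69,0.97,0.83,0.96,4.80
saccharification,hex_enz,143,10,"2,10,10,2",NONE,780-2492,46.62,3.40,1.13,0.89,1.33,0.85,2.56
saccharification,total_enz,141,10,"2,4,4,2",SNVD,780-2492,70.74,6.81,1.00,0.98,1.38,0.96,4.95
saccharification,pent_total,141,8,"2,10,10,2",DET,1108-2492,15.21,1.59,0.48,0.91,0.54,0.88,2.93
saccharification,hex_total,139,9,"2,10,10,2",DET,780-2492,30.38,4.88,1.08,0.95,1.24,0.94,3.95
saccharification,sugar_total,138,9,"1,4,4,1",WMSC,1108-2492,45.31,3.97,1.21,0.91,1.38,0.88,2.88
saccharification,ferm_hex,144,9,"2,8,8,2",WMSC,408-2492,71.17,10.11,1.78,0.97,2.20,0.95,4.60
integrative,cellulose,234,7,"2,5,5,2",WMSC,1108-2492,26.09,4.95,1.56,0.90,1.69,0.88,2.94
integrative,ara,236,5,"2,4,4,1",NONE,780-2492,13.25,1.30,0.70,0.71,0.73,0.69,1.79
integrative,xyl,233,9,"2,4,4,2",NONE,1108-2492,75.16,2.71,1.04,0.85,1.15,0.82,2.35
integrative,xa,230,8,"0,0,1,1",SNV,408-2492,5.73,0.72,0.36,0.75,0.37,0.73,1.94
integrative,asl,234,9,"2,5,5,2",WMSC,780-2492,3.12,0.38,0.14,0.87,0.16,0.83,2.45
integrative,ail,231,7,"2,4,4,1",SNVD,1108-2492,8.34,1.34,0.69,0.74,0.74,0.69,1.81
integrative,lignin_total,231,7,"0,0,1,1",SNVD,408-2492,11.46,1.47,0.71,0.77,0.74,0.74,1.98
integrative,pent_pre,234,7,"2,4,4,2",MSC,1108-2492,9.78,1.24,0.43,0.88,0.47,0.86,2.63
integrative,hex_pre,228,8,"2,8,8,1",SNV,1108-2492,18.60,7.58,1.08,0.98,1.14,0.98,6.63
integrative,total_pre,230,12,"2,8,8,1",WMSC,780-2492,28.57,6.54,1.02,0.98,1.19,0.97,5.48
integrative,pent_enz,230,11,"2,10,10,2",NONE,1108-2492,24.37,3.84,0.74,0.96,0.81,0.96,4.74
integrative,hex_enz,233,10,"1,4,4,1",DET,408-2492,46.94,3.19,1.15,0.87,1.26,0.85,2.54
integrative,total_enz,230,12,"2,8,8,1",WMSC,780-2492,71.43,6.54,1.02,0.98,1.19,0.97,5.48
integrative,pent_total,234,12,"1,4,4,1",NONE,1108-2492,15.35,1.54,0.46,0.91,0.51,0.89,3.05
integrative,hex_total,232,11,"2,8,8,1",WMSC,1108-2492,29.89,4.62,1.20,0.93,1.40,0.91,3.30
integrative,sugar_total,233,11,"2,5,5,2",NONE,1108-2492,45.21,3.94,1.35,0.88,1.65,0.83,2.39
integrative,ferm_hex,235,9,"1,4,4,1",SNVD,408-2492,72.03,9.65,1.76,0.97,1.86,0.96,5.19
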