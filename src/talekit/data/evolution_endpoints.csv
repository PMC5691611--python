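il,strain,ale,start_conc_pct,initial_rate_h,end_conc_pct,final_rate_h,final_rate_sd_h,conc_change_pct,n_flasks
[C4C1Im]Cl,MG1655,1,1.5,0.3,6.2,0.2,0.02,4.7,62
[C4C1Im]Cl,MG1655,2,1.5,0.2,6.2,0.1,0.03,4.7,67
[C4C1Im]Cl,MG1655,3,1.5,0.3,4.9,0.3,0.12,3.4,63
[C4C1Im]Cl,MG1655,4,1.5,0.2,5.6,0.1,0.05,4.1,84
[C4C1Im]Cl,DH1,5,1.5,0.2,4.8,0.2,0.05,3.3,61
[C4C1Im]Cl,DH1,6,1.5,0.2,5.6,0.3,0.08,4.1,72
[C4C1Im]Cl,DH1,7,1.5,0.2,5.6,0.1,0.01,4.1,79
[C4C1Im]Cl,DH1,8,1.5,0.2,4.2,0.2,0.02,2.7,50
[C2C1Im][OAc],MG1655,9,2.0,0.2,5.9,0.1,0.00,3.9,86
[C2C1Im][OAc],MG1655,10,2.0,0.2,5.9,0.1,0.04,3.9,87
[C2C1Im][OAc],MG1655,11,2.0,0.2,6.5,0.2,0.00,4.5,91
[C2C1Im][OAc],MG1655,12,2.0,0.2,5.9,0.1,0.01,3.9,92
[C2C1Im][OAc],DH1,13,1.0,0.1,4.5,0.1,0.06,3.5,77
[C2C1Im][OAc],DH1,14,1.0,0.1,4.5,0.1,0.02,3.5,92
[C2C1Im][OAc],DH1,15,1.0,0.2,4.5,0.2,0.01,3.5,79
[C2C1Im][OAc],DH1,16,1.0,0.2,5.2,0.2,0.02,4.2,88
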