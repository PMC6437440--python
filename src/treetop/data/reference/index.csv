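n_obs,d,k,rho,n_reps,seed,n_trees,b_ref,filename
10000,5,50,0,100,101,200,2.001010101,ref_n10000_d5_k50_rho0.csv
10000,10,50,0,100,102,200,2.001010101,ref_n10000_d10_k50_rho0.csv
10000,5,100,0,100,103,200,2.840909091,ref_n10000_d5_k100_rho0.csv
10000,5,150,0,100,104,200,4.034343434,ref_n10000_d5_k150_rho0.csv
10000,5,200,0,100,105,200,4.790909091,ref_n10000_d5_k200_rho0.csv
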