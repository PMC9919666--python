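n_features,mean_random,mean_minimal,lower_bound,upper_bound,pct_decrease
4,1.000000,1.000000,1,8.333333,0.000000
16,1.000000,1.000000,1,54.091664,0.000000
64,97.400000,4.200000,3,303.609018,95.687885
256,600.000000,18.600000,13,1567.832310,96.900000
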