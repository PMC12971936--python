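response,sex,pubertal_group,n_stratum,p5,p25,p50,p75,p95
bri,female,prepubertal,442,1.156,1.459,1.709,1.985,2.509
bri,female,pubertal,1174,1.084,1.398,1.677,2.025,2.592
absi,female,all,1616,0.0727,0.0762,0.0788,0.0815,0.0863
bri,male,prepubertal,687,1.228,1.586,1.816,2.115,2.605
bri,male,pubertal,1175,1.039,1.348,1.645,2.038,2.670
absi,male,all,1862,0.0734,0.0764,0.0787,0.0811,0.0860
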