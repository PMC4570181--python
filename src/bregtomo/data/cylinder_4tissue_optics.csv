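region,label,mu_ax,mu_sx_prime,mu_am,mu_sm_prime
muscle,1,0.0052,1.08,0.0068,1.03
lungs,2,0.0133,1.97,0.0203,1.95
bone,3,0.0024,1.75,0.0035,1.61
heart,4,0.0083,1.01,0.0104,0.99
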