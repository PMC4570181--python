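tissue,mu_a,mu_s_prime
adipose,0.1017,1.2929
bladder,0.1017,1.2929
heart,1.5477,1.1674
lungs,4.6832,2.3271
liver,9.2860,0.7786
spleen,9.2860,0.7786
stomach,0.3082,1.6320
kidneys,1.7334,2.7599
bone,1.5233,3.0393
intestines,0.2891,1.3548
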