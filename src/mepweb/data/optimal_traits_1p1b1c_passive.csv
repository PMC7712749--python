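group,ecotype,trait,value
P,1,eps,0.3452
P,1,t_on,0.0
P,1,t_off,1.0
P,1,omega_amp,0.8036
B,1,eps,0.1618
B,1,omega_1,0.3852
B,1,omega_2,0.1609
B,1,omega_3,0.4539
C,1,eps,0.9971
C,1,omega_P1,0.0
C,1,omega_B1,0.3888
C,1,omega_C1,0.5868
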