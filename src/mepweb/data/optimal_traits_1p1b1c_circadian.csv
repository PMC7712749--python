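group,ecotype,trait,value
P,1,eps,0.3788
P,1,t_on,0.2389
P,1,t_off,0.7799
P,1,omega_amp,1.0
B,1,eps,0.1628
B,1,omega_1,0.4349
B,1,omega_2,0.2869
B,1,omega_3,0.2782
C,1,eps,0.0001
C,1,omega_P1,0.6547
C,1,omega_B1,0.5809
C,1,omega_C1,0.0963
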