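group,ecotype,trait,value
P,1,eps,0.2536
P,1,t_on,0.0
P,1,t_off,1.0
P,1,omega_amp,0.6746
B,1,eps,0.1686
B,1,omega_1,0.3351
B,1,omega_2,0.1997
B,1,omega_3,0.4651
C,1,eps,0.0001
C,1,omega_P1,0.7288
C,1,omega_B1,0.0729
C,1,omega_C1,0.4396
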