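program,R_m,K,N_1
san_diego,1.57,210325,240690
alachua,4.1,19323,36398
orcat,2.45,101,661
ucf,1.17,34,68
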