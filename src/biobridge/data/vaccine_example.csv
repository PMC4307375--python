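trial_id,n_t,n_c,b_t,b_c,x_t,x_c
1,1477,1477,2,213,0,23
2,1600,1600,10,86,1,6
3,265,264,2,45,0,2
4,1837,1837,27,130,3,8
5,1726,1726,24,296,0,30
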