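pdb_id,val,val_sem,coul,coul_sem,lj,lj_sem
1DPU,-1.80,0.01,3.83,0.14,-17.27,0.09
1RST,0.01,0.01,-1.45,0.13,-8.62,0.08
2LQC,2.92,0.01,-0.66,0.14,-9.89,0.09
2MNU,-2.13,0.01,7.33,0.16,-9.00,0.10
2MWY,3.95,0.01,-2.39,0.11,-16.89,0.07
4F14,-0.49,0.01,3.69,0.14,-11.18,0.09
4Q6F,-5.86,0.01,12.24,0.12,-14.05,0.07
5E0M,-3.18,0.01,10.75,0.14,-14.20,0.09
5OVC,-1.16,0.01,8.90,0.14,-16.46,0.08
6EVO,2.34,0.01,3.59,0.12,-13.90,0.07
6H8C,3.09,0.01,8.83,0.14,-19.15,0.09
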