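pdb_id,dh_exp,dh_exp_sem,temperature_c,reference
1DPU,-16.80,0.28,,Xie et al
1RST,-12.56,0.09,,Schmidt et al
2LQC,-6.91,0.07,,Liu and Vogel
2MNU,-4.60,0.10,,Yu et al
2MWY,-17.50,0.30,,Grace et al
4F14,-8.46,0.48,,Eulitz et al
4Q6F,-9.81,0.04,,Tallant et al
5E0M,-8.20,0.10,,Clark et al
5OVC,-6.80,0.04,,Ponna et al
6EVO,-8.70,0.80,,Murthy et al
6H8C,-5.91,0.09,,Huber et al
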