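observer,kind,fom,ci_lower,ci_upper,std_err,wllf_at_fpf_0_2
RetinaNet,cnn,0.81,0.75,0.87,0.028,0.71
U-Net,cnn,0.58,0.47,0.68,0.052,0.41
Reader 1,reader,0.82,0.79,0.86,0.017,0.71
Reader 2,reader,0.87,0.83,0.90,0.017,0.79
Reader 3,reader,0.74,0.68,0.79,0.029,0.57
Reader 4,reader,0.74,0.70,0.78,0.022,0.59
Reader 5,reader,0.78,0.75,0.81,0.015,0.65
Reader 6,reader,0.87,0.83,0.91,0.020,0.79
Reader 7,reader,0.83,0.79,0.88,0.022,0.74
Reader 8,reader,0.54,0.44,0.63,0.048,0.31
Reader 9,reader,0.84,0.79,0.88,0.023,0.75
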