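observer,kind,tp,fp,fn
RetinaNet,cnn,268,66,102
U-Net,cnn,256,279,114
Reader 1,reader,244,5,126
Reader 2,reader,278,15,92
Reader 3,reader,207,29,163
Reader 4,reader,185,9,185
Reader 5,reader,201,9,169
Reader 6,reader,294,35,76
Reader 7,reader,273,52,97
Reader 8,reader,281,276,89
Reader 9,reader,276,35,94
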