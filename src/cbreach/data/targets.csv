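target,x_cm,y_cm,z_cm
1,-10,20,-30
2,-10,20,-10
3,-10,30,-30
4,-10,30,-20
5,30,20,-30
6,30,20,-10
7,20,40,-20
8,30,30,-10
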