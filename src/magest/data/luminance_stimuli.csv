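stimulus,x_chrom,y_chrom,Y,is_reference
1,0.303,0.307,1.0,0
2,0.308,0.314,1.8,0
3,0.311,0.317,3.2,0
4,0.314,0.321,5.7,0
5,0.313,0.322,10.0,1
6,0.315,0.322,17.9,0
7,0.314,0.321,32.0,0
8,0.315,0.322,57.2,0
9,0.313,0.320,100.0,0
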