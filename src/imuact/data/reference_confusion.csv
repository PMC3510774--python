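true_class,C1,C2,C3,C4,C5,C6,C7,C8,C9
C1,572,30,5,0,0,0,0,0,0
C2,29,602,13,0,0,4,5,0,1
C3,7,17,475,25,0,0,1,0,2
C4,0,1,32,389,0,0,0,2,0
C5,0,0,0,0,266,0,0,0,0
C6,8,15,2,0,0,67,4,0,0
C7,6,7,3,0,0,4,77,0,0
C8,1,8,10,1,0,0,0,50,1
C9,0,16,14,0,0,1,0,0,34
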