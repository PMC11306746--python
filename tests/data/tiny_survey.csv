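f1,f2,f3,target
0,2,1,1.5
1,0,1,-0.25
2,1,0,3.0
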