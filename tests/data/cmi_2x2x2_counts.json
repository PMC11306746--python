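{
 "comment": "joint counts n(x,y,z) over binary x,y,z for the conditional-MI oracle check",
 "counts": [[[5, 1], [2, 4]], [[1, 6], [3, 2]]]
}
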