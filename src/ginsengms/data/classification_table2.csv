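sample,actual,recognized_raw,recognized_normalized
S1,LN,JL,LN
S2,LN,LN,LN
S3,LN,JL,LN
S4,LN,JL,LN
S5,HLJ,HLJ,HLJ
S6,HLJ,HLJ,HLJ
S7,HLJ,HLJ,HLJ
S8,HLJ,JL,HLJ
S9,JL,JL,JL
S10,JL,JL,JL
S11,JL,JL,JL
S12,JL,JL,JL
S13,HLJ,HLJ,HLJ
S14,HLJ,HLJ,HLJ
S15,HLJ,JL,HLJ
S16,HLJ,HLJ,HLJ
S17,JL,JL,JL
S18,JL,JL,JL
S19,JL,JL,JL
S20,JL,JL,JL
S21,JL,JL,JL
S22,JL,JL,JL
S23,JL,JL,JL
S24,JL,JL,JL
S25,JL,JL,JL
S26,JL,JL,JL
S27,JL,JL,JL
S28,JL,JL,JL
S29,JL,JL,JL
S30,JL,JL,JL
S31,JL,JL,JL
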