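sample,actual,recognized
S32,LN,LN
S33,HLJ,HLJ
S34,JL,JL
S35,JL,JL
S36,JL,JL
S37,JL,JL
S38,JL,JL
S39,JL,JL
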