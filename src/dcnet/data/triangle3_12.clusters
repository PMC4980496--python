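taxa: 1,2,3,4,5,6,7
1,2,3,5
1,2,4,6
1,3,4,7
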