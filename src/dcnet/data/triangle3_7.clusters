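taxa: 1,2,3,4,5
2,3
1,2,4
1,3,5
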