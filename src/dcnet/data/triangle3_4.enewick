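(((1)#H1,(2)#H2,(3)#H3,6),(#H1,#H2,4),(#H1,#H3,5));
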