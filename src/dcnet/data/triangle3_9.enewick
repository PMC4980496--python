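((((1,(2)#H1,(3)#H2),4),#H1),#H2);
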