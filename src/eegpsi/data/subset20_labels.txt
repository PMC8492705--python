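E1
E8
E9
E17
E18
E27
E28
E38
E39
E47
E55
E56
E64
E72
E73
E77
E82
E83
E87
E92
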