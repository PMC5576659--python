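synth_0000	site	1,5
synth_0001	site	22,25,55
synth_0002	site	57
synth_0003	site	6,31
synth_0004	site	7,20,53
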