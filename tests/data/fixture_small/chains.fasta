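>synth_0000
ENRLESATARETLGKADPPNIYYQPQIDRLGLTVIMGNHITFNCSSFTAHDKSFAIECMG
>synth_0001
LDIARTDQSYTKYYLRVLTQGEMCDALKKMDVQSVMAQMSLSYHEIRKMDRGETDLVCQH
>synth_0002
MDAKRNGRLYSSGEEKLESTGLNRDGRMVKIGFPGTGPMNVEDDALESAILEIFGVHINP
>synth_0003
IRNENCDEIAVFGIVIKGYICPQIEIKYTNCQRAIGMPELYAIHITKTMKFSPEDDVISV
>synth_0004
LNTLIFDLSKAECHQNPKDHLLFSKTGVDRAFTHVVSITKDTSDTLRGETNDHTKHHSKV
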