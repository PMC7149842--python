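# Genes previously reported as causal for congenital cervical vertebral fusion
GDF6
MEOX1
GDF3
MYO18B
RIPPLY2
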