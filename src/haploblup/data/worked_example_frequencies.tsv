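haplotype	frequency
1	0.4
2	0.3
3	0.2
4	0.1
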