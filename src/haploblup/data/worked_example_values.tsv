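i	j	value
1	1	25
1	2	18
1	3	15
1	4	10
2	2	30
2	3	33
2	4	40
3	3	17
3	4	12
4	4	35
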