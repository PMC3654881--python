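# five-position worked-example weighted sequence
# position 2 and 5 are deterministic (G, C); others carry distributions
1	A:0.5,C:0.25,G:0.25
2	G:1.0
3	A:0.6,C:0.4
4	A:0.25,C:0.25,G:0.25,T:0.25
5	C:1.0
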