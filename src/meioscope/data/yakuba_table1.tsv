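arm	n0	n1	n2	n3	n4
X	447	901	200	74	0
2L	835	708	116	2	0
2R	463	312	50	14	2
3L	694	781	209	17	0
3R	683	829	107	15	1
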