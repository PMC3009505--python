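bond	a1-2	a1-3	a1-4	a1-6	b1-2	b1-3	b1-4	b1-6	a2-3	a2-6	a2-8	a2-9	-6	-3	-4
a1-2	1
a1-3	0.6	1
a1-4	0.6	0.9	1
a1-6	0.6	0.6	0.6	1
b1-2	0.8	0.5	0.5	0.5	1
b1-3	0.5	0.8	0.6	0.5	0.6	1
b1-4	0.5	0.6	0.8	0.5	0.6	0.9	1
b1-6	0.5	0.5	0.5	0.8	0.6	0.6	0.6	1
a2-3	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	1
a2-6	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.6	1
a2-8	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.6	0.7	1
a2-9	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.4	0.6	0.7	0.85	1
-6	0	0	0	0.55	0	0	0	0.3	0	0	0	0	1
-3	0	0.47	0	0	0	0.41	0	0	0	0	0	0	0	1
-4	0	0	0.8	0	0	0	0.2	0	0	0	0	0	0	0	1
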