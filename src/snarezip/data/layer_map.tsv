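chain	layer	residue
sn1	-7	29
sn1	-6	32
sn1	-5	36
sn1	-4	39
sn1	-3	43
sn1	-2	46
sn1	-1	50
sn1	0	53
sn1	1	57
sn1	2	60
sn1	3	64
sn1	4	67
sn1	5	71
sn1	6	74
sn1	7	78
sn1	8	81
sn2	-7	150
sn2	-6	153
sn2	-5	157
sn2	-4	160
sn2	-3	164
sn2	-2	167
sn2	-1	171
sn2	0	174
sn2	1	178
sn2	2	181
sn2	3	185
sn2	4	188
sn2	5	192
sn2	6	195
sn2	7	199
sn2	8	202
syb	-7	32
syb	-6	35
syb	-5	39
syb	-4	42
syb	-3	46
syb	-2	49
syb	-1	53
syb	0	56
syb	1	60
syb	2	63
syb	3	67
syb	4	70
syb	5	74
syb	6	77
syb	7	81
syb	8	84
syx	-7	202
syx	-6	205
syx	-5	209
syx	-4	212
syx	-3	216
syx	-2	219
syx	-1	223
syx	0	226
syx	1	230
syx	2	233
syx	3	237
syx	4	240
syx	5	244
syx	6	247
syx	7	251
syx	8	254
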