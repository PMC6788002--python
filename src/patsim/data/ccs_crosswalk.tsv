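icd_prefix	ccs
E10	49
E11	49
E12	49
E13	49
E14	49
E115	50
E142	50
E03	48
E66	58
E78	53
I20	102
I25	101
I50	108
I63	109
J18	122
J44	127
J45	128
K21	138
K73	151
K76	151
N18	158
N39	159
G45	112
M81	206
D64	59
F32	69
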