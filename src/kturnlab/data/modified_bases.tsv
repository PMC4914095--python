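code	parent
PSU	U
1MA	A
2MA	A
MA6	A
A2M	A
1MG	G
2MG	G
M2G	G
7MG	G
OMG	G
G7M	G
YG	G
5MC	C
OMC	C
4OC	C
5MU	U
OMU	U
4SU	U
H2U	U
UR3	U
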