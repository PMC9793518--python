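gene	allele	freq
A	A*02:01:01:01	0.27
A	A*01:01:01:01	0.16
A	A*03:01:01:01	0.13
A	A*24:02:01:01	0.12
A	A*11:01:01:01	0.10
A	A*26:01:01:01	0.08
A	A*68:01:02:01	0.08
A	A*31:01:02:01	0.06
B	B*07:02:01:01	0.16
B	B*08:01:01:01	0.13
B	B*44:02:01:01	0.12
B	B*15:01:01:01	0.11
B	B*35:01:01:02	0.11
B	B*40:01:02:01	0.11
B	B*51:01:01:01	0.10
B	B*18:01:01:02	0.09
B	B*57:01:01:01	0.07
C	C*07:01:01:01	0.17
C	C*07:02:01:03	0.16
C	C*04:01:01:06	0.14
C	C*03:04:01:01	0.12
C	C*06:02:01:01	0.12
C	C*05:01:01:02	0.11
C	C*12:03:01:01	0.10
C	C*01:02:01:01	0.08
DRB1	DRB1*15:01:01:01	0.15
DRB1	DRB1*03:01:01:01	0.13
DRB1	DRB1*07:01:01:01	0.13
DRB1	DRB1*04:01:01:01	0.11
DRB1	DRB1*01:01:01:01	0.10
DRB1	DRB1*11:01:01:01	0.10
DRB1	DRB1*13:01:01:01	0.10
DRB1	DRB1*08:01:01:01	0.09
DRB1	DRB1*09:01:02:01	0.09
DQB1	DQB1*03:01:01:01	0.19
DQB1	DQB1*02:01:01:01	0.15
DQB1	DQB1*06:02:01:01	0.14
DQB1	DQB1*05:01:01:01	0.13
DQB1	DQB1*03:02:01:01	0.12
DQB1	DQB1*04:02:01:01	0.10
DQB1	DQB1*06:03:01:01	0.09
DQB1	DQB1*05:03:01:01	0.08
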