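	SC	Thalamus	RTN	GPi/SNr	STN	GPe	Str-D2	Str-D1	CCortex
SC		1
Thalamus			1		1	1	1	1	1
RTN		-1
GPi/SNr	-1	-1	-1
STN				2		2			2
GPe			-1/2	-1/2	-1/2		-1/2	-1/2
Str-D2						-1
Str-D1				-1/2		-1/2
CCortex	1/2	1/2	1/2		1/2		1/2	1/2
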