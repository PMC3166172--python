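orf	gene	5g_25	5g_50	5g_100	15g_25	15g_50	15g_100
YBR292C		-2.3	-1.5	-1.2			-1.5
YJL120W				-3.25	-2.95	-4.5	-4.6
YGR130C		-2.1	-2.4	-2.2			
YJL121C	RPE1			-2.6	-3.1		-4.2
YHR206W	SKN7			-2.45	-3.7	-4.7	
YML028W	TSA1			-2.2		-2.7	-3.3
YGL148W	ARO2			-1.3		-2.6	-3.05
YPR074C	TKL1			-1.3		-3.75	-3.9
YLR380W	CSR1			-1.1		-4.6	-2.8
YBR035C	PDX3				-2.2	-2.4	-2.6
YIL162W	SUC2				-2	-3.3	-3.7
YFR036W	CDC26				-3.1	-4.3	-4.4
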