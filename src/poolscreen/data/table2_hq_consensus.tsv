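orf	gene	5g_25	5g_50	5g_100	15g_25	15g_50	15g_100
YOL081W	IRA2	-2.5	-3.3	-4.1	-4	-6.2	-2.6
YOL085C		-1.95	-2.1	-3	-4.35	-4.85	-3.3
YHL009C	YAP3	-2.3	-2.3	-2.9	-4.15	-3.6	
YJL121C	RPE1	-2.2	-2.4	-2.85	-3.3	-3	
YDR032C	PST2		-2.3	-3	-2.3	-3.4	-3.2
YOL013C	HRD1		-1.5	-2.1	-4.2	-3.8	-3.1
YOL079W			-2.4	-2.45	-3.55	-2.95	-3.35
YOL025W	LAG2		-1.7	-1.9	-3.5	-3.3	-2.55
YJL120W			-1.9	-2.25	-3.9	-3.8	
YGR130C		-2.1	-2.2	-2.4			
YLR077W	FMP25	-1.6	-1.5	-1.1			
YKL147C		-1.6	-1.4	-1.3			
YCR068W	ATG15	-1.6	-1.2	-1.6			
YMR237W	BCH1	-1.5	-1.3	-1.4			
YOR084W	LPX1	-1.3	-1.4	-1.3			
YCR004C	YCP4		-1.5	-1.5			-3.6
YOR325W			-1.3	-1.6			-2.2
YDL020C	RPN4			-1.6	-3.8	-3.4	
YNL148C	ALF1	-1.9		-2.5	-3.9		
YGR139W		-1.7	-1.5	-1.5			
YHR030C	SLT2			-1.6	-2.7		-3.3
YKL040C	NFU1			-1.4		-1.9	-2.1
YIL162W	SUC2				-3.8	-4.4	-4.1
YMR022W	UBC7				-2.4	-2.4	-2.2
YBR035C	PDX3				-2.4	-2.4	-2.3
YPR074C	TKL1				-2.3	-3.1	-3.8
YDL225W	SHS1				-1.8	-3.2	-2.9
YDR112W	IRC2				-4.1	-4.4	-4.3
YEL056W	HAT2				-3.6	-3.7	-3.8
YDR457W	TOM1				-3.1	-3.2	-2.2
YPL138C	SPP1				-2.8	-3.3	-3.2
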