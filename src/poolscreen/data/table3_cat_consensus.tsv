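orf	gene	5g_25	5g_50	5g_100	15g_25	15g_50	15g_100
YGR130C		-2.3	-2.2	-2.3		-1.9	-1.8
YPR076W		-1.8	-1.8	-1.7	-2.9		
YGR117C		-2	-2	-1.9	-3.1		
YKR046C	PET10	-1.4	-1.4	-1.3	-4		
YDL211C		-1.2	-1.3	-1.1	-4		
YAL002W	VPS8			-2.3	-3.5	-3.6	-5
YJL120W				-1.5	-2.75	-2.95	-4
YKL133C				-1.2	2.8	2.6	2.6
YJL121C	RPE1			-1.1	-2.9	-2.6	-3.8
YOR084W	LPX1	-1.2	-1.1	-1.1			
YPL230W	USV1	-1.2	-1.2	-1.1			
YHR060W	VMA22	-1.4	-2.05	-2.45			
YHR137W	ARO9	-2	-2	-1.9			
YDL182W	LYS20	-1.7	-1.9	-1.8			
YGL043W	DST1	-1.6	-1.6	-1.4			
YGL071W	AFT1	-1.4	-2.65	-3.8			
YKL119C	VPH2	-2	-2.85	-2.4			
YOR089C	VPS21			-1.5		-2.45	-4.7
YCL007C		-2.1	-2.2	-2.7			
YOR331C		-2.1	-2.2	-2.1			
YKR052C	MRS4				-2.45	-4.35	-5.7
YMR153W	NUP53				-0.45	-2.2	-2
YFR036W	CDC26				-5.2	-4.95	-4.75
YKR020W	VPS51				-2.3	-2.4	-2.95
YKL071W					-1.6	-1.3	-1.3
YKL123W					-2.2	-1.6	-1.7
YKL222C					-2.2	-1.9	-2
YGL094C	PAN2				-2.1	-2.1	-2.2
YGR110W	CLD1				-1.9	-1.8	-1.9
YDL236W	PHO13				-1.8	-1.6	-1.7
YKL051W	SFK1				-1.8	-1.7	-1.8
YKR033C					-1.8	-1.5	-1.6
YHL026C					-1.7	-1.4	-1.5
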