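gene	rpkm	region	mirna	start_spec	dg_spec	ratio_spec	length
EPOR	8.1	5'UTR	ID01633.3p-miR	77	-108	91	21
EPOR	8.1	5'UTR	ID01599.3p-miR	79	-119	89	23
EPOR	8.1	5'UTR	ID01626.3p-miR	80	-129	90	23
MAZ	9.5	5'UTR	ID00968.3p-miR	16	-117	93	20
MAZ	9.5	5'UTR	ID01476.3p-miR	16	-134	91	23
MAZ	9.5	5'UTR	miR-1470	18	-123	97	21
MAZ	9.5	5'UTR	ID00620.3p-miR	27	-127	91	23
MAZ	9.5	5'UTR	miR-6850-5p	92	-115	87	22
MAZ	9.5	5'UTR	miR-4466	107	-110	98	18
MAZ	9.5	5'UTR	miR-762	111	-123	91	22
MAZ	9.5	5'UTR	D00915.3p-miR	112	-127	88	24
MAZ	9.5	5'UTR	ID02979.5p-miR	114	-121	92	22
NISCH	32.2	5'UTR	ID03445.3p-miR	31	-125	88	24
NISCH	32.2	5'UTR	ID01560.3p-miR	38	-123	89	23
NISCH	32.2	5'UTR	ID03119.5p-miR	41	-125	88	24
MAPK3	32.6	CDS	ID00149.3p-miR	1,144	-117	93	22
MAPK3	32.6	CDS	ID01748.3p-miR	1,144	-110	91	21
MAPK3	32.6	CDS	miR-6805-3p	1,145	-117	87	23
MAZ	9.5	CDS	miR-6729-5p	361	-115	87	22
MAZ	9.5	CDS	ID02623.3p-miR	363	-125	89	23
MAZ	9.5	CDS	ID02460.5p-miR	372	-119	92	22
MAZ	9.5	CDS	miR-2861	375	-110	95	19
MAZ	9.5	CDS	ID02294.5p-miR (3)	457 ÷ 469	-134 ÷ -138	91 ÷ 94	24
MAZ	9.5	CDS	ID02986.5p-miR	459	-119	93	21
MAZ	9.5	CDS	ID01819.5p-miR	461	-125	87	25
MAZ	9.5	CDS	ID01804.3p-miR (2)	464 ÷ 467	-140	88	25
MAZ	9.5	CDS	ID02064.5p-miR	489	-121	92	21
MAZ	9.5	CDS	ID02538.3p-miR	489	-125	94	22
MAZ	9.5	CDS	ID00296.3p-miR	500	-138	88	25
MAZ	9.5	CDS	miR-3960	505	-119	95	20
MAZ	9.5	CDS	ID01641.3p-miR	506	-132	89	24
MAZ	9.5	CDS	miR-4706	605	-123	87	25
MAZ	9.5	CDS	ID01705.3p-miR	608	-117	92	21
MAZ	9.5	CDS	ID01641.3p-miR	608	-134	90	24
MAZ	9.5	CDS	miR-3960	612	-117	93	20
MAZ	9.5	CDS	ID01768.3p-miR	893	-113	90	22
MAZ	9.5	CDS	ID01911.5p-miR	900	-123	89	23
MAZ	9.5	CDS	ID00849.3p-miR	901	-125	97	22
BRCA2	0.1	3'UTR	ID00112.5p-miR	10,722	-102	91	21
BRCA2	0.1	3'UTR	ID02744.3p-miR	10,738	-104	92	22
BRCA2	0.1	3'UTR	miR-619-5p	10,746	-117	96	22
CDK6	2.2	3'UTR	miR-548h-3p	1,677	-104	91	23
CDK6	2.2	3'UTR	miR-548z	1,677	-104	91	23
CDK6	2.2	3'UTR	miR-548aq-3p	1,678	-102	94	22
CDK6	2.2	3'UTR	miR-548az-3p	1,678	-98	94	21
CDK6	2.2	3'UTR	ID03264.3p-miR	1,678	-98	90	22
CDK6	2.2	3'UTR	ID00436.3p-miR (9)	1,896 ÷ 1,920	-104 ÷ -106	89 ÷ 91	23
CDK6	2.2	3'UTR	ID01030.3p-miR (7)	1,900 ÷ 1,918	-108 ÷ -115	89 ÷ 95	23
CDK6	2.2	3'UTR	ID02513.5p-miR	1,901	-102	91	22
CDK6	2.2	3'UTR	miR-466 (10)	1,908 ÷ 1,926	-104 ÷ -108	90 ÷ 93	23
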