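gene	rpkm	region	mirna	start_spec	dg_spec	ratio_spec	length
CBL	3.9	5'UTR	ID03332.3p-miR (4)	16 ÷ 25	-134 ÷ -140	90 ÷ 94	24
CBL	3.9	5'UTR	ID01310.3p-miR (4)	17 ÷ 26	-121	92	22
CBL	3.9	5'UTR	ID02761.3p-miR	28	-138	93	24
CBL	3.9	5'UTR	miR-1908-3p	30	-121	92	21
CBL	3.9	5'UTR	ID00278.3p-miR	32	-125	91	23
CBL	3.9	5'UTR	ID02430.3p-miR	34	-110	98	18
MMP2	192.4	5'UTR	ID00278.3p-miR	110	-123	89	23
MMP2	192.4	5'UTR	ID01310.3p-miR	113	-121	92	22
MMP2	192.4	5'UTR	ID03037.3p-miR	115	-121	90	22
MMP2	192.4	5'UTR	ID03345.5p-miR	124	-127	90	24
MMP2	192.4	5'UTR	ID03368.3p-miR	125	-117	89	23
RAB5A	16.1	5'UTR	ID02930.3p-miR	184	-132	89	24
RAB5A	16.1	5'UTR	ID03445.3p-miR	189	-127	90	24
RAB5A	16.1	5'UTR	ID01859.5p-miR	191	-121	89	23
RAB5A	16.1	5'UTR	ID01804.3p-miR	325	-140	88	25
RAB5A	16.1	5'UTR	ID03367.5p-miR	328	-121	97	20
RAB5A	16.1	5'UTR	ID00061.3p-miR	334	-127	92	22
ATM	3.9	3'UTR	ID03006.5p-miR	9,778	-121	89	24
ATM	3.9	3'UTR	miR-5095	9,787	-108	93	21
ATM	3.9	3'UTR	miR-619-5p	9,793	-119	98	22
ATM	3.9	3'UTR	miR-1273a	11,054	-119	90	25
ATM	3.9	3'UTR	ID00367.5p-miR	11,069	-110	90	22
ATM	3.9	3'UTR	miR-1273g-3p	11,076	-113	96	21
CBL	3.9	3'UTR	miR-1273a	7,727	-117	89	25
CBL	3.9	3'UTR	ID01838.5p-miR	7,728	-117	93	24
CBL	3.9	3'UTR	miR-1273g-3p	7,749	-115	98	21
IL11	0.1	3'UTR	miR-1273f	1,466	-102	98	19
IL11	0.1	3'UTR	miR-1273d	1,467	-121	89	25
IL11	0.1	3'UTR	ID01404.5p-miR	1,470	-113	91	23
IL11	0.1	3'UTR	miR-1273e	1,476	-113	96	22
RUNX1	9.0	3'UTR	ID01030.3p-miR (2)	5,454 ÷ 5,464	-108 ÷ -113	89 ÷ 93	23
RUNX1	9.0	3'UTR	miR-466 (2)	5,456 ÷ 5,460	-106 ÷ -110	91 ÷ 95	23
RUNX1	9.0	3'UTR	D00436.3p-miR	5,464	-108	93	23
SFN	9.4	3'UTR	miR-6089	826	-129	87	24
SFN	9.4	3'UTR	ID01774.5p-miR	835	-129	90	23
SFN	9.4	3'UTR	miR-6846-5p	839	-113	91	22
SFN	9.4	3'UTR	ID00790.3p-miR	1,179	-104	89	23
SFN	9.4	3'UTR	ID02868.3p-miR	1,188	-113	90	23
SFN	9.4	3'UTR	miR-466 (6)	1,190 ÷ 1,200	-106	91	23
SFN	9.4	3'UTR	ID01030.3p-miR (6)	1,190 ÷ 1,200	-108	89	23
SFN	9.4	3'UTR	ID00436.3p-miR (7)	1,190 ÷ 1,202	-104	89	23
SFN	9.4	3'UTR	ID01727.5p-miR (2)	1,203 ÷ 1,205	-104 ÷ -106	89 ÷ 91	23
SFN	9.4	3'UTR	ID02882.3p-miR	1,210	-108	91	21
STMN1	6.6	3'UTR	miR-1273a	1,729	-115	87	25
STMN1	6.6	3'UTR	ID03011.5p-miR	1,730	-106	91	22
STMN1	6.6	3'UTR	ID00367.5p-miR	1,744	-113	91	22
STMN1	6.6	3'UTR	miR-1273g-3p	1,751	-108	93	21
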