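gene	rpkm	region	mirna	start_spec	dg_spec	ratio_spec	length
FOXA1	10.2	5'UTR	ID00297.5p-miR	99	-123	89	24
FOXA1	10.2	5'UTR	ID02106.3p-miR	110	-123	89	23
FOXA1	10.2	5'UTR	ID00252.5p-miR	111	-140	94	24
FOXA1	10.2	5'UTR	ID02769.5p-miR	112	-127	92	22
FOXA1	10.2	5'UTR	ID01099.5p-miR	116	-108	100	17
FOXA1	10.2	5'UTR	ID01190.5p-miR	118	-108	100	17
FOXA1	10.2	5'UTR	ID00296.3p-miR	115	-140	89	25
FOXA1	10.2	5'UTR	ID01641.3p-miR	122	-134	90	24
FOXA1	10.2	5'UTR	ID01403.5p-miR	120	-123	91	23
FOXA1	10.2	5'UTR	ID00061.3p-miR	127	-129	94	22
FOXA1	10.2	5'UTR	ID03367.5p-miR (2)	121 ÷ 122	-117	93	20
FOXA1	10.2	5'UTR	miR-3960	120	-115	92	20
FOXA1	10.2	5'UTR	ID00071.3p-miR (2)	118 ÷ 121	-117 ÷ -121	93 ÷ 97	20
FOXA1	10.2	5'UTR	ID02457.3p-miR	118	-108	100	17
FOXA1	10.2	5'UTR	ID02595.5p-miR	118	-115	92	20
FOXA1	10.2	5'UTR	ID01702.3p-miR	120	-140	89	25
FOXA1	10.2	5'UTR	ID00457.3p-miR	124	-123	91	22
FOXA1	10.2	5'UTR	ID02499.3p-miR (2)	127 ÷ 130	-119 ÷ -121	92 ÷ 93	21
HMGA2	0.0	5'UTR	miR-6756-5p	529	-117	87	23
HMGA2	0.0	5'UTR	ID01737.3p-miR	539	-119	93	21
HMGA2	0.0	5'UTR	ID01041.5p-miR (2)	541 ÷ 544	-129 ÷ -134	88 ÷ 91	24
HMGA2	0.0	5'UTR	ID00089.3p-miR	542	-125	91	22
HMGA2	0.0	5'UTR	ID01323.3p-miR	542	-117	95	20
HMGA2	0.0	5'UTR	ID02296.5p-miR	542	-115	93	20
HMGA2	0.0	5'UTR	ID0296.3p-miR	544	-146	93	25
HMGA2	0.0	5'UTR	ID01641.3p-miR	544	-142	96	24
HMGA2	0.0	5'UTR	ID01403.5p-miR	547	-119	88	23
HMGA2	0.0	5'UTR	ID00061.3p-miR	550	-132	95	22
HMGA2	0.0	5'UTR	ID03367.5p-miR	550	-115	92	20
HMGA2	0.0	5'UTR	miR-3960	549	-117	93	20
HMGA2	0.0	5'UTR	miR-4739	573	-123	87	25
HMGA2	0.0	5'UTR	ID00425.5p-miR	575	-121	88	24
HMGA2	0.0	5'UTR	ID00564.5p-miR	585	-110	90	22
ITGB1	63.6	CDS	ID02187.5p-miR	91	-127	92	23
ITGB1	63.6	CDS	miR-4787-5p	92	-123	92	22
ITGB1	63.6	CDS	ID00457.3p-miR	95	-123	91	22
ITGB1	63.6	CDS	ID02770.5p-miR	98	-117	93	20
ITGB1	63.6	CDS	ID01184.3p-miR	101	-117	93	20
HMGA2	0.0	3'UTR	ID01970.3p-miR	1,255	-113	90	23
HMGA2	0.0	3'UTR	ID00849.3p-miR (2)	1,261 ÷ 1,268	-117	90	22
HMGA2	0.0	3'UTR	ID01545.3p-miR	1,275	-115	95	21
SMAD3		3'UTR	miR-4690-5p	2,066	-115	92	22
SMAD3		3'UTR	ID02822.5p-miR	2,070	-127	91	23
SMAD3		3'UTR	ID00978.5p-miR	2,072	-119	90	22
SMAD3		3'UTR	miR-6089 (2)	2,073 ÷ 2,078	-132 ÷ -136	89 ÷ 91	24
SMAD3		3'UTR	ID01382.3p-miR	2,075	-113	93	20
SMAD3		3'UTR	miR-3620-5p (2)	2,069 ÷ 2,074	-117 ÷ -115	87 ÷ 89	22
SOX4	13.2	3'UTR	ID01839.3p-miR	2,994	-123	89	23
SOX4	13.2	3'UTR	ID01282.3p-miR	3,000	-125	95	23
SOX4	13.2	3'UTR	ID03445.3p-miR	3,000	-127	90	24
SOX4	13.2	3'UTR	ID00101.3p-miR	3,001	-115	92	22
TGFB1	19.5	3'UTR	ID03306.3p-miR	2,060	-123	94	21
TGFB1	19.5	3'UTR	miR-6089 (4)	2,060 ÷ 2,095	-132 ÷ -136	89 ÷ 91	24
TGFB1	19.5	3'UTR	ID01382.3p-miR	2,062	-113	93	20
TGFB1	19.5	3'UTR	miR-3620-5p	2,086	-115	87	22
TGFB1	19.5	3'UTR	ID03208.5p-miR	2,066	-125	88	24
TGFB1	19.5	3'UTR	ID00978.5p-miR	2,089	-119	90	22
TGFB1	19.5	3'UTR	ID00296.3p-miR	2,093	-140	89	25
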