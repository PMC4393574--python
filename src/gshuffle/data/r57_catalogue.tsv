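gene	chromosome	region	position	direction	ref	alt	protein_change	zygosity	sift_score	group_tag
NRG1	IV	CDS	137	.	C	A	P46Q	homo	0.00	.
UBP7	IX	CDS	2466	.	T	A	N822K	homo	0.33	a
ART5	VII	CDS	454	.	C	A	L152I	het	0.17	a
SSA1	I	CDS	91	.	C	A	Q31K	het	0.00	a
GDH1	XV	CDS	47	.	C	T	S16F	het	0.00	b
GDH1	XV	CDS	68	.	T	G	F23C	het	0.00	b
ARO1	IV	CDS	1283	.	C	T	S428F	het	0.00	b
ARO1	IV	CDS	1284	.	C	T	silent	het	.	b
STE5	IV	CDS	512	.	C	T	S171F	het	0.00	b
STE5	IV	CDS	2649	.	T	C	silent	het	.	b
MAL11	VII	CDS	310	.	C	T	P104S	het	0.00	b
MAL11	VII	CDS	482	.	T	A	M161K	het	0.02	b
GSH1	X	UTR5	73	upstream	T	A	.	het	.	c
PBP1	VII	UTR5	191	upstream	T	C	.	het	.	c
FIT3	XV	UTR3	42	downstream	C	T	.	het	.	c
NOP58	XV	UTR3	25	downstream	A	T	.	het	.	c
YNL058C	XIV	CDS	7	.	A	G	K3E	het	0.42	d
DOP1	IV	CDS	40	.	A	T	N14Y	het	0.05	d
TOF2	XI	CDS	2141	.	C	T	S714L	het	0.27	d
SGO1	XV	CDS	575	.	C	A	S192Y	het	0.03	d
BCS1_3prime	IV	intergenic	43	downstream	.	.	.	het	.	.
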