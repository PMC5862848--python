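# Ub-VPS probe-labeling sites identified in HEK 293T cell lysate (curated transcription
# of the published summary table). One row per (protein, site). Flags: high_confidence =
# site detected in more than one biological replicate (printed bold); non_catalytic =
# non-active-site Cys of a DUB (printed starred); catalytic_of_non_dub = catalytic residue
# of a non-DUB protein (printed dagger). Sites are 1-based Cys positions.
protein	class	site	high_confidence	non_catalytic	catalytic_of_non_dub
UBP1	USP	90	1	0	0
UBP3	USP	168	1	0	0
UBP5	USP	219	0	1	0
UBP5	USP	335	1	0	0
UBP5	USP	471	1	1	0
UBP7	USP	90	0	1	0
UBP7	USP	121	0	1	0
UBP7	USP	223	1	0	0
UBP7	USP	315	1	1	0
UBP8	USP	786	1	0	0
UBP8	USP	809	0	1	0
USP9X	USP	1566	1	0	0
UBP10	USP	424	1	0	0
UBP10	USP	436	1	1	0
UBP10	USP	697	0	1	0
UBP12	USP	48	1	0	0
UBP13	USP	345	0	0	0
UBP14	USP	105	0	1	0
UBP14	USP	114	1	0	0
UBP14	USP	122	0	1	0
UBP14	USP	203	1	1	0
UBP14	USP	257	1	1	0
UBP14	USP	359	1	1	0
UBP14	USP	415	0	1	0
UBP15	USP	289	0	1	0
UBP15	USP	298	1	0	0
UBP16	USP	205	1	0	0
UBP19	USP	506	1	0	0
UBP21	USP	221	0	0	0
UBP22	USP	171	1	1	0
UBP22	USP	185	1	0	0
UBP24	USP	1698	1	0	0
UBP25	USP	178	1	0	0
UBP27	USP	87	1	0	0
UBP27	USP	91	1	1	0
UBP28	USP	171	1	0	0
UBP30	USP	77	1	0	0
UBP33	USP	194	1	0	0
UBP34	USP	1903	1	0	0
UBP35	USP	450	1	0	0
UBP36	USP	131	0	0	0
UBP37	USP	350	1	0	0
UBP38	USP	454	1	0	0
UBP40	USP	50	1	0	0
UBP42	USP	120	1	0	0
UBP45	USP	199	1	0	0
UBP47	USP	197	1	0	0
UBP54	USP	42	0	0	0
OTU1	OTU	160	1	0	0
OTU6B	OTU	158	1	0	0
OTU6B	OTU	172	1	1	0
OTU7A	OTU	210	1	0	0
OTUB1	OTU	91	1	0	0
OTUB2	OTU	51	1	0	0
OTUD3	OTU	76	1	0	0
OTUD4	OTU	45	1	0	0
OTUD5	OTU	224	1	0	0
ZRAN1	OTU	443	1	0	0
BAP1	UCH	91	1	0	0
BAP1	UCH	103	0	1	0
UCHL1	UCH	47	1	1	0
UCHL1	UCH	90	1	0	0
UCHL1	UCH	152	1	1	0
UCHL1	UCH	220	1	1	0
UCHL3	UCH	50	1	1	0
UCHL3	UCH	95	1	0	0
UCHL5	UCH	9	1	1	0
UCHL5	UCH	88	1	0	0
UCHL5	UCH	100	1	1	0
ATX3	JOS	14	1	0	0
ATX3	JOS	18	1	1	0
JOS1	JOS	36	1	0	0
JOS2	JOS	24	1	0	0
1433T	Other	134	0	0	0
A6NLJ7	Other	9	0	0	0
ADRM1	Other	357	0	0	0
ALDOA	Other	339	1	0	0
AUP1	Other	391	0	0	0
BOLA2	Other	31	0	0	0
CATB	Other	319	0	0	0
CH60	Other	442	1	0	0
CLIC4	Other	35	0	0	0
DCAF7	Other	256	1	0	0
DDX55	Other	437	1	0	0
DFFA	Other	165	0	0	0
EF1A1	Other	411	1	0	0
EF2	Other	41	0	0	0
EIF3I	Other	76	1	0	0
FETUA	Other	132	1	0	0
HECD1	Other	2579	1	0	0
IF5A1	Other	22	1	0	0
IF5A1	Other	73	0	0	0
IMDH2	Other	331	1	0	0
KLH28	Other	189	0	0	0
KPYM	Other	423	0	0	0
KPYM	Other	424	1	0	0
LDH6A	Other	163	1	0	0
LDHA	Other	35	0	0	0
LDHB	Other	36	0	0	0
LDHB	Other	294	1	0	0
MIF	Other	60	0	0	0
MIF	Other	81	1	0	0
NDK8	Other	94	0	0	0
PAIRB	Other	11	0	0	0
PAL4A	Other	62	1	0	0
PCBP1	Other	54	1	0	0
PPIA	Other	115	1	0	0
PROF1	Other	128	1	0	0
Q5HYB6	Other	154	1	0	0
RCC2	Other	428	1	0	0
RHOA	Other	16	1	0	0
RL10L	Other	105	0	0	0
RL12	Other	141	1	0	0
RL14	Other	42	0	0	0
RL23	Other	28	1	0	0
RL9	Other	134	1	0	0
RS20	Other	70	1	0	0
RS27L	Other	77	1	0	0
RS28	Other	27	1	0	0
RS3	Other	134	0	0	0
RS6	Other	12	0	0	0
RSSA	Other	148	0	0	0
SAP	Other	409	0	0	0
SAP	Other	476	0	0	0
SENP8	Other	163	1	0	1
SERA	Other	369	1	0	0
SPEE	Other	71	1	0	0
SQSTM	Other	113	0	0	0
TBA1A	Other	25	1	0	0
TBA1A	Other	129	1	0	0
TBA1A	Other	295	1	0	0
TBA1A	Other	347	0	0	0
TBA1A	Other	376	1	0	0
TBA1B	Other	347	1	0	0
TBB2A	Other	12	1	0	0
TBB2A	Other	239	1	0	0
TBB2A	Other	303	1	0	0
TBB2A	Other	354	1	0	0
TBB4A	Other	127	0	0	0
TBC15	Other	24	1	0	0
TEBP	Other	40	1	0	0
THIO	Other	32	1	0	0
THIO	Other	35	0	0	0
THIO	Other	73	1	0	0
UBE3C	Other	1051	1	0	1
ZNFX1	Other	1860	1	0	0
ZUFSP	Other	360	1	0	0
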