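strain	phylogroup	species_specific_18mers	strain_specific_18mers	retained
MGB0747	I	1201260	83	0
MGB0761	I	1201306	81	0
L9	I	1186502	0	0
MGYG-HGUT-02388	I	1186506	0	0
NJ	I	1188566	17470	1
347-16	I	1207017	130	0
CACC 566	I	1207087	216	0
Lp02	I	1177634	11840	1
IJH-SONE68	I	1183896	26679	1
IIA	I	1198699	16607	1
10266	I	1172488	25784	1
ZY-1	I	1216121	46665	1
LC355	I	1179984	17903	1
SRCM103299	I	1194448	23021	1
HD1-7	I	1201260	83	0
HDS-01	I	1201306	81	0
MGB0734	singleton	1178026	65524	1
Zhang	II	1143566	8885	0
LOCK919	II	1230630	28394	1
ZFM54	II	1169160	22145	1
TK1501	II	1154098	19871	1
12A	II	1103714	28753	1
8700:2	II	1184388	23564	1
Lpc10	II	1179984	39486	1
MGB0245	III	1184705	50602	1
MGB0625	III	1228586	48092	1
TK-P4A	III	1212483	86180	1
TMW 1.1434	III	1199252	25090	1
IBB3423	III	1250212	38367	1
CBA3611	III	1188329	89	0
LC2W	III	1188152	38	0
AO356	III	1182816	121	0
BL23	III	1199366	427	0
W56	III	1199237	571	0
BD-II	III	1199063	144	0
TCS	III	1199506	244	0
NFFJ04	singleton	1155507	71319	1
NSMJ15	singleton	1060651	77519	1
VKM B-1144	singleton	1100024	73388	1
TD 062	IV	1000877	22825	1
FAM18149	IV	1028072	28405	1
CAUH35	IV	1052575	38375	1
ATCC 334	IV	1143681	38932	1
EG9	IV	1093799	37831	1
N1115	IV	1105817	25748	1
KL1	IV	1165966	20265	1
JCM 8130	IV	1134441	43983	1
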