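strain	species	phylogroup	genus_specific_18mers
MGB0747	paracasei	I	1342841
MGB0761	paracasei	I	1342893
L9	paracasei	I	1326474
MGYG-HGUT-02388	paracasei	I	1326474
NJ	paracasei	I	1335035
347-16	paracasei	I	1354652
CACC 566	paracasei	I	1354718
Lp02	paracasei	I	1307893
IJH-SONE68	paracasei	I	1316002
IIA	paracasei	I	1334702
10266	paracasei	I	1306215
ZY-1	paracasei	I	1354745
LC355	paracasei	I	1311398
SRCM103299	paracasei	I	1333804
HDS-01	paracasei	I	1310186
HD1-7	paracasei	I	1310389
Zhang	paracasei	II	1267650
LOCK919	paracasei	II	1373093
ZFM54	paracasei	II	1310426
TK1501	paracasei	II	1289097
12A	paracasei	II	1301297
8700:2	paracasei	II	1319012
Lpc10	paracasei	II	1345201
MGB0245	paracasei	III	1331017
MGB0625	paracasei	III	1391072
TK-P4A	paracasei	III	1352170
TMW 1.1434	paracasei	III	1323010
IBB3423	paracasei	III	1400224
CBA3611	paracasei	III	1316237
LC2W	paracasei	III	1316047
AO356	paracasei	III	1310307
BL23	paracasei	III	1337551
W56	paracasei	III	1337353
BD-II	paracasei	III	1337137
TCS	paracasei	III	1337717
TD 062	paracasei	IV	1129425
FAM18149	paracasei	IV	1162779
CAUH35	paracasei	IV	1187210
ATCC 334	paracasei	IV	1229640
EG9	paracasei	IV	1243018
N1115	paracasei	IV	1235840
KL1	paracasei	IV	1234653
JCM 8130	paracasei	IV	1286351
MGB0734	paracasei	singleton	1327753
NFFJ04	paracasei	singleton	1287217
VKM B-1144	paracasei	singleton	1274372
NSMJ15	paracasei	singleton	1208720
ATCC 393	casei		1216652
LC5	casei		1398284
CECT 9104	zeae		1326946
LM010	manihotivorans		1381360
4B15	rhamnosus		1357067
GG	rhamnosus		1357107
BIO6870	rhamnosus		1356905
LR-B1	rhamnosus		1357098
WQ2	rhamnosus		1351500
LRB	rhamnosus		1333164
hsryfm 1301	rhamnosus		1352189
DSM 14870	rhamnosus		1346181
IDCC 3201	rhamnosus		1323375
BFE5264	rhamnosus		1338512
1-0320	rhamnosus		1350218
LR5	rhamnosus		1370793
LOCK900	rhamnosus		1332726
Pen	rhamnosus		1329920
BPL5	rhamnosus		1392367
ATCC 8530	rhamnosus		1362386
Lc 705	rhamnosus		1377678
ASCC 290	rhamnosus		1357004
SCT-10-10-60	rhamnosus		1377318
ATCC 11443	rhamnosus		1377473
LOCK908	rhamnosus		1377399
NCTC13764	rhamnosus		1377359
BIO5326	rhamnosus		1377176
NCTC13710	rhamnosus		1377380
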