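symbol	classification	log2fc	fdr	stratum
TRMT9B	DRG	-0.5504	0.0001	cag
SPINK8	DRG	1.1801	0.0000	cag
GCNT4	DRG	-0.4312	0.0004	cag
DYDC2	DRG	-0.8206	0.0003	cag
TNIP3	DRG	-1.7133	0.0000	cag
FAM83H	URG	-0.5040	0.0001	cag
RNF123	URG	-0.4283	0.0000	cag
SPON2	URG	-0.8406	0.0000	cag
ZSCAN1	URG	-0.7667	0.0000	cag
GLB1L2	URG	-0.5157	0.0000	cag
TMEM236	URG	1.5482	0.0000	cag
DHDDS	URG	-0.4200	0.0000	cag
OR3A2	DRG	-0.5151	0.0064	onset_age
PRCD	DRG	-0.4182	0.0025	onset_age
CD177	DRG	1.9313	0.0162	onset_age
VWA7	DRG	-0.7744	0.0001	onset_age
PDZD7	DRG	-0.5045	0.0000	onset_age
NRBP2	DRG	-0.4667	0.0000	onset_age
EPHA10	DRG	-0.6829	0.0000	onset_age
SCN4B	DRG	-0.5889	0.0000	onset_age
CIDEA	DRG	-0.6417	0.0004	onset_age
PLEKHD1	DRG	-0.7914	0.0001	onset_age
CES4A	DRG	-0.6246	0.0000	onset_age
FASN	DRG	-0.4322	0.0000	onset_age
FTH1	DRG	-0.5208	0.0000	onset_age
CORO6	DRG	-0.4891	0.0000	onset_age
MVD	DRG	-0.5133	0.0004	onset_age
MAMDC2	DRG	0.5831	0.0004	onset_age
MTHFD2L	DRG	0.4417	0.0002	onset_age
TRIM17	DRG	-0.4646	0.0000	onset_age
NRG1	DRG	-0.6523	0.0000	onset_age
CEP112	DRG	0.5611	0.0000	onset_age
SYT2	DRG	-1.7452	0.0000	onset_age
STAC2	DRG	-0.5169	0.0000	onset_age
CBLN3	DRG	-1.7130	0.0001	onset_age
VAMP1	DRG	-0.6175	0.0000	onset_age
TP53TG5	DRG	-0.7439	0.0000	onset_age
WNT3	DRG	0.5000	0.0001	onset_age
SCN1B	DRG	-0.5948	0.0000	onset_age
PLA2G4C	DRG	-0.4849	0.0000	onset_age
SEC14L5	DRG	-0.5010	0.0000	onset_age
P2RX6	DRG	-0.5360	0.0000	onset_age
MYO15A	DRG	-0.5266	0.0000	onset_age
RGS11	DRG	-0.4597	0.0001	onset_age
TNIP3	DRG	-1.7133	0.0000	onset_age
MRC1	URG	1.8902	0.0000	onset_age
STUM	URG	-0.8045	0.0000	onset_age
KCNJ12	URG	-0.5354	0.0001	onset_age
TMEM151B	URG	-0.4485	0.0000	onset_age
FAM91A1	URG	0.4735	0.0000	onset_age
TCP11L1	URG	-0.4481	0.0000	onset_age
PDGFD	URG	1.0627	0.0007	onset_age
SHOX2	URG	2.6702	0.0000	onset_age
ABCA1	URG	0.9330	0.0000	onset_age
CA10	URG	-0.6081	0.0000	onset_age
SPHKAP	URG	-0.9092	0.0000	onset_age
SRD5A1	URG	-0.4246	0.0000	onset_age
ARPP19	URG	-0.4803	0.0000	onset_age
FEZF1	URG	1.6361	0.0000	onset_age
SIX1	URG	1.9791	0.0058	onset_age
TWIST1	URG	1.0096	0.0009	onset_age
SLC9A2	URG	0.6608	0.0007	onset_age
GABRR2	URG	1.3858	0.0000	onset_age
SMPD3	URG	-0.4803	0.0000	onset_age
TBX5	URG	2.0175	0.0000	onset_age
PPEF1	URG	-1.1849	0.0000	onset_age
TMEM38A	URG	-0.5346	0.0000	onset_age
ARHGAP10	URG	0.6159	0.0000	onset_age
PITX1	URG	7.0377	0.0000	onset_age
RCN1	URG	0.6193	0.0000	onset_age
NRXN3	URG	-0.5461	0.0000	onset_age
NUDT18	DRG	-0.7345	0.0000	vonsattel
CLEC2L	DRG	-0.7127	0.0000	vonsattel
TIMM23B	DRG	-0.4999	0.0013	vonsattel
IQANK1	DRG	-0.7817	0.0000	vonsattel
SMIM10L2B	DRG	-0.6233	0.0000	vonsattel
KAZN	DRG	-0.4590	0.0000	vonsattel
PDZD7	DRG	-0.5045	0.0000	vonsattel
AHNAK2	DRG	-0.6515	0.0000	vonsattel
NRBP2	DRG	-0.4667	0.0000	vonsattel
EPHA10	DRG	-0.6829	0.0000	vonsattel
NXPH4	DRG	-1.0172	0.0000	vonsattel
SCN4B	DRG	-0.5889	0.0000	vonsattel
CIDEA	DRG	-0.6417	0.0004	vonsattel
PLEKHD1	DRG	-0.7914	0.0001	vonsattel
PHOSPHO1	DRG	-0.5368	0.0008	vonsattel
CES4A	DRG	-0.6246	0.0000	vonsattel
LDLRAD4	DRG	-0.4421	0.0000	vonsattel
HR	DRG	-0.7181	0.0000	vonsattel
CORO6	DRG	-0.4891	0.0000	vonsattel
MVD	DRG	-0.5133	0.0004	vonsattel
NRG1	DRG	-0.6523	0.0000	vonsattel
ZSCAN1	DRG	-0.7667	0.0000	vonsattel
RIT2	DRG	-0.7547	0.0000	vonsattel
TMEM163	DRG	-0.5153	0.0001	vonsattel
PLBD2	DRG	-0.4840	0.0000	vonsattel
PCYOX1L	DRG	-0.6316	0.0001	vonsattel
SYT2	DRG	-1.7452	0.0000	vonsattel
STAC2	DRG	-0.5169	0.0000	vonsattel
VAMP1	DRG	-0.6175	0.0000	vonsattel
KIF12	DRG	-0.8271	0.0000	vonsattel
ANGPTL2	DRG	-0.8151	0.0004	vonsattel
ACP2	DRG	-0.5411	0.0000	vonsattel
KCNC3	DRG	-0.5356	0.0000	vonsattel
ARHGEF2	DRG	-0.4720	0.0000	vonsattel
MECR	DRG	-0.4410	0.0000	vonsattel
SLC30A3	DRG	-0.7125	0.0000	vonsattel
VIPR1	DRG	-0.4111	0.0001	vonsattel
SCN1B	DRG	-0.5948	0.0000	vonsattel
NAPA	DRG	-0.4614	0.0000	vonsattel
NEFM	DRG	-0.6006	0.0000	vonsattel
SEC14L5	DRG	-0.5010	0.0000	vonsattel
NUP93	DRG	-0.4756	0.0000	vonsattel
GSTZ1	DRG	-0.5657	0.0001	vonsattel
P2RX6	DRG	-0.5360	0.0000	vonsattel
MYO15A	DRG	-0.5266	0.0000	vonsattel
ADAM11	DRG	-0.5504	0.0000	vonsattel
F7	DRG	-0.8341	0.0000	vonsattel
SLC5A3	URG	0.8459	0.0000	vonsattel
HMGN5	URG	0.5588	0.0002	vonsattel
TOPORS	URG	0.4285	0.0001	vonsattel
PTAR1	URG	0.6316	0.0000	vonsattel
PLEKHF2	URG	0.6301	0.0000	vonsattel
GPR171	URG	1.8061	0.0000	vonsattel
SLFN11	URG	1.0408	0.0000	vonsattel
BCL2	URG	0.5718	0.0000	vonsattel
ARHGAP42	URG	0.7404	0.0000	vonsattel
STOX1	URG	0.5138	0.0000	vonsattel
RHOBTB3	URG	0.7695	0.0000	vonsattel
RANBP3L	URG	1.2461	0.0000	vonsattel
PPP4R2	URG	0.4286	0.0000	vonsattel
GRAMD2B	URG	0.8249	0.0000	vonsattel
GABPA	URG	0.4045	0.0002	vonsattel
BCL2L11	URG	0.5653	0.0002	vonsattel
GXYLT1	URG	0.4231	0.0002	vonsattel
PARD3	URG	0.9958	0.0000	vonsattel
SLC39A12	URG	1.1799	0.0000	vonsattel
G3BP1	URG	0.4533	0.0000	vonsattel
USP53	URG	0.8390	0.0000	vonsattel
YAP1	URG	1.1163	0.0000	vonsattel
SLC38A2	URG	0.8775	0.0000	vonsattel
MAP7D3	URG	0.5214	0.0019	vonsattel
FEZF1	URG	1.6361	0.0000	vonsattel
GNA13	URG	0.7054	0.0000	vonsattel
UPK1B	URG	2.6019	0.0000	vonsattel
GMNN	URG	0.7335	0.0001	vonsattel
GABRR2	URG	1.3858	0.0000	vonsattel
DSE	URG	0.9154	0.0000	vonsattel
ITGB8	URG	0.6760	0.0000	vonsattel
ATP11C	URG	0.6688	0.0000	vonsattel
EZR	URG	0.7495	0.0000	vonsattel
TGFBR3	URG	1.1844	0.0000	vonsattel
LAPTM4A	URG	0.5393	0.0000	vonsattel
IL17RB	URG	1.1067	0.0000	vonsattel
RCN1	URG	0.6193	0.0000	vonsattel
MRC1	DRG	1.8902	0.0000	lifespan
STUM	DRG	-0.8045	0.0000	lifespan
GAS1	DRG	1.0313	0.0001	lifespan
NPAS4	DRG	-2.8925	0.0049	lifespan
SPTLC3	DRG	1.9498	0.0001	lifespan
S100P	DRG	2.4416	0.0000	lifespan
SLC16A12	DRG	3.0162	0.0000	lifespan
OSR1	DRG	1.3507	0.0036	lifespan
STRA6	DRG	1.3572	0.0138	lifespan
CEMIP	DRG	0.7861	0.0000	lifespan
FCGR2B	DRG	2.3809	0.0000	lifespan
PKP2	DRG	1.0042	0.0001	lifespan
MARCO	DRG	2.1951	0.0000	lifespan
TMEM163	URG	-0.5153	0.0001	lifespan
ANGPT2	URG	1.4528	0.0000	lifespan
RIPOR3	URG	1.2127	0.0000	lifespan
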