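protein	locus_id	tsc1	tsc2	tsc3	status	ubiquitinated_forms	shrna_stabilized	mln4924	degron	note
HIVEP1/2	P15822/P31629	13	0	69	novel	yes	untested	stable	DSGESEEE	aggregates two loci
Nrf2	Q16236	18	8	9	known	untested	untested	untested
CReP	Q5SWA1	12	11	13	novel	yes	partial	yes	DDGFDSD
UBE4B	O95155	17	5	23	novel	yes	stable	stable	DTTFLLD
ATF-4	P18848	11	9	19	known	untested	untested	untested
CDC25A	P30304	11	7	14	known	untested	untested	untested
ZNF395	Q9H8N7	9	6	11	novel	yes	untested	yes	DSGSSTTS
ZNF704	Q6ZNC4	7	3	9	novel	yes	partial	partial	DDGIDEAE/SDGEED
PDCD4	Q53EL6	5	4	4	known	untested	untested	untested
bHLHE40	O14503	5	2	14	known	yes	untested	stable
CDC25B	P30305	3	2	10	known	untested	untested	untested
BAT2	P48634	2	3	6	novel	no	untested	untested	DSGGSSSE/DSGVDLS/DSGHCVPE
Deptor	Q8TB45	3	2	7	known	untested	untested	untested
SUN2	Q9UH99	3	3	0	novel	yes	untested	yes	DDGSSSS
AEBP2	Q6ZN18	1	2	6	novel	yes	partial	partial	SDGEPLS
RAPGEF2	Q9Y4G8	3	0	5	known	untested	untested	untested
GGNBP2	Q9H3C7	2	1	3	novel	untested	untested	untested	DSGKGAKS
TFAP4	Q01664	3	0	3	known	yes	untested	yes
Emi1	Q9UKT4	1	2	0	known	untested	untested	untested
Per2	O15055	2	0	3	known	untested	untested	untested
ALDH2	P05091	1	0	6	novel	no	untested	untested	DGDFFSYT
WWTR1	Q9GZV5	2	0	2	known	untested	untested	untested
TRIM9	Q9C026	1	1	2	novel	yes	untested	stable	DSGYGS
CEP44	Q9C0F1	1	1	0	novel	no	untested	untested	SSGKSE
DACT1	Q9NYF0	1	1	0	novel	untested	untested	untested	SSGFYELS
FNIP1	Q8TF40	1	1	0	novel	yes	untested	no	DSGIARS
RIPK4	P57078	1	0	3	novel	yes	untested	untested	DSGAS
RASSF3	Q86WH2	0	1	2	novel	yes	no	no	SSGYSS
NFκB p100	Q00653	1	0	11	below_bar
β-catenin	P35222	33	18	36	below_bar
eEF2K	O00418	0	0	6	below_bar
REST	Q13127	0	0	12	below_bar
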