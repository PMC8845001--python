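id	parent_id	label	aliases
brca1		BRCA1
brca2		BRCA2	fancd1
tp53		TP53	p53
pten		PTEN
stk11		STK11	lkb1
cdh1		CDH1	e-cadherin
palb2		PALB2	fancn
atm		ATM
chek2		CHEK2	chk2
bard1		BARD1
brip1		BRIP1	fancj
rad51c		RAD51C	fanco
rad51d		RAD51D
rad50		RAD50
mre11		MRE11	mre11a
nbn		NBN	nibrin
nf1		NF1
nf2		NF2
cdkn2a		CDKN2A	p16
cdk4		CDK4
mlh1		MLH1
msh2		MSH2
msh6		MSH6
pms2		PMS2
pms1		PMS1
mlh3		MLH3
epcam		EPCAM	tacstd1
apc		APC
mutyh		MUTYH	myh
bmpr1a		BMPR1A
smad4		SMAD4	dpc4
pole		POLE
pold1		POLD1
grem1		GREM1
axin2		AXIN2
nthl1		NTHL1
msh3		MSH3
rnf43		RNF43
rps20		RPS20
ctnna1		CTNNA1
vhl		VHL
met		MET
flcn		FLCN
fh		FH
sdha		SDHA
sdhb		SDHB
sdhc		SDHC
sdhd		SDHD
sdhaf2		SDHAF2
tmem127		TMEM127
max		MAX
ret		RET
men1		MEN1
cdc73		CDC73	hrpt2
prkar1a		PRKAR1A
tsc1		TSC1
tsc2		TSC2
wt1		WT1
rb1		RB1
dicer1		DICER1
smarca4		SMARCA4	brg1
smarcb1		SMARCB1	ini1
smarce1		SMARCE1
sufu		SUFU
ptch1		PTCH1
ptch2		PTCH2
bap1		BAP1
mitf		MITF
tert		TERT
pot1		POT1
acd		ACD	tpp1
terf2ip		TERF2IP	rap1
cdkn1b		CDKN1B	p27
cdkn1c		CDKN1C	p57
aip		AIP
gpc3		GPC3
phox2b		PHOX2B
alk		ALK
kif1b		KIF1B
runx1		RUNX1
cebpa		CEBPA
gata2		GATA2
ddx41		DDX41
etv6		ETV6
ankrd26		ANKRD26
srp72		SRP72
terc		TERC
samd9		SAMD9
samd9l		SAMD9L
mpl		MPL
elane		ELANE
hax1		HAX1
sbds		SBDS
was		WAS
blm		BLM	recql3
wrn		WRN	recql2
recql4		RECQL4
recql		RECQL
dkc1		DKC1
tinf2		TINF2
nhp2		NHP2
nop10		NOP10
fanca		FANCA
fancb		FANCB
fancc		FANCC
fancd2		FANCD2
fance		FANCE
fancf		FANCF
fancg		FANCG
fanci		FANCI
fancl		FANCL
fancm		FANCM
slx4		SLX4	fancp
ercc4		ERCC4	fancq
xpa		XPA
xpc		XPC
ercc2		ERCC2	xpd
ercc3		ERCC3	xpb
ercc5		ERCC5	xpg
ddb2		DDB2	xpe
polh		POLH	xpv
mc1r		MC1R
hoxb13		HOXB13
ar		AR
kit		KIT
pdgfra		PDGFRA
ntrk1		NTRK1
egfr		EGFR
abraxas1		ABRAXAS1	fam175a
xrcc2		XRCC2
rad51b		RAD51B
gen1		GEN1
bub1b		BUB1B
trip13		TRIP13
dis3l2		DIS3L2
hras		HRAS
ctc1		CTC1
rtel1		RTEL1
parn		PARN
stn1		STN1
wrap53		WRAP53
mbd4		MBD4
atr		ATR
chek1		CHEK1	chk1
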