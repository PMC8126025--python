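# Curated subcellular membrane marker proteins (gene symbols / AGIs),
# one compartment per protein. source column cites the curated marker table
# of origin (t1-t6). NDC1 is excluded: it is dual-localized (chloroplast and
# mitochondria) and marker entries must carry a unique compartment.
protein_id	compartment	source
VHA-A	TP	t2
VHA-B2	TP	t2
VHA-C	TP	t2
VHA-D	TP	t2
VHA-E3	TP	t2
VHA-F	TP	t2
VHA-G1	TP	t2
VHA-H	TP	t2
VHA-a3	TP	t2
VHA-c2	TP	t2
VHA-d2	TP	t2
AVP1	TP	t2
TIP2-1	TP	t2
TIP1-1	TP	t2
TPC1	TP	t2
CLC-B	TP	t2
CLC-C	TP	t2
KCR1	ER	t1
CYTB5-B	ER	t1
CRT1	ER	t3
STL2P	ER	t3
OST1B	ER	t3
At2g21160	ER	t3
BIP2	ER	t3
ARF1	GA	t3
At1g62020	GA	t3
At4g31480	GA	t3
At1g52360	GA	t3
At4g34450	GA	t3
At3g07100	GA	t3
APY2	GA	t3
GAUT1	GA	t3
GAUT9	GA	t3
At1g04430	GA	t3
At1g60070	TGN	t3
CHC1	TGN	t3
TIC55	Chl-envelope	t4
TIC110	Chl-envelope	t4
TOC34	Chl-envelope	t4
At4g02530	TLK	t4
ATPC1	TLK	t4
ATPD	TLK	t4
LHCB1.3	TLK	t4
LHCA1	TLK	t4
PSAD2	TLK	t4
PSAF	TLK	t4
PSAH2	TLK	t4
PSAL	TLK	t4
PSAK	TLK	t4
HCF136	TLK	t4
PSBR	TLK	t4
VDAC1	MT	t5
VDAC2	MT	t5
VDAC4	MT	t5
TOM9-2	MT	t5
PHB2	MT	t5
PHB3	MT	t5
At5g08680	MT	t5
UCR1-1	MT	t5
COX5B-2	MT	t5
MPPbeta	MT	t5
BOU	MT	t5
MPT3	MT	t5
DTC	MT	t5
AHA2	PM	t6
AHA4	PM	t6
AHA5	PM	t6
mipA	PM	t6
mipD	PM	t6
mipH	PM	t6
PIP2-5	PM	t6
PIP2-8	PM	t6
ERD4	PM	t6
SUC2	PM	t6
PLT5	PM	t6
FLA2	PM	t6
FLA6	PM	t6
At4g27520	PM	t6
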