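# Restriction enzyme panel (REBASE). recognition: IUPAC, read 5'->3' on the top strand.
# cut_top / cut_bottom: cleavage offsets in top-strand coordinates, measured in bases
# from the first base of the recognition site; offsets may fall outside the site for
# Type IIS enzymes (BbsI, BsrI).
name	recognition	cut_top	cut_bottom
AccI	GTMKAC	2	4
AluI	AGCT	2	2
ApeKI	GCWGC	1	4
AvaI	CYCGRG	1	5
BamHI	GGATCC	1	5
BbsI	GAAGAC	8	12
BsrI	ACTGG	6	4
Bsu36I	CCTNAGG	2	5
DpnI	GATC	2	2
EcoNI	CCTNNNNNAGG	5	6
EcoRI	GAATTC	1	5
HindIII	AAGCTT	1	5
MluI	ACGCGT	1	5
MspI	CCGG	1	3
NdeI	CATATG	2	4
NruI	TCGCGA	3	3
PstI	CTGCAG	5	1
SacI	GAGCTC	5	1
SalI	GTCGAC	1	5
SpeI	ACTAGT	1	5
XbaI	TCTAGA	1	5
XhoI	CTCGAG	1	5
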