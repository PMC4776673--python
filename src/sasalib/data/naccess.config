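# NACCESS-compatible radius subset on the same atom typing

types:
C3H0 1.76 apolar
C3H1 1.76 apolar
C4H1 1.87 apolar
C4H2 1.87 apolar
C4H3 1.87 apolar
N3H0 1.65 polar
N3H1 1.65 polar
N3H2 1.65 polar
N4H3 1.50 polar
O1H0 1.40 polar
O2H0 1.40 polar
O2H1 1.40 polar
O2H2 1.40 polar
P4 1.80 polar
S2H0 1.85 polar
S2H1 1.85 polar
SE2 1.90 polar

atoms:
ALA N N3H1
ALA CA C4H1
ALA C C3H0
ALA O O1H0
ALA OXT O1H0
ALA CB C4H3

ARG N N3H1
ARG CA C4H1
ARG C C3H0
ARG O O1H0
ARG OXT O1H0
ARG CB C4H2
ARG CG C4H2
ARG CD C4H2
ARG NE N3H1
ARG CZ C3H0
ARG NH1 N3H2
ARG NH2 N3H2

ASN N N3H1
ASN CA C4H1
ASN C C3H0
ASN O O1H0
ASN OXT O1H0
ASN CB C4H2
ASN CG C3H0
ASN OD1 O1H0
ASN ND2 N3H2

ASP N N3H1
ASP CA C4H1
ASP C C3H0
ASP O O1H0
ASP OXT O1H0
ASP CB C4H2
ASP CG C3H0
ASP OD1 O1H0
ASP OD2 O1H0

CYS N N3H1
CYS CA C4H1
CYS C C3H0
CYS O O1H0
CYS OXT O1H0
CYS CB C4H2
CYS SG S2H1

GLN N N3H1
GLN CA C4H1
GLN C C3H0
GLN O O1H0
GLN OXT O1H0
GLN CB C4H2
GLN CG C4H2
GLN CD C3H0
GLN OE1 O1H0
GLN NE2 N3H2

GLU N N3H1
GLU CA C4H1
GLU C C3H0
GLU O O1H0
GLU OXT O1H0
GLU CB C4H2
GLU CG C4H2
GLU CD C3H0
GLU OE1 O1H0
GLU OE2 O1H0

GLY N N3H1
GLY CA C4H2
GLY C C3H0
GLY O O1H0
GLY OXT O1H0

HIS N N3H1
HIS CA C4H1
HIS C C3H0
HIS O O1H0
HIS OXT O1H0
HIS CB C4H2
HIS CG C3H0
HIS ND1 N3H1
HIS CD2 C3H1
HIS CE1 C3H1
HIS NE2 N3H1

ILE N N3H1
ILE CA C4H1
ILE C C3H0
ILE O O1H0
ILE OXT O1H0
ILE CB C4H1
ILE CG1 C4H2
ILE CG2 C4H3
ILE CD1 C4H3

LEU N N3H1
LEU CA C4H1
LEU C C3H0
LEU O O1H0
LEU OXT O1H0
LEU CB C4H2
LEU CG C4H1
LEU CD1 C4H3
LEU CD2 C4H3

LYS N N3H1
LYS CA C4H1
LYS C C3H0
LYS O O1H0
LYS OXT O1H0
LYS CB C4H2
LYS CG C4H2
LYS CD C4H2
LYS CE C4H2
LYS NZ N4H3

MET N N3H1
MET CA C4H1
MET C C3H0
MET O O1H0
MET OXT O1H0
MET CB C4H2
MET CG C4H2
MET SD S2H0
MET CE C4H3

PHE N N3H1
PHE CA C4H1
PHE C C3H0
PHE O O1H0
PHE OXT O1H0
PHE CB C4H2
PHE CG C3H0
PHE CD1 C3H1
PHE CD2 C3H1
PHE CE1 C3H1
PHE CE2 C3H1
PHE CZ C3H1

PRO N N3H0
PRO CA C4H1
PRO C C3H0
PRO O O1H0
PRO OXT O1H0
PRO CB C4H2
PRO CG C4H2
PRO CD C4H2

SER N N3H1
SER CA C4H1
SER C C3H0
SER O O1H0
SER OXT O1H0
SER CB C4H2
SER OG O2H1

THR N N3H1
THR CA C4H1
THR C C3H0
THR O O1H0
THR OXT O1H0
THR CB C4H1
THR OG1 O2H1
THR CG2 C4H3

TRP N N3H1
TRP CA C4H1
TRP C C3H0
TRP O O1H0
TRP OXT O1H0
TRP CB C4H2
TRP CG C3H0
TRP CD1 C3H1
TRP CD2 C3H0
TRP NE1 N3H1
TRP CE2 C3H0
TRP CE3 C3H1
TRP CZ2 C3H1
TRP CZ3 C3H1
TRP CH2 C3H1

TYR N N3H1
TYR CA C4H1
TYR C C3H0
TYR O O1H0
TYR OXT O1H0
TYR CB C4H2
TYR CG C3H0
TYR CD1 C3H1
TYR CD2 C3H1
TYR CE1 C3H1
TYR CE2 C3H1
TYR CZ C3H0
TYR OH O2H1

VAL N N3H1
VAL CA C4H1
VAL C C3H0
VAL O O1H0
VAL OXT O1H0
VAL CB C4H1
VAL CG1 C4H3
VAL CG2 C4H3

SEC N N3H1
SEC CA C4H1
SEC C C3H0
SEC O O1H0
SEC OXT O1H0
SEC CB C4H2
SEC SE SE2

PYL N N3H1
PYL CA C4H1
PYL C C3H0
PYL O O1H0
PYL OXT O1H0
PYL CB C4H2
PYL CG C4H2
PYL CD C4H2
PYL CE C4H2
PYL NZ N3H1
PYL C2 C3H0
PYL O2 O1H0
PYL CA2 C4H1
PYL CB2 C4H1
PYL CG2 C4H3
PYL CD2 C4H2
PYL CE2 C3H1
PYL N2 N3H0

MSE N N3H1
MSE CA C4H1
MSE C C3H0
MSE O O1H0
MSE OXT O1H0
MSE CB C4H2
MSE CG C4H2
MSE SE SE2
MSE CE C4H3

A P P4
A OP1 O1H0
A OP2 O1H0
A OP3 O1H0
A O5' O2H0
A C5' C4H2
A C4' C4H1
A O4' O2H0
A C3' C4H1
A O3' O2H0
A C2' C4H1
A O2' O2H1
A C1' C4H1
A N9 N3H0
A C8 C3H1
A N7 N3H0
A C5 C3H0
A C6 C3H0
A N6 N3H2
A N1 N3H0
A C2 C3H1
A N3 N3H0
A C4 C3H0

G P P4
G OP1 O1H0
G OP2 O1H0
G OP3 O1H0
G O5' O2H0
G C5' C4H2
G C4' C4H1
G O4' O2H0
G C3' C4H1
G O3' O2H0
G C2' C4H1
G O2' O2H1
G C1' C4H1
G N9 N3H0
G C8 C3H1
G N7 N3H0
G C5 C3H0
G C6 C3H0
G O6 O1H0
G N1 N3H1
G C2 C3H0
G N2 N3H2
G N3 N3H0
G C4 C3H0

C P P4
C OP1 O1H0
C OP2 O1H0
C OP3 O1H0
C O5' O2H0
C C5' C4H2
C C4' C4H1
C O4' O2H0
C C3' C4H1
C O3' O2H0
C C2' C4H1
C O2' O2H1
C C1' C4H1
C N1 N3H0
C C2 C3H0
C O2 O1H0
C N3 N3H0
C C4 C3H0
C N4 N3H2
C C5 C3H1
C C6 C3H1

U P P4
U OP1 O1H0
U OP2 O1H0
U OP3 O1H0
U O5' O2H0
U C5' C4H2
U C4' C4H1
U O4' O2H0
U C3' C4H1
U O3' O2H0
U C2' C4H1
U O2' O2H1
U C1' C4H1
U N1 N3H0
U C2 C3H0
U O2 O1H0
U N3 N3H1
U C4 C3H0
U O4 O1H0
U C5 C3H1
U C6 C3H1

DA P P4
DA OP1 O1H0
DA OP2 O1H0
DA OP3 O1H0
DA O5' O2H0
DA C5' C4H2
DA C4' C4H1
DA O4' O2H0
DA C3' C4H1
DA O3' O2H0
DA C2' C4H2
DA C1' C4H1
DA N9 N3H0
DA C8 C3H1
DA N7 N3H0
DA C5 C3H0
DA C6 C3H0
DA N6 N3H2
DA N1 N3H0
DA C2 C3H1
DA N3 N3H0
DA C4 C3H0

DG P P4
DG OP1 O1H0
DG OP2 O1H0
DG OP3 O1H0
DG O5' O2H0
DG C5' C4H2
DG C4' C4H1
DG O4' O2H0
DG C3' C4H1
DG O3' O2H0
DG C2' C4H2
DG C1' C4H1
DG N9 N3H0
DG C8 C3H1
DG N7 N3H0
DG C5 C3H0
DG C6 C3H0
DG O6 O1H0
DG N1 N3H1
DG C2 C3H0
DG N2 N3H2
DG N3 N3H0
DG C4 C3H0

DC P P4
DC OP1 O1H0
DC OP2 O1H0
DC OP3 O1H0
DC O5' O2H0
DC C5' C4H2
DC C4' C4H1
DC O4' O2H0
DC C3' C4H1
DC O3' O2H0
DC C2' C4H2
DC C1' C4H1
DC N1 N3H0
DC C2 C3H0
DC O2 O1H0
DC N3 N3H0
DC C4 C3H0
DC N4 N3H2
DC C5 C3H1
DC C6 C3H1

DT P P4
DT OP1 O1H0
DT OP2 O1H0
DT OP3 O1H0
DT O5' O2H0
DT C5' C4H2
DT C4' C4H1
DT O4' O2H0
DT C3' C4H1
DT O3' O2H0
DT C2' C4H2
DT C1' C4H1
DT N1 N3H0
DT C2 C3H0
DT O2 O1H0
DT N3 N3H1
DT C4 C3H0
DT O4 O1H0
DT C5 C3H0
DT C7 C4H3
DT C5M C4H3
DT C6 C3H1

DU P P4
DU OP1 O1H0
DU OP2 O1H0
DU OP3 O1H0
DU O5' O2H0
DU C5' C4H2
DU C4' C4H1
DU O4' O2H0
DU C3' C4H1
DU O3' O2H0
DU C2' C4H2
DU C1' C4H1
DU N1 N3H0
DU C2 C3H0
DU O2 O1H0
DU N3 N3H1
DU C4 C3H0
DU O4 O1H0
DU C5 C3H1
DU C6 C3H1

ACE C C3H0
ACE O O1H0
ACE CH3 C4H3

NH2 N N3H2

HOH O O2H2
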