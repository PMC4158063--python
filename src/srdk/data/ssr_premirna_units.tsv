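unit	unit_class	count
A	mono	1
G	mono	1
T	mono	5
AC	di	2
AG	di	5
AT	di	2
CT	di	3
GA	di	7
GT	di	1
TA	di	12
TC	di	3
AAG	tri	1
ACA	tri	1
ATA	tri	1
ATT	tri	3
CAG	tri	1
CTT	tri	7
GAT	tri	2
GTG	tri	1
TAA	tri	5
TCA	tri	1
TGC	tri	1
TGG	tri	2
TTC	tri	5
CATG	tetra	1
TCAT	tetra	1
TGCA	tetra	1
TTAA	tetra	2
TTCT	tetra	4
TTTG	tetra	1
TATAAT	hexa	2
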