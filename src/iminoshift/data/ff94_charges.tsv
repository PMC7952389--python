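residue	atom	charge
A	P	1.1662
A	OP1	-0.7760
A	OP2	-0.7760
A	O5'	-0.4989
A	C5'	0.0558
A	H5'	0.0679
A	H5''	0.0679
A	C4'	0.1065
A	H4'	0.1174
A	O4'	-0.3548
A	C1'	0.0394
A	H1'	0.2007
A	C3'	0.2022
A	H3'	0.0615
A	O3'	-0.5246
A	C2'	0.0670
A	H2'	0.0972
A	O2'	-0.6139
A	HO2'	0.4186
A	N9	-0.0251
A	C8	0.2006
A	H8	0.1553
A	N7	-0.6073
A	C5	0.0515
A	C6	0.7009
A	N6	-0.9019
A	H61	0.4115
A	H62	0.4115
A	N1	-0.7615
A	C2	0.5875
A	H2	0.0473
A	N3	-0.6997
A	C4	0.3053
G	P	1.1662
G	OP1	-0.7760
G	OP2	-0.7760
G	O5'	-0.4989
G	C5'	0.0558
G	H5'	0.0679
G	H5''	0.0679
G	C4'	0.1065
G	H4'	0.1174
G	O4'	-0.3548
G	C1'	0.0191
G	H1'	0.2006
G	C3'	0.2022
G	H3'	0.0615
G	O3'	-0.5246
G	C2'	0.0670
G	H2'	0.0972
G	O2'	-0.6139
G	HO2'	0.4186
G	N9	0.0492
G	C8	0.1374
G	H8	0.1640
G	N7	-0.5709
G	C5	0.1744
G	C6	0.4770
G	O6	-0.5597
G	N1	-0.4787
G	H1	0.3424
G	C2	0.7657
G	N2	-0.9672
G	H21	0.4364
G	H22	0.4364
G	N3	-0.6323
G	C4	0.1222
C	P	1.1662
C	OP1	-0.7760
C	OP2	-0.7760
C	O5'	-0.4989
C	C5'	0.0558
C	H5'	0.0679
C	H5''	0.0679
C	C4'	0.1065
C	H4'	0.1174
C	O4'	-0.3548
C	C1'	0.0066
C	H1'	0.2029
C	C3'	0.2022
C	H3'	0.0615
C	O3'	-0.5246
C	C2'	0.0670
C	H2'	0.0972
C	O2'	-0.6139
C	HO2'	0.4186
C	N1	-0.0484
C	C6	0.0053
C	H6	0.1958
C	C5	-0.5215
C	H5	0.1928
C	C4	0.8185
C	N4	-0.9530
C	H41	0.4234
C	H42	0.4234
C	N3	-0.7584
C	C2	0.7538
C	O2	-0.6252
U	P	1.1662
U	OP1	-0.7760
U	OP2	-0.7760
U	O5'	-0.4989
U	C5'	0.0558
U	H5'	0.0679
U	H5''	0.0679
U	C4'	0.1065
U	H4'	0.1174
U	O4'	-0.3548
U	C1'	0.0674
U	H1'	0.1824
U	C3'	0.2022
U	H3'	0.0615
U	O3'	-0.5246
U	C2'	0.0670
U	H2'	0.0972
U	O2'	-0.6139
U	HO2'	0.4186
U	N1	0.0418
U	C6	-0.1126
U	H6	0.2188
U	C5	-0.3635
U	H5	0.1811
U	C4	0.5952
U	O4	-0.5761
U	N3	-0.3549
U	H3	0.3154
U	C2	0.4687
U	O2	-0.5477
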