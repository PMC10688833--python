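cluster	n_phages	n_subclusters
A	256	19
B	63	12
C	31	2
D	5	2
E	25	0
F	157	5
G	18	5
H	6	2
I	6	2
J	11	0
K	66	7
L	22	4
M	7	2
N	19	0
O	5	0
P	24	6
Q	1	0
R	2	0
S	2	0
T	2	0
U	1	0
V	1	0
X	1	0
Y	2	0
Z	2	0
AA	1	0
AB	2	0
AC	3	0
AD	1	0
Singletons	6	n/a
Unknown	3	n/a
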