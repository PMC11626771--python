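# metalgeom common oxidation states, version 1
# One row per metal element; states are the common positive oxidation states
# in ascending order, comma-separated (curated from standard inorganic
# chemistry references).
# element	states
Li	1
Be	2
Na	1
Mg	2
Al	3
K	1
Ca	2
Sc	3
Ti	3,4
V	2,3,4,5
Cr	2,3,6
Mn	2,3,4,7
Fe	2,3
Co	2,3
Ni	2
Cu	1,2
Zn	2
Ga	3
Rb	1
Sr	2
Y	3
Zr	4
Nb	5
Mo	2,4,6
Tc	4,7
Ru	2,3,4
Rh	1,3
Pd	2,4
Ag	1
Cd	2
In	3
Sn	2,4
Sb	3,5
Cs	1
Ba	2
La	3
Ce	3,4
Pr	3
Nd	3
Pm	3
Sm	2,3
Eu	2,3
Gd	3
Tb	3
Dy	3
Ho	3
Er	3
Tm	3
Yb	2,3
Lu	3
Hf	4
Ta	5
W	4,6
Re	3,4,7
Os	2,3,4,8
Ir	1,3,4
Pt	2,4
Au	1,3
Hg	1,2
Tl	1,3
Pb	2,4
Bi	3,5
Po	2,4
Fr	1
Ra	2
Ac	3
Th	4
Pa	5
U	4,6
Np	5
Pu	4
Am	3
Cm	3
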