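# Per-residue protein-interaction propensities used for the Boman index:
# water->cyclohexane transfer free energies (kcal/mol), sign oriented so that
# HIGH values mean the residue favors protein (aqueous) over lipid contact.
# Proline has no experimental value in this series and is set to 0.0.
residue	value
L	-4.92
I	-4.92
V	-4.04
F	-2.98
M	-2.35
W	-2.33
A	-1.81
C	-1.28
G	-0.94
Y	-0.14
P	0.00
T	2.57
S	3.40
H	4.66
Q	5.54
K	5.55
N	6.64
E	6.81
D	8.72
R	14.92
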