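# SYNTHETIC per-residue Hsp70 substrate-affinity scale.
# The experimentally derived per-residue values from peptide-library scans are
# not redistributable here; this stand-in preserves only the qualitative
# orientation of the published data (Hsp70 binding cores favor large
# aliphatic/aromatic residues and basic residues at flanks, and are strongly
# disfavored by acidic residues). HIGH value = contributes to a predicted
# Hsp70 binding site. Replace with transcribed experimental values for any
# quantitative use.
residue	affinity
L	2.0
I	1.8
V	1.4
F	1.6
Y	1.2
W	1.0
M	1.0
A	0.5
R	0.8
K	0.6
H	0.3
G	0.0
S	0.0
T	0.0
C	0.2
N	-0.3
Q	-0.3
P	-0.5
D	-2.0
E	-2.0
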