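# Pharmacophore feature perception rules, v1.
# Columns: ftype <TAB> pattern <TAB> placement
#   ftype      one of A D H N P R
#   pattern    SMARTS, or the procedural tokens <ring> / <cluster>
#   placement  atom     -> feature at first matched atom
#              centroid -> feature at centroid of all matched atoms
#              ring     -> aromatic-ring centroid + normal (pattern ignored)
#              cluster  -> connected apolar-carbon/halogen clusters, size>=2
# Defaults (editable):
#   A  N/O atoms bearing a lone pair and no positive charge; amide/aniline N excluded
#   D  N/O with at least one bound hydrogen (charged donors included)
#   P  positively charged nitrogen (protonated amine/amidinium/guanidinium/pyridinium)
#   N  carboxylate / sulfonate-sulfate / phosphate anionic groups, at group centroid
#   H  maximal connected clusters of apolar carbons (+ halogens), centroid
#   R  aromatic rings by aromaticity perception, centroid + ring normal
A	[OX1,OX2;!+]	atom
A	[N;X1,X2;!+;!$([N]=[N+]);!$([N-])]	atom
A	[n;X2;!+]	atom
A	[NX3;!+;!$([NX3][#6X3]);!$([NX3][a])]	atom
D	[#7,#8;!H0;!-]	atom
P	[#7;+;!$([N+]~[O-])]	atom
N	[CX3](=[OX1])[OX1-]	centroid
N	[SX4](=[OX1])(=[OX1])[OX1-]	centroid
N	[PX4](=[OX1])([OX1-])	centroid
R	<ring>	ring
H	<cluster>	cluster
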