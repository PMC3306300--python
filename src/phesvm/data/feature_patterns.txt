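# phesvm ligand feature patterns
# one pattern per line: <label> <kind> <SMARTS>
# kind is HBD, HBA or HP; the feature position is the centroid of the
# matched atoms.  Lines starting with '#' are comments.
#
# Hydrophobe ring / aliphatic-cluster detection is procedural (see
# phesvm.features) because maximal connected carbon groups are not
# expressible as a single SMARTS; only the halogenated-carbon hydrophobe
# lives here.
donor_NOS        HBD  [#7,#8,#16;!H0]
acceptor_N_arom  HBA  [nX2]
acceptor_N       HBA  [N;X1,X2,X3;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3]a);!$([NX3][SX4](=O)=O);!$([N+])]
acceptor_O       HBA  [$([OX2;!$([OX2][NX3]=[OX1])]),$([OX1;!$([OX1]~[NX3])])]
hp_halocarbon    HP   [#6;$([#6][F,Cl,Br,I])]
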