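group,mhc_residue,mhc_atom,tcr_loop,tcr_residue,tcr_atom,in_crystal,persistence_A,persistence_B
alpha1,Arg62,Nη1/2,CDR2β,Asp56,Oδ1/2,No,54,
alpha1,Gln65,Nε2,CDR2β,Ser51,Oγ,No,,10
alpha1,Gln65,Nε2,CDR2β,Glu52,Oε1/2,No,,27
alpha1,Gln65,Oε1,CDR3α,Asn97,Nδ2,Yes,23,5
alpha1,Gln65,Oε1,CDR2β,Glu52,N,No,7,
alpha1,Lys68,Nζ,CDR2β,Glu52,Oε1/2,No,48,39
alpha2,Arg151,Nη1/2,CDR2α,Asp53,Oδ1/2,No,46,
alpha2,Arg151,Nη1/2,CDR2α,Glu57,Oε1/2,No,,36
alpha2,Glu154,Oε1,CDR2α,Arg48,Nη2,No,,7
alpha2,Glu154,Oε1,CDR2α,Asn50,Nδ2,No,15,9
alpha2,Glu154,Oε2,CDR2α,Asn50,Nδ2,Yes,14,6
alpha2,Gln155,Nε2,CDR3α,Phe95,O,Yes,3,1
alpha2,Gln155,O,CDR3α,Tyr96,Oη,No,,15
alpha2,Arg157,Nη1/2,CDR2α,Glu54,Oε1/2,No,,27
peptide,Leu5,O,CDR3α,Asn97,N,Yes,60,52
peptide,Pro6,O,CDR1β,Asn30,Nδ2,Yes,42,18
peptide,Gln7,Nε2,CDR3α,Tyr96,O,No,63,46
peptide,Gln7,Nε2,CDR3α,Ser93,Oγ,Yes,17,25
peptide,Gln7,O,CDR1β,Asn30,N,Yes,4,
peptide,Gln7,O,CDR1β,Ser31,N,Yes,15,61
peptide,Gln7,Oε1,CDR1α,Tyr31,Oη,Yes,66,39
peptide,Gln7,O1,CDR3α,Ser93,Oγ,Yes,21,25
peptide,Gln7,Oε1,CDR1β,Tyr33,Oη,Yes,,5
peptide,Gly8,O,CDR1β,Asn30,N,Yes,77,35
peptide,Gly8,O,CDR1β,Asn30,Nδ2,Yes,13,18
peptide,Gln9,N,CDR1β,His29,Nδ1,Yes,1,1
peptide,Gln9,Nε2,CDR1β,Asn28,O,No,7,15
peptide,Gln9,Nε2,CDR1β,Asn28,Oδ1,Yes,,
peptide,Gln9,Nε2,CDR1β,His29,Nδ1,No,35,16
peptide,Gln9,Oε1,CDR3β,Tyr103,Oη,No,,5
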