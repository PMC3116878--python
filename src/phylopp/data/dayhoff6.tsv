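# Dayhoff 6-class amino-acid recoding: class letter -> member residues.
# Classes group residues with similar chemical properties (small/neutral,
# sulfhydryl, acid/amide, aromatic, basic, hydrophobic).
A	AGPST
B	C
C	DENQ
D	FWY
E	HKR
F	ILMV
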