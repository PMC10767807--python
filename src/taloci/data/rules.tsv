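# TA pairing rule table: one row per type/variant.
# Columns: ta_type, variant, toxin_molecule, antitoxin_molecule,
#   strand (same|opposite|either), dmin, dmax (bp, inclusive; '.' = unbounded),
#   families ('.' = any; else comma-separated family restriction).
# Distances are gaps between nearest gene edges; negative = overlap, so
# dmax=-1 encodes a strict 'distance < 0 bp' requirement over integer bp.
ta_type	variant	toxin_molecule	antitoxin_molecule	strand	dmin	dmax	families
I	I	protein	rna	opposite	.	200	.
II	II	protein	protein	same	-20	150	.
III	III	protein	rna	same	-20	150	.
IV	IV	protein	protein	same	-20	150	.
V	V	protein	protein	same	-20	150	.
VI	VI	protein	protein	same	-20	150	.
VII	VII	protein	protein	same	-20	150	.
VIII	VIII-creTA	rna	rna	either	.	200	creTA
VIII	VIII-sdsr	rna	rna	opposite	.	-1	sdsR-ryeA
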