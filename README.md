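# taloci

Prediction of type I–VIII toxin–antitoxin (TA) loci in prokaryotic genomes
and analysis of their mobile-genetic-element (MGE) context.

Toxin–antitoxin systems are compact two-gene modules — a stable toxin and a
labile antitoxin that neutralises it — implicated in plasmid maintenance,
phage defence and the stabilisation of mobile DNA. They are classified into
types I–VIII by the molecular nature of the antitoxin and its mechanism:
type I pairs a protein toxin with an antisense RNA antitoxin on the
opposite strand; types II–VII are (mostly protein/protein) tandem operons;
type VIII pairs two RNAs (the creTA arrangement on either strand, and the
strictly overlapping antisense SdsR/RyeA arrangement). Because TA loci
frequently ride on prophages, genomic islands, ICEs, integrons, insertion
sequences and plasmids, locating them relative to MGEs — and grouping
similar MGEs across genomes — is central to understanding their spread.

`taloci` is a library (plus a thin CLI) that implements this analysis
end to end on annotated replicons:

1. **Homology search** — every annotated protein is aligned locally
   (Smith–Waterman, BLOSUM62, affine gaps 11/1) against experimentally
   validated reference toxins/antitoxins; reference RNAs are searched
   against both strands of the replicon DNA (+2/−3, gaps 5/2). Optional
   HMMER3 domain profiles (via pyhmmer) add a second evidence channel.
2. **Candidate filter** — a hit is retained when its *H*-value, the
   product of the alignment identity fraction and the fraction of the
   *reference* covered, strictly exceeds 0.36
   (`H = identity × coverage > 0.36`), and, for proteins, when the
   translation length lies in [30, 500] residues.
3. **Pair calling** — candidates are paired exhaustively under
   type-specific strand/distance rules (distance = gap between nearest
   gene edges; negative = overlap): types II–VII same strand at
   −20..150 bp; type I opposite strands at ≤ 200 bp with unlimited
   overlap; type VIII creTA either strand at ≤ 200 bp; type VIII
   SdsR/RyeA opposite strands at < 0 bp. The rule table ships as an
   editable TSV (`src/taloci/data/rules.tsv`).
4. **MGE association** — an MGE is TA-associated when it harbours a locus
   (full containment), or, for ISs/transposons only, when the
   edge-to-edge interval is < 5 kbp; a plasmid replicon harbours every
   locus it carries. Each (locus, MGE) pair is a separate relationship.
5. **MGE similarity networks** — bottom-s MinHash sketches (k = 21,
   s = 1000) give pairwise Mash distances
   `d = −(1/k)·ln(2j/(1+j))`; MGEs at d < 0.01 are similar elements.
   TA–MGE links and MGE–MGE similarity edges form one network
   (networkx), with per-locus subnetworks and summary tables.

A first-class synthetic-genome generator (`taloci.synthetic_data`) plants
TA loci of every type at controlled distances, strands and sequence
identities, plus MGEs at controlled placements, and emits the matching
ground truth — so the entire pipeline is testable offline with known
answers.

## Worked example

`examples/01_predict_ta_loci.py` builds a 60 kb genome with three planted
loci and predicts them:

```
3 TA loci predicted (planted: 3)
type     family                    toxin          antitoxin  dist  score
II       relBE           3000-3288   +    3318-3570   +    30   1.00
I        hok-sok         6570-6729   +    6779-6843   -    50   1.00
VIII-sdsr sdsR-ryeA       9843-9943   +    9933-10037  -   -10   0.91
```

Each row is a called locus: gene coordinates (0-based half-open) and
strands, the edge-to-edge intergenic distance (negative = overlap, so the
SdsR/RyeA-like pair overlaps by 10 bp on opposite strands), and the locus
score — the weaker partner's H-value. `examples/02_mge_association.py`
continues with MGE links (note the plasmid-borne locus linked to its own
plasmid):

```
3 loci, 3 MGEs, 3 TA-MGE links
  rep1:g0001-g0002:II                      prophage      harbored     gap=0
  rep1:g0003-g0004:IV                      IS_transposon flanking_IS  gap=1000
  rep2:g0005-g0006:II                      plasmid       harbored     gap=0
```

and `examples/03_similarity_network.py` shows two prophage copies at Mash
distance 0.0010 (< 0.01, a similarity edge) joining one TA locus
subnetwork, while an unrelated island saturates at d = 1.0.

The same flow is available from the shell
(`examples/04_cli_pipeline.sh`): `taloci simulate | predict | associate |
network | stats`, with every stage reading and writing documented TSVs
and recording a manifest of thresholds and input checksums.

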