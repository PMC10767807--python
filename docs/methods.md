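# Methods

## Scope and model

`taloci` predicts toxin–antitoxin (TA) loci of types I–VIII on annotated
prokaryotic replicons by homology to experimentally validated reference
toxins and antitoxins, then relates the called loci to mobile genetic
elements (MGEs). It does not call genes from bare DNA (annotation is
required input) and does not predict MGEs (their intervals are an input,
as produced by any MGE-annotation tool); plasmid replicons are the one
MGE class derived internally, from the replicon's declared kind.

All internal coordinates are 0-based half-open `[start, end)`;
GenBank/GFF3 1-based inclusive coordinates are converted only at the I/O
boundary. Circular replicons are read but treated as linear: no gene
pair or association is formed across the origin (documented limitation).
Compound CDS locations collapse to their outer span so each gene
contributes exactly one interval to pair calling.

## Homology search and the H-value filter

**Proteins.** Every `protein_coding` feature's translation is aligned
locally against every reference protein with Biopython's
`PairwiseAligner` (Smith–Waterman; BLOSUM62; a gap of length L costs
11 + L). The reference plays the BLAST *query* role. From the optimal
alignment we take identity (identical columns / all alignment columns,
gaps included) and query coverage (reference residues aligned /
reference length).

**RNAs.** Reference RNAs are searched against each replicon and its
reverse complement (match +2, mismatch −3, gap 5 + 2L — megablast-like).
The search is two-stage: *locate* by optimal local alignment, then
*evaluate* the hit by projecting the full reference footprint onto the
replicon and re-aligning that window globally with the same scoring.
The evaluation stage exists because the score-optimal local alignment of
a short (~60–100 nt) RNA at ~70% identity occasionally collapses to a
small perfectly matching core, under-reporting coverage; measuring
identity and coverage over the whole located footprint restores the
intended semantics ("how similar is this homolog region to the
reference") without changing exact-copy behaviour. After each accepted
hit the aligned core is masked with N and the search repeats (up to 8
hits per reference per strand), so multiple copies are found. A hit is
attached to an annotated `rna` feature when footprint and feature
overlap ≥ 50% reciprocally; otherwise a new `rna` feature is synthesised
at the footprint (antitoxin sRNAs are rarely annotated in real inputs).

**E-value ceiling.** Hits are pre-filtered at a permissive raw E-value
ceiling (default 0.01) computed from Karlin–Altschul bit scores with
fixed published constants (protein: λ = 0.267, K = 0.041 for gapped
BLOSUM62 11/1; nucleotide: λ = 0.625, K = 0.41) and plain m·n search
space. These E-values are approximate by design — the decisive
retention criterion is the H-value below, and the ceiling only bounds
the candidate list.

**Domains.** Protein translations can additionally be scanned against
HMMER3 profiles via pyhmmer (`hmmsearch`, E ≤ 1e-5). Profile NAME
fields carry `id|role|type|family`, the same convention as reference
FASTA headers.

**Retention.** A (feature, role, TA type) candidate is kept when its
best alignment hit satisfies `H = identity × query_coverage > 0.36`
(strict), or when a domain hit supports it (OR-combination by default;
`require_blast=True` demands the alignment criterion, matching a
stringent corpus-scale configuration). The strict comparison uses a
1e-9 epsilon so that a 60%-identity/60%-coverage hit — whose product is
0.36 up to floating-point round-up — fails the boundary as intended.
Protein candidates additionally require a translation length in
[30, 500] residues, inclusive. All thresholds live in one module
(`taloci.config`) and are surfaced in `RunConfig`; overrides are echoed
to the run manifest.

## Pair calling

Distance between two features is the gap between their nearest edges,
`max(starts) − min(ends)`; a negative value −n means n bp of overlap.
This convention is forced by the tandem window's negative lower bound
(−20 bp is permitted overlap). The bundled rule table encodes:

| variant | molecules (T/A) | strands | distance (bp) |
|---|---|---|---|
| I | protein / RNA | opposite | ≤ 200, overlap unlimited |
| II, IV–VII | protein / protein | same | −20 … 150 |
| III | protein / RNA | same | −20 … 150 |
| VIII-creTA | RNA / RNA | either | ≤ 200 |
| VIII-sdsr | RNA / RNA | opposite | < 0 (encoded dmax = −1) |

Window bounds are inclusive; "< 0" is strict (distance 0 fails). Both
gene orders are admissible for the tandem types. The two type VIII
variants are family-restricted (creTA, sdsR-ryeA respectively), since
they model two specific validated systems. Pair enumeration is
exhaustive — every (toxin, antitoxin) candidate pair of a type is tested
before any resolution. Type I pairing requires only proximity and
opposite strands (no explicit antisense-overlap requirement), and creTA
uses the same 200 bp window on both strand configurations; both are
deliberate readings of under-specified corners, chosen for recall.

A locus scores `min(toxin H, antitoxin H)` — a pair is only as credible
as its weaker partner. When one feature pair is called under competing
types/families, the highest score wins (ties: lower type number, then
lexicographic family, then variant); loci sharing only one feature are
all kept. Toxin/antitoxin family disagreement keeps the toxin's family
and sets `family_conflict`.

## MGE association and similarity

A TA-associated MGE either *harbours* a locus — the locus span (min
start to max end over its two genes) lies fully inside the element; a
locus straddling an edge is not harboured — or, for ISs/transposons and
IS clusters only, *flanks* one at an edge-to-edge gap of 0 ≤ gap <
5000 bp (strict: 5000 fails, 4999 links). Prophages, genomic islands,
ICEs and integrons associate only by harbouring. Every qualifying
(locus, MGE) pair emits its own link, and downstream statistics count
each link as one relationship while counting each distinct locus once
for association proportions. A locus flanked by the same IS cannot also
be harboured by it; link identity is the (locus, MGE) pair.

MGE sequences are sketched with bottom-s MinHash: canonical k-mers
(lexicographic min of k-mer and reverse complement; k = 21, odd so the
two always differ), s = 1000 smallest 64-bit hashes, k-mers containing
N skipped. Hashing is a seeded MurmurHash3-finalizer-style mix applied
to the 2-bit-packed k-mer, vectorised in numpy, with fixed seed 42 so
sketches are deterministic and comparable across runs. The Mash
distance is `d = −(1/k)·ln(2j/(1+j))` with j estimated as the shared
fraction of the bottom-s sketch of the union; j = 0 saturates at
d = 1.0 (bounded output simplifies thresholding). With s at least the
number of distinct k-mers the estimate equals the exact Jaccard index,
which the tests verify by exhaustive enumeration. All-pairs similarity
is O(n²) over sketches — adequate at study scale; a locality-sensitive
pre-filter is a documented extension point.

## Synthetic studies and ground truth

The generator materialises a `SimulationPlan` — replicons (length, kind,
topology), planted loci (type variant, family, distance, strand
configuration, gene order, per-gene identity), planted MGEs (harboured
around a locus, at an exact gap, a mutated copy of another element, or
unrelated), background gene density (default 0.8 genes/kb; recovery
studies use 0.5), GC (default 0.5) — into a genome, reference set, MGE
table and truth table, all deterministic in one seed.

Planted genes are copies of the bundled synthetic references mutated to
the requested identity by point substitutions only (positions sampled
uniformly without replacement, always to a different letter). With no
indels, alignment coverage stays ≈ 1 and realised H tracks requested
identity, making the 0.36 boundary directly steerable: identity 1.0
realises H = 1.0, 0.7 → H ≈ 0.69, 0.37 → H ≈ 0.368 (passes), 0.30 →
H ≈ 0.305 (fails). The below-threshold decoy therefore uses identity
0.30; note that identity 0.5 at full coverage yields H ≈ 0.5 and
*passes* the published criterion. Proteins are reverse-translated with
one fixed codon per residue and annotated with their planted
translation (GenBank output carries `/translation`, so round trips are
exact); RNAs are annotated as `rna` features.

When planted genes overlap (negative distances), the later-written
gene's bases win in the DNA; RNA genes are always written last so
antisense antitoxins stay intact over protein toxins. Two *RNA/RNA*
genes cannot both realise independent reference identities in one
sequence — the generator refuses plans whose overlap would degrade the
corrupted RNA below ~0.5 effective identity (`PlanError`), defining the
generatable range explicitly. Background ORFs are random codon
sequences with no homology to the references, kept ≥ 300 bp from
planted genes; planted groups are separated by ≥ 3 kb spacers (> 5.1 kb
around MGEs) so no accidental pairings or associations arise. Copy-MGEs
duplicate their source span after background fill, so cargo ORFs copy
too; copies of MGEs harbouring RNA-based loci would duplicate
detectable RNA genes and are not used in the recovery fixtures.

What the synthetic data does *not* emulate: indels and rearrangements,
GC skew and codon bias, overlapping reading frames beyond the planted
geometry, truncated or mis-annotated genes, and real TADB reference
sequences (the bundled references are deterministic synthetic
stand-ins). Passing recovery tests therefore demonstrates the decision
logic — windows, strands, filters, associations — under clean
annotations, not detection sensitivity on diverged natural sequences.

## Recovery study design

The grid study plants every type variant at the minimum, midpoint and
maximum of its distance window, in both admissible arrangements, at
identities 1.0 and 0.7 (27 loci per genome over three 50 kb replicons;
4 genomes). For windows unbounded on the overlap side the grid minimum
is a deep but faithfully generatable overlap: type I −100 bp (the RNA,
written last, sits fully antisense inside the toxin gene), SdsR/RyeA
−20 bp, creTA 0 bp (real creTA pairs are adjacent, not overlapping).
The decoy study plants 27 pairs each violating exactly one rule
dimension — distance one step outside either window edge, wrong strand
configuration, identity 0.30, toxin length 29 or 501 residues (via
dedicated short/long reference families) — and expects zero calls.
Acceptance runs verify 100% recall, zero false positives and zero decoy
leaks, plus bitwise determinism of repeated runs on the ~200 kb standard
fixture (8 loci, 5 MGEs, chromosome + plasmid).

## Numerical and degenerate-input choices

Strict threshold comparisons use a 1e-9 epsilon only where a product of
fractions can round up onto the boundary (the H filter). Ties in
overlap resolution are broken deterministically (score, type order,
family, variant). Empty inputs yield empty outputs everywhere except
where the configuration is unusable (empty reference set, empty profile
file: errors). Internal stop codons in forced translations truncate
with a warning. Sketching a sequence shorter than k is a domain error;
k must be odd. Sequences are uppercase-normalised on read; non-ACGT
characters never enter sketches.

## Known limitations

Origin-spanning loci on circular replicons are not called. E-values are
approximate (no edge-effect correction). RNA search finds at most 8
copies per reference per strand per replicon. The per-species summary
parses the species from the first two tokens of the organism string.
HMM-only candidates carry H = 0 and rely on their partner's score in
locus ranking.
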