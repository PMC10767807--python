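"""Synthetic annotated genomes with planted TA loci, MGEs and ground truth.

Every stage of the pipeline is testable offline against genomes whose TA
content is known by construction.  A :class:`SimulationPlan` describes
replicons, planted TA loci (type, variant, family, intergenic distance,
strand configuration, per-gene sequence identity to the reference) and
planted MGE intervals (harboured around a locus, at a controlled gap from
one, a mutated copy of another element, or unrelated background).  The
generator emits an :class:`~taloci.genome_io.AnnotatedGenome`, the
reference set, the MGE table and a :class:`TruthTable` that is bijective
with the planted elements.

Design notes:

* Planted toxin/antitoxin genes are copies of the bundled synthetic
  reference sequences mutated to the requested identity with point
  substitutions only (no indels), so alignment coverage stays ~1 and the
  realised H-value tracks the requested identity - which makes the 0.36
  retention boundary directly steerable from the plan.
* Protein genes are reverse-translated with one fixed codon per residue
  and annotated with their planted translation; RNA genes are annotated
  as ``rna`` features.  When planted genes overlap (negative distances),
  the later-written gene's bases win in the DNA, while annotations keep
  every planted sequence - RNA genes are always written last so antisense
  antitoxins stay intact.
* Background ORFs are random codon sequences with no homology to the
  references; planted elements are separated by generous spacers
  (default 3000 bp, and >5 kbp across locus/MGE groups) so no accidental
  pairings or associations arise.
* Everything is driven by one integer seed; identical plans give
  byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from taloci.genome_io import AnnotatedGenome, GenomicFeature, Replicon, write_genbank
from taloci.homology import TA_MOLECULES, ReferenceEntry, write_reference_fasta
from taloci.mge_association import FLANKING_CLASSES, MGEAnnotation, write_mge_table

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: One fixed codon per residue (frequent E. coli codons); stop = TAA.
_CODON = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

_COMP = str.maketrans("ACGT", "TGCA")

#: Default family per type variant (first entry of the fixture set).
DEFAULT_FAMILY = {
    "I": "hok-sok",
    "II": "relBE",
    "III": "toxIN",
    "IV": "cbtA-cbeA",
    "V": "ghoST",
    "VI": "socAB",
    "VII": "hha-tomB",
    "VIII-creTA": "creTA",
    "VIII-sdsr": "sdsR-ryeA",
}


class PlanError(ValueError):
    """The plan is internally inconsistent or cannot be placed."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int, alphabet: str, gc: float | None = None) -> str:
    if gc is not None and alphabet == _NT:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list(_NT), size=length, p=p))
    return "".join(rng.choice(list(alphabet), size=length))


def mutate_to_identity(seq: str, target_identity: float, seed: int, alphabet: str | None = None) -> str:
    """Substitute positions of ``seq`` to reach ``target_identity``.

    Exactly ``round((1 - target) * len)`` positions, sampled uniformly
    without replacement, are replaced by a different letter; no indels,
    so the realised identity is within 1/len of the target.
    """
    n = len(seq)
    if not (0.0 < target_identity <= 1.0):
        raise ValueError(f"target identity {target_identity} outside (0, 1]")
    if target_identity < 1.0 / n:
        raise ValueError(f"target identity {target_identity} below 1/{n} resolution")
    n_sub = round((1.0 - target_identity) * n)
    if n_sub == 0:
        return seq
    if alphabet is None:
        alphabet = _NT if set(seq) <= set(_NT) else _AA
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def fixture_references(seed: int = 7654321) -> list[ReferenceEntry]:
    """The bundled synthetic reference set: one toxin/antitoxin pair per family.

    Sequences are deterministic random stand-ins for experimentally
    validated references (synthetic - no real TADB sequences), sized like
    typical members of each family.  The ``tinyT`` and ``grandT`` type II
    families carry 29- and 501-residue toxins for exercising the protein
    length window.
    """
    rng = np.random.default_rng(seed)
    spec: list[tuple[str, str, int, int]] = [
        # (ta_type, family, toxin_len, antitoxin_len); lengths in residues
        # for proteins, nucleotides for RNAs per TA_MOLECULES.
        ("I", "hok-sok", 52, 64),
        ("I", "tisB-istR", 35, 75),
        ("II", "relBE", 95, 83),
        ("II", "mazEF", 111, 82),
        ("II", "higBA", 92, 104),
        ("II", "vapBC", 132, 86),
        ("II", "tinyT", 29, 80),
        ("II", "grandT", 501, 80),
        ("III", "toxIN", 171, 108),
        ("IV", "cbtA-cbeA", 124, 122),
        ("V", "ghoST", 57, 98),
        ("VI", "socAB", 84, 93),
        ("VII", "hha-tomB", 72, 124),
        ("VIII", "creTA", 96, 77),
        ("VIII", "sdsR-ryeA", 100, 104),
    ]
    refs: list[ReferenceEntry] = []
    for ta_type, family, tox_len, anti_len in spec:
        tox_mol, anti_mol = TA_MOLECULES[ta_type]
        for role, mol, length in (("toxin", tox_mol, tox_len), ("antitoxin", anti_mol, anti_len)):
            if mol == "protein":
                seq = "M" + _random_seq(rng, length - 1, _AA)
            else:
                seq = _random_seq(rng, length, _NT)
            refs.append(ReferenceEntry(f"{family}_{role[0].upper()}", role, ta_type, family, mol, seq))
    return refs


@dataclass
class PlantedLocus:
    """One TA locus to plant: type/variant, geometry and per-gene identity."""

    ta_type: str
    variant: str = ""
    family: str = ""
    distance: int = 30
    strands: tuple[str, str] = ("+", "+")  # (toxin, antitoxin)
    order: Literal["toxin_first", "antitoxin_first"] = "toxin_first"
    toxin_identity: float = 1.0
    antitoxin_identity: float = 1.0
    replicon: int = 0

    def __post_init__(self) -> None:
        if not self.variant:
            self.variant = "VIII-creTA" if self.ta_type == "VIII" else self.ta_type
        if not self.family:
            self.family = DEFAULT_FAMILY[self.variant]


@dataclass
class PlantedMGE:
    """One MGE interval: harboured around a locus, at a gap from one, a
    mutated copy of an earlier element, or unrelated background."""

    mge_class: str
    placement: Literal["harbored", "gap", "unrelated", "copy"] = "unrelated"
    anchor_locus: int | None = None
    gap_bp: int = 0
    copy_of: int | None = None  # index into planted_mges
    identity: float = 1.0  # for copies
    length: int = 1200
    margin: int = 1500  # harboured: span beyond the locus on each side
    replicon: int = 0


@dataclass
class SimulationPlan:
    """Deterministic description of one synthetic study genome."""

    seed: int
    replicons: list[tuple[int, str, str]] = field(
        default_factory=lambda: [(60000, "chromosome", "linear")]
    )
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    planted_mges: list[PlantedMGE] = field(default_factory=list)
    background_gene_density: float = 0.8  # genes per kb
    gc: float = 0.5
    organism: str = "Synthetica exempli"
    spacer: int = 3000  # bp between planted groups


@dataclass
class ExpectedLocus:
    """Ground-truth record of one planted locus, in final coordinates."""

    replicon_id: str
    ta_type: str
    variant: str
    family: str
    toxin_start: int
    toxin_end: int
    toxin_strand: str
    antitoxin_start: int
    antitoxin_end: int
    antitoxin_strand: str
    distance: int

    @property
    def start(self) -> int:
        return min(self.toxin_start, self.antitoxin_start)

    @property
    def end(self) -> int:
        return max(self.toxin_end, self.antitoxin_end)

    def key(self) -> tuple:
        return (
            self.replicon_id,
            self.ta_type,
            self.variant,
            self.toxin_start,
            self.toxin_end,
            self.toxin_strand,
            self.antitoxin_start,
            self.antitoxin_end,
            self.antitoxin_strand,
        )


@dataclass
class ExpectedLink:
    locus_index: int  # into TruthTable.expected_loci
    mge_id: str
    link_kind: str
    gap: int


@dataclass
class TruthTable:
    expected_loci: list[ExpectedLocus]
    expected_links: list[ExpectedLink]


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def generate(
    plan: SimulationPlan,
    references: Sequence[ReferenceEntry] | None = None,
) -> tuple[AnnotatedGenome, list[ReferenceEntry], list[MGEAnnotation], TruthTable]:
    """Materialise a plan into a genome, reference set, MGE table and truth.

    Raises :class:`PlanError` before emitting anything if a planted
    element cannot be placed inside its replicon.
    """
    rng = np.random.default_rng(plan.seed)
    refs = list(references) if references is not None else fixture_references()
    by_key = {(r.ta_type, r.family, r.role): r for r in refs}

    rep_ids = [f"rep{i + 1}" for i in range(len(plan.replicons))]
    buffers: list[bytearray] = []
    for (length, _, _), _rid in zip(plan.replicons, rep_ids):
        buffers.append(bytearray(_random_seq(rng, length, _NT, gc=plan.gc).encode()))
    cursors = [plan.spacer for _ in plan.replicons]
    gene_intervals: list[list[tuple[int, int]]] = [[] for _ in plan.replicons]

    features: list[GenomicFeature] = []
    expected_loci: list[ExpectedLocus] = []
    mges: list[MGEAnnotation] = []
    gene_counter = 0

    def _write(rep: int, start: int, dna: str, strand: str) -> None:
        if start < 0 or start + len(dna) > len(buffers[rep]):
            raise PlanError(f"planted gene [{start},{start + len(dna)}) outside replicon {rep_ids[rep]}")
        payload = dna if strand == "+" else _revcomp(dna)
        buffers[rep][start : start + len(dna)] = payload.encode()
        gene_intervals[rep].append((start, start + len(dna)))

    def _plant_gene(
        pl: PlantedLocus, role: str, identity: float
    ) -> tuple[str, str, str]:
        """Returns (molecule, annotated_sequence, gene_dna)."""
        tox_mol, anti_mol = TA_MOLECULES[pl.ta_type]
        mol = tox_mol if role == "toxin" else anti_mol
        ref = by_key.get((pl.ta_type, pl.family, role))
        if ref is None:
            raise PlanError(f"no reference for type {pl.ta_type} family {pl.family} {role}")
        sub_seed = int(rng.integers(2**31 - 1))
        mutated = mutate_to_identity(ref.sequence, identity, sub_seed)
        if mol == "protein":
            return "protein_coding", mutated, _reverse_translate(mutated)
        return "rna", mutated, mutated

    # --- plant loci and their anchored MGEs, replicon by replicon, in order
    mges_by_anchor: dict[int, list[int]] = {}
    deferred: list[int] = []
    for mi, pm in enumerate(plan.planted_mges):
        if pm.placement in ("harbored", "gap"):
            if pm.anchor_locus is None:
                raise PlanError(f"MGE {mi}: {pm.placement} placement needs anchor_locus")
            mges_by_anchor.setdefault(pm.anchor_locus, []).append(mi)
        else:
            deferred.append(mi)
    mge_records: dict[int, MGEAnnotation] = {}

    for li, pl in enumerate(plan.planted_loci):
        rep = pl.replicon
        cursor = cursors[rep]
        tox_mol_kind, tox_seq, tox_dna = _plant_gene(pl, "toxin", pl.toxin_identity)
        anti_mol_kind, anti_seq, anti_dna = _plant_gene(pl, "antitoxin", pl.antitoxin_identity)
        # generatable-range guard: when two RNA genes overlap, the overlap
        # bases belong to the later-written gene, so the earlier gene's
        # realized identity is ~identity x (1 - overlap/len).  Refuse plans
        # whose corrupted gene would fall below a recoverable 0.5.
        if tox_mol_kind == "rna" and anti_mol_kind == "rna" and pl.distance < 0:
            overlap = min(-pl.distance, len(tox_dna))
            effective = pl.toxin_identity * (1 - overlap / len(tox_dna))
            if effective < 0.5:
                raise PlanError(
                    f"locus {li}: RNA/RNA overlap {overlap} bp degrades the toxin RNA to "
                    f"~{effective:.2f} effective identity; outside the generatable range"
                )
        first_is_toxin = pl.order == "toxin_first"
        first_dna, second_dna = (tox_dna, anti_dna) if first_is_toxin else (anti_dna, tox_dna)
        a_start = cursor
        a_end = a_start + len(first_dna)
        b_start = a_end + pl.distance
        b_end = b_start + len(second_dna)
        if b_start < 0:
            raise PlanError(f"locus {li}: overlap deeper than upstream gene")
        tox_span = (a_start, a_end) if first_is_toxin else (b_start, b_end)
        anti_span = (b_start, b_end) if first_is_toxin else (a_start, a_end)
        # protein genes first, RNA genes last so antisense RNAs stay intact
        writes = [
            (tox_mol_kind, tox_span, tox_dna, pl.strands[0]),
            (anti_mol_kind, anti_span, anti_dna, pl.strands[1]),
        ]
        writes.sort(key=lambda w: w[0] == "rna")
        for _mol, span, dna, strand in writes:
            _write(rep, span[0], dna, strand)
        gene_counter += 1
        tox_feat = GenomicFeature(
            f"g{gene_counter:04d}", rep_ids[rep], tox_span[0], tox_span[1], pl.strands[0],
            tox_mol_kind, product=f"{pl.family} toxin",
            translation=tox_seq if tox_mol_kind == "protein_coding" else "",
        )
        gene_counter += 1
        anti_feat = GenomicFeature(
            f"g{gene_counter:04d}", rep_ids[rep], anti_span[0], anti_span[1], pl.strands[1],
            anti_mol_kind, product=f"{pl.family} antitoxin",
            translation=anti_seq if anti_mol_kind == "protein_coding" else "",
        )
        features.extend([tox_feat, anti_feat])
        conv_distance = max(tox_span[0], anti_span[0]) - min(tox_span[1], anti_span[1])
        expected_loci.append(
            ExpectedLocus(
                rep_ids[rep], pl.ta_type, pl.variant, pl.family,
                tox_span[0], tox_span[1], pl.strands[0],
                anti_span[0], anti_span[1], pl.strands[1],
                conv_distance,
            )
        )
        locus_span = (min(a_start, b_start), max(a_end, b_end))
        cursor = locus_span[1]
        for mi in mges_by_anchor.get(li, ()):
            pm = plan.planted_mges[mi]
            if pm.replicon != rep:
                raise PlanError(f"MGE {mi} anchored to locus {li} on a different replicon")
            if pm.placement == "harbored":
                m_start = max(0, locus_span[0] - pm.margin)
                m_end = locus_span[1] + pm.margin
            else:  # gap
                m_start = locus_span[1] + pm.gap_bp
                m_end = m_start + pm.length
            if m_end > len(buffers[rep]):
                raise PlanError(f"MGE {mi} extends past replicon {rep_ids[rep]}")
            mge_records[mi] = MGEAnnotation(f"mge{mi + 1:03d}", rep_ids[rep], m_start, m_end, pm.mge_class)
            cursor = max(cursor, m_end)
        # isolate locus/MGE groups beyond the flanking window so gap-anchored
        # ISs never also associate with the next planted locus
        gap_after = max(plan.spacer, 5100) if mges_by_anchor.get(li) else plan.spacer
        cursors[rep] = cursor + gap_after

    # --- unrelated and copy MGEs
    pending_copies: list[tuple[int, int, MGEAnnotation, float, int]] = []
    for mi in deferred:
        pm = plan.planted_mges[mi]
        rep = pm.replicon
        cursors[rep] = cursors[rep] - plan.spacer + max(plan.spacer, 5100)
        if pm.placement == "copy":
            if pm.copy_of is None or pm.copy_of not in mge_records:
                raise PlanError(f"MGE {mi}: copy_of must name an already-placed MGE")
            src = mge_records[pm.copy_of]
            m_start = cursors[rep]
            m_end = m_start + (src.end - src.start)
            if m_end + plan.spacer > len(buffers[rep]):
                raise PlanError(f"MGE {mi} does not fit on replicon {rep_ids[rep]}")
            # reserve now, copy bytes after background fill so the copy sees
            # the source's final sequence (including its cargo ORFs)
            gene_intervals[rep].append((m_start, m_end))
            pending_copies.append((rep, m_start, src, pm.identity, int(rng.integers(2**31 - 1))))
        else:  # unrelated
            m_start = cursors[rep]
            m_end = m_start + pm.length
            if m_end + plan.spacer > len(buffers[rep]):
                raise PlanError(f"MGE {mi} does not fit on replicon {rep_ids[rep]}")
        mge_records[mi] = MGEAnnotation(f"mge{mi + 1:03d}", rep_ids[rep], m_start, m_end, pm.mge_class)
        cursors[rep] = m_end + max(plan.spacer, 5100)
    mges = [mge_records[mi] for mi in sorted(mge_records)]

    # --- background ORFs in free space, >=300 bp clear of planted genes
    for rep, (length, _, _) in enumerate(plan.replicons):
        target = int(plan.background_gene_density * length / 1000)
        target = max(0, target - len([f for f in features if f.replicon_id == rep_ids[rep]]))
        blocked = sorted((max(0, s - 300), e + 300) for s, e in gene_intervals[rep])
        merged: list[list[int]] = []
        for s, e in blocked:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        free: list[tuple[int, int]] = []
        prev = 0
        for s, e in merged:
            if s > prev:
                free.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            free.append((prev, length))
        placed = 0
        for fs, fe in free:
            pos = fs + 150
            while placed < target:
                aa_len = int(rng.integers(80, 150))
                dna_len = 3 * (aa_len + 1)
                if pos + dna_len + 150 > fe:
                    break
                prot = "M" + _random_seq(rng, aa_len - 1, _AA)
                dna = _reverse_translate(prot)
                strand = "+" if rng.random() < 0.5 else "-"
                buffers[rep][pos : pos + dna_len] = (dna if strand == "+" else _revcomp(dna)).encode()
                gene_counter += 1
                features.append(
                    GenomicFeature(
                        f"g{gene_counter:04d}", rep_ids[rep], pos, pos + dna_len, strand,
                        "protein_coding", product="hypothetical protein", translation=prot,
                    )
                )
                placed += 1
                pos += dna_len + 150
            if placed >= target:
                break

    for rep, m_start, src, identity, sub_seed in pending_copies:
        src_rep = rep_ids.index(src.replicon_id)
        src_seq = buffers[src_rep][src.start : src.end].decode()
        seq = src_seq if identity >= 1.0 else mutate_to_identity(src_seq, identity, sub_seed)
        buffers[rep][m_start : m_start + len(seq)] = seq.encode()

    replicons = [
        Replicon(rid, buffers[i].decode(), topology=topo, kind=kind, organism=plan.organism)
        for i, (rid, (length, kind, topo)) in enumerate(zip(rep_ids, plan.replicons))
    ]
    genome = AnnotatedGenome(replicons, features)
    for m in mges:
        m.sequence = genome.replicon(m.replicon_id).sequence[m.start : m.end]

    # --- expected links from the final geometry (plain interval logic)
    expected_links: list[ExpectedLink] = []
    kind_of = {rid: plan.replicons[i][1] for i, rid in enumerate(rep_ids)}
    for li, el in enumerate(expected_loci):
        for m in mges:
            if m.replicon_id != el.replicon_id:
                continue
            if m.start <= el.start and el.end <= m.end:
                expected_links.append(ExpectedLink(li, m.mge_id, "harbored", 0))
            elif m.mge_class in FLANKING_CLASSES:
                gap = max(el.start, m.start) - min(el.end, m.end)
                if 0 <= gap < 5000:
                    expected_links.append(ExpectedLink(li, m.mge_id, "flanking_IS", gap))
        if kind_of[el.replicon_id] == "plasmid":
            expected_links.append(ExpectedLink(li, f"plasmid:{el.replicon_id}", "harbored", 0))

    return genome, refs, mges, TruthTable(expected_loci, expected_links)


#: Representative {min, mid, max} intergenic distances per type variant.
#: Windows with an unbounded overlap side use a deep-but-generatable
#: overlap as their "min" (type I: the antitoxin RNA fully antisense to
#: the toxin gene; RNA/RNA variants: ~half-RNA overlaps).
GRID_DISTANCES = {
    "I": (-100, 50, 200),
    "II": (-20, 65, 150),
    "III": (-20, 65, 150),
    "IV": (-20, 65, 150),
    "V": (-20, 65, 150),
    "VI": (-20, 65, 150),
    "VII": (-20, 65, 150),
    "VIII-creTA": (0, 100, 200),
    "VIII-sdsr": (-20, -10, -1),
}

#: Strand configurations per variant for the two admissible arrangements.
_GRID_STRANDS = {
    "I": (("+", "-"), ("-", "+")),
    "VIII-sdsr": (("+", "-"), ("-", "+")),
    "VIII-creTA": (("+", "+"), ("+", "-")),  # same-strand and antisense forms
}


def recovery_grid_plan(identity: float, arrangement: int, seed: int) -> SimulationPlan:
    """All 9 type variants x {min, mid, max} distance, one gene arrangement.

    ``arrangement`` 0/1 selects toxin-first vs antitoxin-first for tandem
    types and the alternative strand configuration for antisense types.
    Both genes of every locus are planted at ``identity`` to their
    reference.  27 loci over three 50 kb replicons.
    """
    loci = []
    for variant, distances in GRID_DISTANCES.items():
        ta_type = "VIII" if variant.startswith("VIII") else variant
        strands = _GRID_STRANDS.get(variant, (("+", "+"), ("-", "-")))[arrangement]
        order = "toxin_first" if arrangement == 0 else "antitoxin_first"
        if variant in ("I", "VIII-sdsr", "VIII-creTA"):
            order = "toxin_first"  # arrangement varies the strand pattern instead
        for d in distances:
            loci.append(
                PlantedLocus(
                    ta_type, variant=variant, distance=d, strands=strands, order=order,
                    toxin_identity=identity, antitoxin_identity=identity,
                )
            )
    for i, pl in enumerate(loci):
        pl.replicon = i // 9
    return SimulationPlan(
        seed=seed,
        replicons=[(50_000, "chromosome", "linear")] * 3,
        planted_loci=loci,
        background_gene_density=0.5,
    )


def decoy_plan(seed: int) -> SimulationPlan:
    """Single-violation decoys: each planted pair breaks exactly one rule
    dimension (distance one step outside the window, wrong strand, identity
    below the retention cut-off, or protein length outside [30, 500])."""
    tandem = ("II", "III", "IV", "V", "VI", "VII")
    loci: list[PlantedLocus] = []
    for t in tandem:  # distance one past either window edge
        loci.append(PlantedLocus(t, distance=151))
        loci.append(PlantedLocus(t, distance=-21))
    loci.append(PlantedLocus("I", distance=201, strands=("+", "-")))
    loci.append(PlantedLocus("VIII", variant="VIII-creTA", distance=201))
    loci.append(PlantedLocus("VIII", variant="VIII-sdsr", distance=0, strands=("+", "-")))
    for t in tandem:  # wrong strand configuration
        loci.append(PlantedLocus(t, distance=30, strands=("+", "-")))
    loci.append(PlantedLocus("I", distance=50, strands=("+", "+")))
    loci.append(PlantedLocus("VIII", variant="VIII-sdsr", distance=-10, strands=("+", "+")))
    # identity below the retention threshold (H ~ identity at full coverage)
    loci.append(PlantedLocus("II", distance=30, toxin_identity=0.30))
    loci.append(PlantedLocus("I", distance=50, strands=("+", "-"), antitoxin_identity=0.30))
    # toxin length outside the [30, 500] residue window
    loci.append(PlantedLocus("II", family="tinyT", distance=30))
    loci.append(PlantedLocus("II", family="grandT", distance=30))
    for i, pl in enumerate(loci):
        pl.replicon = i % 3
    return SimulationPlan(
        seed=seed,
        replicons=[(60_000, "chromosome", "linear")] * 3,
        planted_loci=loci,
        background_gene_density=0.5,
    )


def plan_from_dict(payload: dict) -> SimulationPlan:
    """Build a plan from a plain mapping (e.g. parsed YAML config)."""
    loci = [PlantedLocus(**{**d, "strands": tuple(d.get("strands", ("+", "+")))}) for d in payload.get("planted_loci", [])]
    mges = [PlantedMGE(**d) for d in payload.get("planted_mges", [])]
    replicons = [tuple(r) for r in payload.get("replicons", [(60000, "chromosome", "linear")])]
    return SimulationPlan(
        seed=int(payload["seed"]),
        replicons=replicons,  # type: ignore[arg-type]
        planted_loci=loci,
        planted_mges=mges,
        background_gene_density=float(payload.get("background_gene_density", 0.8)),
        gc=float(payload.get("gc", 0.5)),
        organism=payload.get("organism", "Synthetica exempli"),
        spacer=int(payload.get("spacer", 3000)),
    )


def write_bundle(
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    mges: Sequence[MGEAnnotation],
    truth: TruthTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a complete fixture bundle in the formats the pipeline reads."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.gbk",
        "refs_protein": outdir / "refs_protein.fasta",
        "refs_rna": outdir / "refs_rna.fasta",
        "mges": outdir / "mges.tsv",
        "truth": outdir / "truth.json",
    }
    write_genbank(genome, paths["genome"])
    write_reference_fasta([r for r in refs if r.molecule == "protein"], paths["refs_protein"])
    write_reference_fasta([r for r in refs if r.molecule == "rna"], paths["refs_rna"])
    write_mge_table(mges, paths["mges"])
    payload = {
        "expected_loci": [vars(e) for e in truth.expected_loci],
        "expected_links": [vars(e) for e in truth.expected_links],
    }
    paths["truth"].write_text(json.dumps(payload, indent=1) + "\n")
    return paths
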