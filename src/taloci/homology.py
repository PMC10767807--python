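"""Candidate toxin/antitoxin detection by homology against validated references.

Protein candidates come from local alignment of every annotated protein
against the reference toxins/antitoxins (Smith-Waterman, BLOSUM62, affine
gaps, BLASTp-like); RNA candidates from nucleotide local alignment of the
reference RNAs against the replicon sequence on both strands
(BLASTn-like).  Profile-HMM domain scans (HMMER3 profiles, via pyhmmer)
provide a second evidence channel.

The retention criterion is the H-value: the product of the alignment
identity fraction and the fraction of the *reference* (query) covered,
so H in [0, 1].  Candidates are kept when H strictly exceeds the
threshold (default 0.36, i.e. a 60%-identity/60%-coverage hit fails) and,
for proteins, when the translation length lies in [30, 500] residues
inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pyhmmer
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from taloci.config import (
    DEFAULT_EVALUE_CEILING,
    DEFAULT_H_THRESHOLD,
    DEFAULT_HMM_EVALUE,
    DEFAULT_LEN_MAX,
    DEFAULT_LEN_MIN,
)
from taloci.genome_io import AnnotatedGenome, FormatError, GenomicFeature

Role = Literal["toxin", "antitoxin"]

TA_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: Molecule of the toxin / antitoxin partner for each TA type.  Type I and
#: type III antitoxins are RNAs; type VIII systems are RNA/RNA; everything
#: else is a protein pair.
TA_MOLECULES: dict[str, tuple[str, str]] = {
    "I": ("protein", "rna"),
    "II": ("protein", "protein"),
    "III": ("protein", "rna"),
    "IV": ("protein", "protein"),
    "V": ("protein", "protein"),
    "VI": ("protein", "protein"),
    "VII": ("protein", "protein"),
    "VIII": ("rna", "rna"),
}

#: Numerical guard for the strict H > threshold comparison: keeps
#: identity 0.6 x coverage 0.6 (floating-point 0.36000000000000004) on the
#: failing side of the 0.36 boundary.
_H_EPS = 1e-9

# Karlin-Altschul parameters for bit-score / E-value conversion.  Gapped
# BLOSUM62 (open 11, extend 1) and blastn reward +2 / penalty -3 values;
# E-values here are a permissive pre-filter only - the decisive criterion
# is the H-value.
_KA_PROTEIN = (0.267, 0.041)
_KA_NUCLEOTIDE = (0.625, 0.41)


class ConfigError(ValueError):
    """Raised for unusable configuration (e.g. empty reference set)."""


@dataclass
class ReferenceEntry:
    """One experimentally validated toxin or antitoxin reference sequence."""

    ref_id: str
    role: Role
    ta_type: str
    family: str
    molecule: Literal["protein", "rna"]
    sequence: str

    def __post_init__(self) -> None:
        if self.ta_type not in TA_TYPES:
            raise ValueError(f"unknown TA type {self.ta_type!r}")
        if not self.family:
            raise ValueError("family must be non-empty")
        toxin_mol, anti_mol = TA_MOLECULES[self.ta_type]
        expected = toxin_mol if self.role == "toxin" else anti_mol
        if self.molecule != expected:
            raise ValueError(
                f"{self.ref_id}: type {self.ta_type} {self.role} must be {expected}, "
                f"got {self.molecule}"
            )
        self.sequence = self.sequence.upper()


@dataclass
class HomologyHit:
    """A local-alignment hit of a reference (query) against a genome feature."""

    feature_id: str
    ref_id: str
    identity: float
    query_coverage: float
    bitscore: float
    evalue: float
    h_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.h_value = h_value(self.identity, self.query_coverage)


@dataclass
class DomainHit:
    """A profile-HMM domain hit on a protein feature."""

    feature_id: str
    profile_id: str
    role: Role
    ta_type: str
    family: str
    evalue: float
    score: float


@dataclass
class Candidate:
    """A feature with homology evidence for one (role, TA type) assignment."""

    feature: GenomicFeature
    role: Role
    ta_type: str
    family: str
    best_hit: HomologyHit | DomainHit
    evidence_kind: Literal["blast", "hmm", "both"]

    @property
    def h_value(self) -> float:
        """H-value of the best alignment hit; 0 for HMM-only candidates."""
        if isinstance(self.best_hit, HomologyHit):
            return self.best_hit.h_value
        return 0.0


def h_value(identity: float, query_coverage: float) -> float:
    """Combined hit credibility: identity fraction x query-coverage fraction.

    Coverage is measured on the reference (query) side of the alignment.
    Both arguments must lie in [0, 1]; the product does too.
    """
    if not (0.0 <= identity <= 1.0):
        raise ValueError(f"identity {identity} outside [0, 1]")
    if not (0.0 <= query_coverage <= 1.0):
        raise ValueError(f"query_coverage {query_coverage} outside [0, 1]")
    return identity * query_coverage


def passes_h(h: float, threshold: float = DEFAULT_H_THRESHOLD) -> bool:
    """Strict H > threshold test with a small epsilon guard against
    floating-point round-up at the boundary."""
    return h > threshold + _H_EPS


def read_reference_fasta(path: str | Path, molecule: Literal["protein", "rna"]) -> list[ReferenceEntry]:
    """Read a reference FASTA whose headers are ``ref_id|role|type|family``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"reference header {rec.id!r}: expected 'ref_id|role|type|family'"
            )
        ref_id, role, ta_type, family = parts
        entries.append(ReferenceEntry(ref_id, role, ta_type, family, molecule, str(rec.seq)))
    return entries


def write_reference_fasta(refs: Sequence[ReferenceEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.ref_id}|{r.role}|{r.ta_type}|{r.family}\n{r.sequence}\n")


def make_protein_aligner() -> PairwiseAligner:
    """Smith-Waterman aligner: BLOSUM62, gap of length L costs 11 + L."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def make_nucleotide_aligner() -> PairwiseAligner:
    """Local DNA aligner: match +2, mismatch -3, gap of length L costs 5 + 2L.

    The alphabet includes N, scored -3 against everything (including N),
    so masked regions never re-align.
    """
    aligner = PairwiseAligner()
    aligner.mode = "local"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = 2.0 if (a == b and a != "N") else -3.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _bit_and_evalue(raw: float, m: int, n: int, ka: tuple[float, float]) -> tuple[float, float]:
    lam, k = ka
    bits = (lam * raw - math.log(k)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bits)
    return bits, evalue


def _alignment_stats(alignment) -> tuple[float, float]:
    """(identity over alignment columns, fraction of query residues aligned)."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qlen = len(alignment.query)
    aligned_q = sum(e - s for s, e in alignment.aligned[1])
    return identity, aligned_q / qlen


def search_protein(
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
) -> list[HomologyHit]:
    """Align every protein feature against every protein reference.

    Returns all hits under the permissive raw E-value ceiling, with
    identity, query coverage (on the reference) and H-value populated.
    The reference plays the BLAST query role.
    """
    refs = [r for r in refs if r.molecule == "protein"]
    if not refs:
        raise ConfigError("empty protein reference set")
    aligner = make_protein_aligner()
    hits: list[HomologyHit] = []
    for feat in genome.proteins():
        target = feat.translation
        for ref in refs:
            raw = aligner.score(target, ref.sequence)
            bits, evalue = _bit_and_evalue(raw, len(target), len(ref.sequence), _KA_PROTEIN)
            if evalue > evalue_ceiling:
                continue
            best = aligner.align(target, ref.sequence)[0]
            identity, coverage = _alignment_stats(best)
            hits.append(HomologyHit(feat.feature_id, ref.ref_id, identity, coverage, bits, evalue))
    return hits


def make_nucleotide_evaluator() -> PairwiseAligner:
    """Global aligner (same scoring) for re-scoring a located RNA footprint.

    A score-optimal local alignment of a short, diverged RNA can collapse
    to a small perfectly-matching core, under-reporting coverage; once the
    homolog region is located, identity and coverage are therefore
    measured over the whole footprint with a global alignment.
    """
    aligner = make_nucleotide_aligner()
    aligner.mode = "global"
    return aligner


def _map_minus(span: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = span
    return length - e, length - s


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def search_rna(
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
    max_hits_per_ref: int = 8,
) -> list[HomologyHit]:
    """Find RNA homologs by nucleotide local alignment on both strands.

    Each reference RNA is aligned against every replicon and its reverse
    complement; after each accepted hit the aligned interval is masked with
    N and the search repeats, so multiple copies are found.  A hit is
    attached to an annotated ``rna`` feature when their intervals overlap
    at least 50% reciprocally; otherwise a new ``rna`` feature is
    synthesised at the hit interval and added to the genome (antitoxin
    sRNAs are rarely annotated in real inputs).
    """
    refs = [r for r in refs if r.molecule == "rna"]
    if not refs:
        raise ConfigError("empty RNA reference set")
    aligner = make_nucleotide_aligner()
    evaluator = make_nucleotide_evaluator()
    hits: list[HomologyHit] = []
    new_features: list[GenomicFeature] = []
    synth_n = 0
    for rep in genome.replicons:
        length = len(rep.sequence)
        annotated = [
            f for f in genome.features if f.replicon_id == rep.id and f.molecule == "rna"
        ]
        for strand, base_seq in (("+", rep.sequence), ("-", str(Seq(rep.sequence).reverse_complement()))):
            for ref in refs:
                work = base_seq
                for _ in range(max_hits_per_ref):
                    raw = aligner.score(work, ref.sequence)
                    bits, evalue = _bit_and_evalue(raw, length, len(ref.sequence), _KA_NUCLEOTIDE)
                    if evalue > evalue_ceiling:
                        break
                    best = aligner.align(work, ref.sequence)[0]
                    t0 = int(best.aligned[0][0][0])
                    t1 = int(best.aligned[0][-1][-1])
                    # project the full reference footprint onto the target:
                    # a trimmed alignment core still marks the whole homolog
                    q0 = int(best.aligned[1][0][0])
                    q1 = int(best.aligned[1][-1][-1])
                    f0 = max(0, t0 - q0)
                    f1 = min(length, t1 + (len(ref.sequence) - q1))
                    # evaluate identity/coverage over the whole (unmasked)
                    # footprint so a trimmed core does not under-report them
                    eval_best = evaluator.align(base_seq[f0:f1], ref.sequence)[0]
                    identity, coverage = _alignment_stats(eval_best)
                    span = (f0, f1) if strand == "+" else _map_minus((f0, f1), length)
                    feature = None
                    for f in annotated:
                        if f.strand == strand and _reciprocal_overlap((f.start, f.end), span) >= 0.5:
                            feature = f
                            break
                    if feature is None:
                        synth_n += 1
                        feature = GenomicFeature(
                            f"{rep.id}_rnahit{synth_n}",
                            rep.id,
                            span[0],
                            span[1],
                            strand,
                            "rna",
                            product=f"putative {ref.family} RNA homolog",
                        )
                        new_features.append(feature)
                        annotated.append(feature)
                    hits.append(
                        HomologyHit(feature.feature_id, ref.ref_id, identity, coverage, bits, evalue)
                    )
                    work = work[:t0] + "N" * (t1 - t0) + work[t1:]
    for f in new_features:
        genome.add_feature(f)
    return hits


def _parse_profile_name(name: str) -> tuple[str, Role, str, str]:
    parts = name.split("|")
    if len(parts) != 4 or parts[1] not in ("toxin", "antitoxin") or parts[2] not in TA_TYPES:
        raise FormatError(
            f"profile name {name!r}: expected 'profile_id|role|type|family'"
        )
    return parts[0], parts[1], parts[2], parts[3]  # type: ignore[return-value]


def scan_domains(
    genome: AnnotatedGenome,
    profiles: str | Path,
    evalue_ceiling: float = DEFAULT_HMM_EVALUE,
) -> list[DomainHit]:
    """Scan protein translations against a HMMER3 profile file via pyhmmer.

    Profile NAME fields follow the same ``id|role|type|family`` convention
    as the reference FASTA headers.  Hits at or below the E-value ceiling
    (default 1e-5) are returned.
    """
    profiles = Path(profiles)
    try:
        with pyhmmer.plan7.HMMFile(str(profiles)) as hf:
            hmms = list(hf)
    except Exception as exc:
        raise FormatError(f"malformed profile file {profiles}: {exc}") from exc
    if not hmms:
        raise FormatError(f"profile file {profiles} contains no profiles")

    feats = genome.proteins()
    if not feats:
        return []
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(name=f.feature_id.encode(), sequence=f.translation).digitize(alphabet)
        for f in feats
    ]
    out: list[DomainHit] = []
    def _text(value) -> str:
        return value.decode() if isinstance(value, bytes) else str(value)

    for top_hits in pyhmmer.hmmsearch(hmms, seqs, E=evalue_ceiling):
        profile_id, role, ta_type, family = _parse_profile_name(_text(top_hits.query.name))
        for hit in top_hits:
            if hit.evalue <= evalue_ceiling:
                out.append(
                    DomainHit(_text(hit.name), profile_id, role, ta_type, family, hit.evalue, hit.score)
                )
    return out


def build_candidates(
    hits: Iterable[HomologyHit],
    domain_hits: Iterable[DomainHit],
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    h_threshold: float = DEFAULT_H_THRESHOLD,
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
    require_blast: bool = False,
) -> list[Candidate]:
    """Apply the H-value and length filters; combine alignment and domain evidence.

    A (feature, role, TA type) candidate is retained when its best
    alignment hit has H > ``h_threshold``, or (unless ``require_blast``)
    when a domain hit supports it.  Protein candidates additionally need a
    translation length in [``len_min``, ``len_max``] inclusive.  The
    family is taken from the best-scoring evidence; output is sorted by
    H-value, descending.
    """
    feat_by_id = {f.feature_id: f for f in genome.features}
    ref_by_id = {r.ref_id: r for r in refs}

    best_blast: dict[tuple[str, str, str], HomologyHit] = {}
    blast_family: dict[tuple[str, str, str], str] = {}
    for hit in hits:
        ref = ref_by_id.get(hit.ref_id)
        if ref is None:
            continue
        key = (hit.feature_id, ref.role, ref.ta_type)
        if key not in best_blast or hit.h_value > best_blast[key].h_value:
            best_blast[key] = hit
            blast_family[key] = ref.family

    best_domain: dict[tuple[str, str, str], DomainHit] = {}
    for dhit in domain_hits:
        key = (dhit.feature_id, dhit.role, dhit.ta_type)
        if key not in best_domain or dhit.score > best_domain[key].score:
            best_domain[key] = dhit

    candidates: list[Candidate] = []
    for key in set(best_blast) | set(best_domain):
        feature_id, role, ta_type = key
        feature = feat_by_id.get(feature_id)
        if feature is None:
            continue
        bhit = best_blast.get(key)
        dhit = best_domain.get(key)
        blast_ok = bhit is not None and passes_h(bhit.h_value, h_threshold)
        hmm_ok = dhit is not None
        if require_blast:
            keep = blast_ok
        else:
            keep = blast_ok or hmm_ok
        if not keep:
            continue
        if feature.molecule == "protein_coding":
            if not (len_min <= len(feature.translation) <= len_max):
                continue
        if blast_ok:
            evidence_kind = "both" if hmm_ok else "blast"
            best: HomologyHit | DomainHit = bhit  # type: ignore[assignment]
            family = blast_family[key]
        else:
            evidence_kind = "hmm"
            best = dhit  # type: ignore[assignment]
            family = dhit.family  # type: ignore[union-attr]
        candidates.append(Candidate(feature, role, ta_type, family, best, evidence_kind))
    candidates.sort(key=lambda c: (-c.h_value, c.feature.feature_id, c.role, c.ta_type))
    return candidates


def hits_to_tsv(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """Export hits as a BLAST outfmt-6-like TSV with an extra h_value column."""
    header = "feature_id\tref_id\tpident\tqcov\tbitscore\tevalue\th_value\n"
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            fh.write(
                f"{h.feature_id}\t{h.ref_id}\t{100 * h.identity:.2f}\t{h.query_coverage:.4f}\t"
                f"{h.bitscore:.1f}\t{h.evalue:.2e}\t{h.h_value:.4f}\n"
            )
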