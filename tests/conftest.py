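"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from taloci.genome_io import GenomicFeature
from taloci.homology import TA_MOLECULES, Candidate, HomologyHit
from taloci.synthetic_data import PlantedLocus, PlantedMGE, SimulationPlan, fixture_references

# ---------------------------------------------------------------------------
# independent brute-force oracles


def dp_local_score(a: str, b: str, matrix=None, gap_open: float = 12.0, gap_ext: float = 1.0) -> float:
    """Plain-Python Gotoh local alignment score oracle.

    Affine gaps: a gap of length L costs gap_open + (L-1)*gap_ext.
    Deliberately independent of Biopython's aligner.
    """
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (moving along b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_pair_variants(tox: Candidate, anti: Candidate) -> list[str]:
    """Literal re-statement of the published pairing windows, independent of
    the rule-table machinery: which type variants admit this pair?"""
    t, a = tox.feature, anti.feature
    if t.replicon_id != a.replicon_id or t.feature_id == a.feature_id:
        return []
    if tox.ta_type != anti.ta_type:
        return []
    d = max(t.start, a.start) - min(t.end, a.end)
    same = t.strand == a.strand
    typ = tox.ta_type
    out = []
    if typ == "I":
        if t.molecule == "protein_coding" and a.molecule == "rna" and not same and d <= 200:
            out.append("I")
    elif typ in ("II", "IV", "V", "VI", "VII"):
        if t.molecule == "protein_coding" and a.molecule == "protein_coding" and same and -20 <= d <= 150:
            out.append(typ)
    elif typ == "III":
        if t.molecule == "protein_coding" and a.molecule == "rna" and same and -20 <= d <= 150:
            out.append("III")
    elif typ == "VIII":
        if t.molecule == "rna" and a.molecule == "rna":
            if tox.family == "creTA" and d <= 200:
                out.append("VIII-creTA")
            if tox.family == "sdsR-ryeA" and not same and d < 0:
                out.append("VIII-sdsr")
    return out


def oracle_call(candidates: list[Candidate]) -> set[tuple[str, str, str]]:
    """Exhaustive double-loop pairing oracle: {(variant, toxin_id, anti_id)}."""
    out = set()
    for tox in candidates:
        if tox.role != "toxin":
            continue
        for anti in candidates:
            if anti.role != "antitoxin":
                continue
            for variant in oracle_pair_variants(tox, anti):
                out.add((variant, tox.feature.feature_id, anti.feature.feature_id))
    return out


def oracle_links(loci, mges, flank_bp: int = 5000) -> set[tuple[str, str, str]]:
    """O(n*m) association predicate oracle: {(locus_id, mge_id, kind)}."""
    out = set()
    for l in loci:
        for m in mges:
            if l.replicon_id != m.replicon_id:
                continue
            if m.start <= l.start and l.end <= m.end:
                out.add((l.locus_id, m.mge_id, "harbored"))
            elif m.mge_class in ("IS_transposon", "IS_cluster"):
                gap = max(l.start, m.start) - min(l.end, m.end)
                if 0 <= gap < flank_bp:
                    out.add((l.locus_id, m.mge_id, "flanking_IS"))
    return out


def exact_jaccard(a: str, b: str, k: int = 21) -> float:
    """Exact canonical k-mer Jaccard by full enumeration."""
    comp = str.maketrans("ACGT", "TGCA")

    def kmers(s: str) -> set[str]:
        out = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) <= set("ACGT"):
                out.add(min(km, km.translate(comp)[::-1]))
        return out

    ka, kb = kmers(a), kmers(b)
    union = ka | kb
    return len(ka & kb) / len(union) if union else 0.0


# ---------------------------------------------------------------------------
# candidate / genome builders


def make_feature(
    fid: str,
    start: int,
    end: int,
    strand: str = "+",
    molecule: str = "protein_coding",
    replicon_id: str = "chr1",
    aa_len: int | None = None,
) -> GenomicFeature:
    translation = ""
    if molecule == "protein_coding":
        n = aa_len if aa_len is not None else max(10, (end - start) // 3 - 1)
        translation = "M" + "A" * (n - 1)
    return GenomicFeature(fid, replicon_id, start, end, strand, molecule, "", translation)


def make_candidate(
    fid: str,
    start: int,
    end: int,
    role: str,
    ta_type: str,
    strand: str = "+",
    family: str | None = None,
    h: float = 0.9,
    replicon_id: str = "chr1",
) -> Candidate:
    tox_mol, anti_mol = TA_MOLECULES[ta_type]
    mol = tox_mol if role == "toxin" else anti_mol
    molecule = "protein_coding" if mol == "protein" else "rna"
    feature = make_feature(fid, start, end, strand, molecule, replicon_id)
    if family is None:
        family = {"I": "hok-sok", "II": "relBE", "III": "toxIN", "IV": "cbtA-cbeA",
                  "V": "ghoST", "VI": "socAB", "VII": "hha-tomB", "VIII": "creTA"}[ta_type]
    hit = HomologyHit(fid, f"{family}_{role[0].upper()}", h, 1.0, 100.0, 1e-30)
    return Candidate(feature, role, ta_type, family, hit, "blast")


def random_candidates(seed: int, n_max: int = 50, replicon_len: int = 100_000) -> list[Candidate]:
    """A random candidate set for oracle-equivalence tests (<= n_max features)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    candidates = []
    types = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    for i in range(n):
        ta_type = types[rng.integers(len(types))]
        role = "toxin" if rng.random() < 0.5 else "antitoxin"
        family = ("creTA" if rng.random() < 0.5 else "sdsR-ryeA") if ta_type == "VIII" else None
        start = int(rng.integers(0, replicon_len - 2000))
        length = int(rng.integers(60, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        # cluster half of the features to make real pairings likely
        if i > 0 and rng.random() < 0.5:
            anchor = candidates[int(rng.integers(len(candidates)))].feature
            start = max(0, anchor.end + int(rng.integers(-300, 300)))
        candidates.append(
            make_candidate(
                f"f{i}", start, start + length, role, ta_type, strand, family,
                h=float(rng.uniform(0.4, 1.0)),
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# shared plans


def standard_plan(seed: int = 42) -> SimulationPlan:
    """The standard study fixture: ~200 kb, 8 planted loci, 5 planted MGEs,
    a chromosome plus a plasmid."""
    loci = [
        PlantedLocus("I", distance=50, strands=("+", "-")),
        PlantedLocus("II", distance=30),
        PlantedLocus("III", distance=40),
        PlantedLocus("IV", distance=65, order="antitoxin_first"),
        PlantedLocus("V", distance=0),
        PlantedLocus("VI", distance=150),
        PlantedLocus("VII", distance=-20),
        PlantedLocus("VIII", variant="VIII-creTA", distance=100, replicon=1),
    ]
    mges = [
        PlantedMGE("prophage", "harbored", anchor_locus=1),
        PlantedMGE("ICE", "harbored", anchor_locus=3),
        PlantedMGE("IS_transposon", "gap", anchor_locus=2, gap_bp=1000),
        PlantedMGE("IS_cluster", "gap", anchor_locus=5, gap_bp=4999),
        PlantedMGE("prophage", "copy", copy_of=0, identity=0.999),
    ]
    return SimulationPlan(
        seed=seed,
        replicons=[(180_000, "chromosome", "linear"), (20_000, "plasmid", "circular")],
        planted_loci=loci,
        planted_mges=mges,
        background_gene_density=0.5,
    )


@pytest.fixture(scope="session")
def refs():
    return fixture_references()


@pytest.fixture(scope="session")
def standard_bundle():
    from taloci.synthetic_data import generate

    return generate(standard_plan())
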