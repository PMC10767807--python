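"""Pairing toxin and antitoxin candidates into TA loci.

Each TA type has a pairing rule over strand configuration and intergenic
distance.  Distance is the gap between the nearest edges of the two gene
intervals; a negative distance of -n means n bp of overlap.  With 0-based
half-open intervals this is simply ``max(starts) - min(ends)``, which makes
the published windows directly expressible:

* types II-VII: same strand (operon-like tandem), distance in [-20, 150] bp;
* type I: protein toxin and antisense RNA antitoxin on opposite strands,
  distance <= 200 bp with no limit on overlap depth;
* type VIII creTA: RNA/RNA on the same or opposite strand, distance
  <= 200 bp;
* type VIII SdsR-RyeA: RNA/RNA on opposite strands, strictly overlapping
  (distance < 0 bp).

The rule table ships as ``data/rules.tsv`` so windows can be tightened or
loosened without code changes.  Pair enumeration is exhaustive: every
(toxin candidate, antitoxin candidate) pair of a type is tested against
the rule before any overlap resolution, and both gene orders are
admissible for the tandem types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from taloci.genome_io import GenomicFeature
from taloci.homology import TA_TYPES, Candidate

_MOLECULE_OF_FEATURE = {"protein_coding": "protein", "rna": "rna"}
_TYPE_ORDER = {t: i for i, t in enumerate(TA_TYPES)}


@dataclass(frozen=True)
class TARule:
    """Strand/distance constraints for one TA type (or type variant)."""

    ta_type: str
    variant: str
    toxin_molecule: str
    antitoxin_molecule: str
    strand_constraint: str  # same | opposite | either
    distance_min: int | None  # None = unbounded overlap
    distance_max: int | None  # inclusive upper bound; None = unbounded
    families: frozenset[str] | None = None  # None = any family

    def admits(self, toxin: Candidate, antitoxin: Candidate, distance: int) -> bool:
        """Does this rule admit the (toxin, antitoxin) pair at ``distance``?"""
        if toxin.ta_type != self.ta_type or antitoxin.ta_type != self.ta_type:
            return False
        if _MOLECULE_OF_FEATURE[toxin.feature.molecule] != self.toxin_molecule:
            return False
        if _MOLECULE_OF_FEATURE[antitoxin.feature.molecule] != self.antitoxin_molecule:
            return False
        if self.families is not None and toxin.family not in self.families:
            return False
        same = toxin.feature.strand == antitoxin.feature.strand
        if self.strand_constraint == "same" and not same:
            return False
        if self.strand_constraint == "opposite" and same:
            return False
        if self.distance_min is not None and distance < self.distance_min:
            return False
        if self.distance_max is not None and distance > self.distance_max:
            return False
        return True


@dataclass
class TALocus:
    """A called toxin + antitoxin pair with its type, family and score."""

    locus_id: str
    ta_type: str
    variant: str
    family: str
    toxin: Candidate
    antitoxin: Candidate
    distance: int
    score: float
    replicon_id: str
    family_conflict: bool = False

    @property
    def start(self) -> int:
        """Locus span start: min start over the two genes."""
        return min(self.toxin.feature.start, self.antitoxin.feature.start)

    @property
    def end(self) -> int:
        """Locus span end: max end over the two genes."""
        return max(self.toxin.feature.end, self.antitoxin.feature.end)


def load_rules(path: str | Path | None = None) -> list[TARule]:
    """Load the pairing rule table (bundled ``rules.tsv`` by default)."""
    if path is None:
        text = resources.files("taloci.data").joinpath("rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules: list[TARule] = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            continue
        row = dict(zip(header, cols))
        rules.append(
            TARule(
                ta_type=row["ta_type"],
                variant=row["variant"],
                toxin_molecule=row["toxin_molecule"],
                antitoxin_molecule=row["antitoxin_molecule"],
                strand_constraint=row["strand"],
                distance_min=None if row["dmin"] == "." else int(row["dmin"]),
                distance_max=None if row["dmax"] == "." else int(row["dmax"]),
                families=None if row["families"] == "." else frozenset(row["families"].split(",")),
            )
        )
    return rules


def intergenic_distance(a: GenomicFeature, b: GenomicFeature) -> int:
    """Gap between the nearest edges of two features; negative = overlap.

    Symmetric in its arguments.  Features must share a replicon.
    """
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"features on different replicons: {a.replicon_id!r} vs {b.replicon_id!r}"
        )
    return max(a.start, b.start) - min(a.end, b.end)


def locus_score(toxin: Candidate, antitoxin: Candidate) -> float:
    """Score of a pair: the weaker partner's H-value."""
    return min(toxin.h_value, antitoxin.h_value)


def call_loci(candidates: Sequence[Candidate], rules: Sequence[TARule] | None = None) -> list[TALocus]:
    """Exhaustively pair candidates into TA loci under the rule table.

    Every (toxin, antitoxin) candidate pair of the same type on the same
    replicon is tested against each matching rule; no greedy early exit.
    Pairs whose toxin and antitoxin evidence disagree on family are kept
    with the toxin's family and ``family_conflict=True``.
    """
    if rules is None:
        rules = load_rules()
    toxins = [c for c in candidates if c.role == "toxin"]
    antitoxins = [c for c in candidates if c.role == "antitoxin"]
    loci: list[TALocus] = []
    for rule in rules:
        for tox in toxins:
            for anti in antitoxins:
                if tox.feature.replicon_id != anti.feature.replicon_id:
                    continue
                if tox.feature.feature_id == anti.feature.feature_id:
                    continue
                d = intergenic_distance(tox.feature, anti.feature)
                if not rule.admits(tox, anti, d):
                    continue
                conflict = tox.family != anti.family
                locus_id = (
                    f"{tox.feature.replicon_id}:{tox.feature.feature_id}"
                    f"-{anti.feature.feature_id}:{rule.variant}"
                )
                loci.append(
                    TALocus(
                        locus_id=locus_id,
                        ta_type=rule.ta_type,
                        variant=rule.variant,
                        family=tox.family,
                        toxin=tox,
                        antitoxin=anti,
                        distance=d,
                        score=locus_score(tox, anti),
                        replicon_id=tox.feature.replicon_id,
                        family_conflict=conflict,
                    )
                )
    return loci


def resolve_overlaps(loci: Iterable[TALocus]) -> list[TALocus]:
    """Deduplicate loci that reuse the same (toxin, antitoxin) feature pair.

    Of competing calls on one feature pair, keep the highest score; break
    ties by lower type number, then lexicographic family, then variant.
    Loci sharing only one feature are all kept.  Output is sorted by
    (replicon_id, span start).
    """
    best: dict[tuple[str, str, str], TALocus] = {}
    for locus in loci:
        key = (locus.replicon_id, locus.toxin.feature.feature_id, locus.antitoxin.feature.feature_id)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = locus
            continue
        cand_rank = (-locus.score, _TYPE_ORDER[locus.ta_type], locus.family, locus.variant)
        inc_rank = (-incumbent.score, _TYPE_ORDER[incumbent.ta_type], incumbent.family, incumbent.variant)
        if cand_rank < inc_rank:
            best[key] = locus
    out = list(best.values())
    out.sort(key=lambda l: (l.replicon_id, l.start, l.end, l.locus_id))
    return out


LOCI_TSV_COLUMNS = [
    "locus_id",
    "replicon_id",
    "ta_type",
    "variant",
    "family",
    "toxin_id",
    "toxin_start",
    "toxin_end",
    "toxin_strand",
    "antitoxin_id",
    "antitoxin_start",
    "antitoxin_end",
    "antitoxin_strand",
    "distance",
    "score",
    "family_conflict",
]


def loci_to_tsv(loci: Sequence[TALocus], path: str | Path) -> None:
    """Write one row per locus (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(LOCI_TSV_COLUMNS) + "\n")
        for l in loci:
            t, a = l.toxin.feature, l.antitoxin.feature
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            l.locus_id,
                            l.replicon_id,
                            l.ta_type,
                            l.variant,
                            l.family,
                            t.feature_id,
                            t.start,
                            t.end,
                            t.strand,
                            a.feature_id,
                            a.start,
                            a.end,
                            a.strand,
                            l.distance,
                            f"{l.score:.6f}",
                            str(l.family_conflict).lower(),
                        ],
                    )
                )
                + "\n"
            )


@dataclass
class LocusRecord:
    """Lightweight locus span read back from a loci TSV (for stage chaining)."""

    locus_id: str
    replicon_id: str
    ta_type: str
    variant: str
    family: str
    start: int
    end: int
    score: float = 0.0
    extra: dict = field(default_factory=dict)


def read_loci_tsv(path: str | Path) -> list[LocusRecord]:
    records: list[LocusRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = set(LOCI_TSV_COLUMNS)
        missing = required - set(header)
        if missing:
            raise ValueError(f"loci TSV missing columns: {', '.join(sorted(missing))}")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            start = min(int(row["toxin_start"]), int(row["antitoxin_start"]))
            end = max(int(row["toxin_end"]), int(row["antitoxin_end"]))
            records.append(
                LocusRecord(
                    row["locus_id"],
                    row["replicon_id"],
                    row["ta_type"],
                    row["variant"],
                    row["family"],
                    start,
                    end,
                    float(row["score"]),
                    extra=row,
                )
            )
    return records
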