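"""TA locus <-> mobile genetic element association by genomic location.

A TA-associated MGE is an MGE that harbours a TA locus (the locus span
lies fully inside the element), or an IS/transposon flanked by a TA locus
at an edge-to-edge interval strictly below 5 kbp.  Plasmids are MGEs in
their own right: every locus on a plasmid replicon is harboured by it.
Each qualifying (locus, MGE) pair yields its own link - a locus inside an
ICE that is also 1 kb from an IS produces two links, counted separately
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Protocol, Sequence

from taloci.config import DEFAULT_FLANK_BP
from taloci.genome_io import AnnotatedGenome, FormatError

MGE_CLASSES = (
    "prophage",
    "genomic_island",
    "ICE",
    "integron",
    "IS_transposon",
    "IS_cluster",
    "plasmid",
)

#: MGE classes that may associate by flanking distance (all others only harbour).
FLANKING_CLASSES = frozenset({"IS_transposon", "IS_cluster"})


class LocusLike(Protocol):
    """Anything with a locus id, replicon and 0-based half-open span."""

    locus_id: str
    replicon_id: str
    start: int
    end: int


@dataclass
class MGEAnnotation:
    """A mobile genetic element interval with its class label."""

    mge_id: str
    replicon_id: str
    start: int
    end: int
    mge_class: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.mge_class not in MGE_CLASSES:
            raise FormatError(
                f"unknown MGE class {self.mge_class!r}; allowed: {', '.join(MGE_CLASSES)}"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(f"MGE {self.mge_id!r}: invalid interval [{self.start},{self.end})")


@dataclass
class TAMGELink:
    """A typed association edge between a TA locus and an MGE."""

    locus_id: str
    mge_id: str
    link_kind: Literal["harbored", "flanking_IS"]
    gap: int  # bp between nearest edges; 0 for harbored


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two intervals; negative on overlap."""
    return max(a_start, b_start) - min(a_end, b_end)


def associate(
    loci: Sequence[LocusLike],
    mges: Sequence[MGEAnnotation],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[TAMGELink]:
    """Compute all TA-MGE links.

    ``harbored``: the locus span lies fully within the MGE interval (a
    locus straddling an MGE edge is not harboured).  ``flanking_IS``: no
    containment, the MGE is an IS/transposon or IS cluster, and the
    edge-to-edge gap satisfies 0 <= gap < ``flank_bp`` (strict; a 5000 bp
    gap does not qualify at the default).  Every qualifying pair emits its
    own link.
    """
    mge_replicons = {m.replicon_id for m in mges}
    locus_replicons = {l.replicon_id for l in loci}
    # Plasmid MGEs cover whole replicons, so any shared-replicon check is
    # only advisory; unknown ids surface as zero links, which is correct.
    links: list[TAMGELink] = []
    for locus in loci:
        for mge in mges:
            if locus.replicon_id != mge.replicon_id:
                continue
            if mge.start <= locus.start and locus.end <= mge.end:
                links.append(TAMGELink(locus.locus_id, mge.mge_id, "harbored", 0))
                continue
            if mge.mge_class not in FLANKING_CLASSES:
                continue
            gap = _span_gap(locus.start, locus.end, mge.start, mge.end)
            if 0 <= gap < flank_bp:
                links.append(TAMGELink(locus.locus_id, mge.mge_id, "flanking_IS", gap))
    _ = mge_replicons, locus_replicons
    return links


def plasmid_mges(genome: AnnotatedGenome) -> list[MGEAnnotation]:
    """One whole-replicon MGE per plasmid replicon of the genome."""
    return [
        MGEAnnotation(f"plasmid:{rep.id}", rep.id, 0, len(rep), "plasmid", rep.sequence)
        for rep in genome.replicons
        if rep.kind == "plasmid"
    ]


def read_mge_table(path: str | Path, genome: AnnotatedGenome | None = None) -> list[MGEAnnotation]:
    """Read MGE intervals from a headered TSV (1-based inclusive coordinates).

    Columns: mge_id, replicon_id, start, end, class.  When a genome is
    given, each element's nucleotide span is extracted into ``sequence``
    (used for MinHash sketching).
    """
    path = Path(path)
    mges: list[MGEAnnotation] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\n").split("\t")
        required = {"mge_id", "replicon_id", "start", "end", "class"}
        missing = required - set(header)
        if missing:
            raise FormatError(f"MGE table missing columns: {', '.join(sorted(missing))}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip() or line.startswith("#"):
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                start1, end1 = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            seq = ""
            if genome is not None:
                try:
                    seq = genome.replicon(row["replicon_id"]).sequence[start1 - 1 : end1]
                except KeyError:
                    pass
            mges.append(
                MGEAnnotation(row["mge_id"], row["replicon_id"], start1 - 1, end1, row["class"], seq)
            )
    return mges


def write_mge_table(mges: Sequence[MGEAnnotation], path: str | Path) -> None:
    """Write MGE intervals as a TSV in 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("mge_id\treplicon_id\tstart\tend\tclass\n")
        for m in mges:
            fh.write(f"{m.mge_id}\t{m.replicon_id}\t{m.start + 1}\t{m.end}\t{m.mge_class}\n")


def links_to_tsv(
    links: Iterable[TAMGELink], mges: Sequence[MGEAnnotation], path: str | Path
) -> None:
    class_of = {m.mge_id: m.mge_class for m in mges}
    with open(path, "w") as fh:
        fh.write("locus_id\tmge_id\tmge_class\tlink_kind\tgap\n")
        for link in links:
            fh.write(
                f"{link.locus_id}\t{link.mge_id}\t{class_of.get(link.mge_id, '?')}\t"
                f"{link.link_kind}\t{link.gap}\n"
            )


def read_links_tsv(path: str | Path) -> list[tuple[TAMGELink, str]]:
    """Read (link, mge_class) rows back from a links TSV."""
    out: list[tuple[TAMGELink, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"locus_id", "mge_id", "mge_class", "link_kind", "gap"}
        missing = required - set(header)
        if missing:
            raise ValueError(f"links TSV missing columns: {', '.join(sorted(missing))}")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                (
                    TAMGELink(row["locus_id"], row["mge_id"], row["link_kind"], int(row["gap"])),  # type: ignore[arg-type]
                    row["mge_class"],
                )
            )
    return out
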