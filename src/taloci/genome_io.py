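"""Reading and writing annotated replicons with one internal coordinate convention.

Everything downstream of this module sees 0-based half-open ``[start, end)``
intervals on explicitly stranded features.  GenBank and GFF3 use 1-based
inclusive coordinates; the conversion happens here, at the I/O boundary,
and nowhere else.

Circular replicons are read but treated as linear for all distance
computations: gene pairs are never formed across the origin.  Compound
(joined) CDS locations collapse to their outer span; the translation is
taken from the annotation (or conceptually translated from the joined
segments) so that a gene contributes exactly one interval to pair calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

Strand = Literal["+", "-"]

#: GFF3/GenBank feature types mapped to the internal ``rna`` molecule kind.
RNA_FEATURE_TYPES = {"ncRNA", "misc_RNA", "sRNA", "antisense_RNA", "tmRNA"}


class FormatError(ValueError):
    """Raised for unparseable or inconsistent input files."""


@dataclass
class Replicon:
    """One chromosome or plasmid: id, uppercase sequence, topology and kind.

    ``kind`` matters downstream: a plasmid replicon is itself a mobile
    genetic element, so every TA locus on it is MGE-associated by default.
    """

    id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    kind: Literal["chromosome", "plasmid"] = "chromosome"
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("replicon id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"replicon {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomicFeature:
    """A located, stranded CDS or RNA feature; the unit paired into TA loci.

    Coordinates are 0-based half-open.  ``molecule`` is ``protein_coding``
    (with a non-empty amino-acid ``translation``) or ``rna``.
    """

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: Strand
    molecule: Literal["protein_coding", "rna"]
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand must be '+' or '-'")
        if self.molecule == "protein_coding" and not self.translation:
            raise ValueError(f"protein_coding feature {self.feature_id!r} lacks a translation")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Replicons plus their features, kept sorted by (replicon_id, start)."""

    replicons: list[Replicon] = field(default_factory=list)
    features: list[GenomicFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate replicon ids")
        known = set(ids)
        for f in self.features:
            if f.replicon_id not in known:
                raise ValueError(f"feature {f.feature_id!r} references unknown replicon {f.replicon_id!r}")
            rep = self.replicon(f.replicon_id)
            if f.end > len(rep):
                raise ValueError(f"feature {f.feature_id!r} extends past replicon end")
        self._sort()

    def _sort(self) -> None:
        self.features.sort(key=lambda f: (f.replicon_id, f.start, f.end))

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def add_feature(self, feature: GenomicFeature) -> None:
        if feature.replicon_id not in {r.id for r in self.replicons}:
            raise ValueError(f"unknown replicon {feature.replicon_id!r}")
        self.features.append(feature)
        self._sort()

    def proteins(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.molecule == "protein_coding"]

    def rnas(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.molecule == "rna"]


def _translate_cds(dna: str, strand: Strand) -> str:
    """Conceptual translation (table 11), truncated at the first internal stop."""
    seq = Seq(dna)
    if strand == "-":
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn("internal stop codon in forced translation; truncating", stacklevel=3)
        aa = aa.split("*", 1)[0]
    return aa


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    One :class:`Replicon` per record.  CDS features become
    ``protein_coding`` (translation from the ``/translation`` qualifier,
    else conceptual translation with the bacterial code, table 11);
    ncRNA/misc_RNA-style features become ``rna``.  GenBank's 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"unparseable GenBank file {path}: {exc}") from exc
    if not records:
        raise FormatError(f"GenBank file {path} contains no records")

    replicons: list[Replicon] = []
    features: list[GenomicFeature] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has no sequence")
        topology = "circular" if rec.annotations.get("topology") == "circular" else "linear"
        descr = (rec.description or "").lower()
        kind = "plasmid" if "plasmid" in descr else "chromosome"
        organism = rec.annotations.get("organism", "")
        replicons.append(Replicon(rec.id, seq, topology=topology, kind=kind, organism=organism))
        counter = 0
        for feat in rec.features:
            if feat.type == "CDS":
                molecule = "protein_coding"
            elif feat.type in RNA_FEATURE_TYPES:
                molecule = "rna"
            else:
                continue
            counter += 1
            # Biopython locations are already 0-based half-open; compound
            # locations collapse to the outer span.
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand: Strand = "-" if feat.location.strand == -1 else "+"
            fid = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("gene", [None])[0]
                or f"{rec.id}_f{counter}"
            )
            product = feat.qualifiers.get("product", [""])[0]
            translation = ""
            if molecule == "protein_coding":
                translation = feat.qualifiers.get("translation", [""])[0]
                if not translation:
                    translation = _translate_cds(str(feat.extract(rec.seq)), "+")
            features.append(
                GenomicFeature(fid, rec.id, start, end, strand, molecule, product, translation)
            )
    return AnnotatedGenome(replicons, features)


def _parse_gff_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_fasta_gff(fasta: str | Path, gff: str | Path) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an :class:`AnnotatedGenome`.

    CDS rows are conceptually translated from the sequence (table 11);
    ncRNA/sRNA-style rows map to ``rna``.  All GFF3 seqids must resolve in
    the FASTA, else a :class:`FormatError` lists the missing ids.
    """
    fasta, gff = Path(fasta), Path(gff)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if not seqs:
        raise FormatError(f"FASTA file {fasta} contains no sequences")

    replicon_meta: dict[str, dict[str, str]] = {}
    rows: list[tuple[str, str, int, int, Strand, dict[str, str]]] = []
    missing: set[str] = set()
    with open(gff) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{gff}:{lineno}: expected 9 tab-separated columns")
            seqid, _, ftype, start_s, end_s, _, strand_s, _, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{gff}:{lineno}: non-integer coordinates") from exc
            if start1 > end1:
                raise FormatError(f"{gff}:{lineno}: start > end")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "region":
                replicon_meta[seqid] = attrs
                continue
            if ftype == "CDS":
                pass
            elif ftype in RNA_FEATURE_TYPES:
                pass
            else:
                continue
            if seqid not in seqs:
                missing.add(seqid)
                continue
            strand: Strand = "-" if strand_s == "-" else "+"
            rows.append((seqid, ftype, start1 - 1, end1, strand, attrs))
    if missing:
        raise FormatError(f"GFF3 seqids missing from FASTA: {', '.join(sorted(missing))}")

    replicons = []
    for rid, seq in seqs.items():
        meta = replicon_meta.get(rid, {})
        replicons.append(
            Replicon(
                rid,
                seq,
                topology="circular" if meta.get("Is_circular") == "true" else "linear",
                kind="plasmid" if meta.get("genome") == "plasmid" else "chromosome",
                organism=meta.get("organism", ""),
            )
        )
    features = []
    for i, (rid, ftype, start, end, strand, attrs) in enumerate(rows, 1):
        fid = attrs.get("ID") or attrs.get("locus_tag") or f"{rid}_f{i}"
        product = attrs.get("product", "")
        if ftype == "CDS":
            translation = _translate_cds(seqs[rid][start:end], strand)
            features.append(
                GenomicFeature(fid, rid, start, end, strand, "protein_coding", product, translation)
            )
        else:
            features.append(GenomicFeature(fid, rid, start, end, strand, "rna", product))
    return AnnotatedGenome(replicons, features)


def write_predictions_gff(loci: Iterable, path: str | Path) -> None:
    """Write called TA loci as GFF3: one row per toxin and per antitoxin.

    Rows of one locus share a ``locus`` attribute; coordinates go back to
    1-based inclusive; attributes carry TA type, family and H-values.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for locus in loci:
        for role, cand in (("toxin", locus.toxin), ("antitoxin", locus.antitoxin)):
            f = cand.feature
            ftype = "CDS" if f.molecule == "protein_coding" else "ncRNA"
            attrs = (
                f"ID={f.feature_id};locus={locus.locus_id};ta_role={role};"
                f"ta_type={locus.ta_type};ta_family={locus.family};"
                f"h_value={cand.h_value:.4f}"
            )
            lines.append(
                "\t".join(
                    [
                        f.replicon_id,
                        "taloci",
                        ftype,
                        str(f.start + 1),
                        str(f.end),
                        f"{locus.score:.4f}",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an :class:`AnnotatedGenome` as a GenBank flat file.

    Translations are emitted as ``/translation`` qualifiers so that a
    read/write round trip preserves them exactly, including for genes whose
    annotated protein differs from the conceptual translation (e.g.
    overlapping gene pairs in synthetic genomes).
    """
    records = []
    for rep in genome.replicons:
        rec = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16], description=rep.kind)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["organism"] = rep.organism
        if rep.kind == "plasmid":
            rec.description = f"{rep.organism} plasmid {rep.id}".strip()
        for f in genome.features:
            if f.replicon_id != rep.id:
                continue
            loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
            qualifiers: dict[str, list[str]] = {"locus_tag": [f.feature_id]}
            if f.product:
                qualifiers["product"] = [f.product]
            if f.molecule == "protein_coding":
                qualifiers["translation"] = [f.translation]
                rec.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
            else:
                rec.features.append(SeqFeature(loc, type="ncRNA", qualifiers=qualifiers))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")
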