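"""Coordinate conventions, format round trips and I/O error handling."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from taloci import genome_io
from taloci.genome_io import (
    AnnotatedGenome,
    FormatError,
    GenomicFeature,
    Replicon,
    read_fasta_gff,
    read_genbank,
    write_genbank,
    write_predictions_gff,
)
from tests.conftest import make_candidate, standard_plan


def _write_gbk(tmp_path, features, seq_len=400, name="t.gbk"):
    rec = SeqRecord(Seq("ACGT" * (seq_len // 4)), id="chr1", name="chr1", description="test")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = features
    path = tmp_path / name
    seqio_write([rec], str(path), "genbank")
    return path


@pytest.mark.parametrize(
    "strand_num, expected_strand",
    [(1, "+"), (-1, "-")],
)
def test_genbank_coordinates_become_zero_based_half_open(tmp_path, strand_num, expected_strand):
    """A GenBank CDS at 101..200 (or its complement) maps to [100, 200)."""
    feat = SeqFeature(
        FeatureLocation(100, 200, strand=strand_num),
        type="CDS",
        qualifiers={"locus_tag": ["g1"], "translation": ["M" + "A" * 32]},
    )
    genome = read_genbank(_write_gbk(tmp_path, [feat]))
    (f,) = genome.features
    assert (f.start, f.end, f.strand) == (100, 200, expected_strand)
    assert f.molecule == "protein_coding"


def test_genbank_rna_feature_and_conceptual_translation(tmp_path):
    rna = SeqFeature(FeatureLocation(10, 80, strand=1), type="ncRNA", qualifiers={"locus_tag": ["r1"]})
    cds = SeqFeature(FeatureLocation(100, 160, strand=1), type="CDS", qualifiers={"locus_tag": ["g1"]})
    genome = read_genbank(_write_gbk(tmp_path, [rna, cds]))
    by_id = {f.feature_id: f for f in genome.features}
    assert by_id["r1"].molecule == "rna"
    # no /translation qualifier: conceptual translation, 60 nt -> 20 aa
    assert by_id["g1"].molecule == "protein_coding"
    assert len(by_id["g1"].translation) == 20


def test_empty_genbank_is_a_format_error(tmp_path):
    empty = tmp_path / "empty.gbk"
    empty.write_text("")
    with pytest.raises(FormatError):
        read_genbank(empty)


def test_fasta_gff_reading(tmp_path):
    (tmp_path / "g.fasta").write_text(">chr1\n" + "ATGGCTGCAGCTGCCGCGTAA" * 20 + "\n")
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\tsrc\tCDS\t1\t21\t.\t+\t0\tID=c1",
            "chr1\tsrc\tCDS\t43\t63\t.\t-\t0\tID=c2",
            "chr1\tsrc\tncRNA\t100\t160\t.\t+\t.\tID=n1",
        ]
    )
    (tmp_path / "g.gff").write_text(gff + "\n")
    genome = read_fasta_gff(tmp_path / "g.fasta", tmp_path / "g.gff")
    assert len(genome.features) == 3
    by_id = {f.feature_id: f for f in genome.features}
    assert by_id["c1"].start == 0 and by_id["c1"].end == 21
    assert by_id["c1"].translation.startswith("MAA")
    assert by_id["n1"].molecule == "rna"


def test_fasta_gff_errors(tmp_path):
    (tmp_path / "g.fasta").write_text(">chr1\nACGTACGTACGT\n")
    (tmp_path / "bad_seqid.gff").write_text("chrX\tsrc\tCDS\t1\t6\t.\t+\t0\tID=c1\n")
    with pytest.raises(FormatError, match="chrX"):
        read_fasta_gff(tmp_path / "g.fasta", tmp_path / "bad_seqid.gff")
    (tmp_path / "bad_coord.gff").write_text("chr1\tsrc\tCDS\t9\t3\t.\t+\t0\tID=c1\n")
    with pytest.raises(FormatError, match="start > end"):
        read_fasta_gff(tmp_path / "g.fasta", tmp_path / "bad_coord.gff")


def test_prediction_gff_written_one_based(tmp_path):
    """A toxin at [100, 200) prints as GFF3 start=101 end=200; rows of one
    locus share a locus attribute; an empty list still yields a header."""
    from taloci.caller import call_loci, load_rules

    tox = make_candidate("t1", 100, 200, "toxin", "II")
    anti = make_candidate("a1", 230, 330, "antitoxin", "II")
    (locus,) = call_loci([tox, anti], load_rules())
    path = tmp_path / "out.gff3"
    write_predictions_gff([locus], path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    assert len(lines) == 3
    cols = lines[1].split("\t")
    assert (cols[3], cols[4]) == ("101", "200")
    assert "locus=" in cols[8] and "ta_type=II" in cols[8]

    write_predictions_gff([], path)
    assert path.read_text().splitlines() == ["##gff-version 3"]


def test_genbank_round_trip_preserves_every_feature(tmp_path):
    """write_genbank -> read_genbank preserves coordinates, strands,
    molecules and translations exactly, plus replicon kind/organism."""
    from taloci.synthetic_data import generate

    genome, _, _, _ = generate(standard_plan(seed=7))
    path = tmp_path / "g.gbk"
    write_genbank(genome, path)
    back = read_genbank(path)
    assert [r.id for r in back.replicons] == [r.id for r in genome.replicons]
    assert [r.kind for r in back.replicons] == [r.kind for r in genome.replicons]
    assert [r.sequence for r in back.replicons] == [r.sequence for r in genome.replicons]
    key = lambda f: (f.replicon_id, f.start, f.end, f.strand, f.molecule, f.translation)
    assert sorted(map(key, back.features)) == sorted(map(key, genome.features))


def test_feature_and_genome_invariants():
    with pytest.raises(ValueError):
        GenomicFeature("f", "r", 50, 50, "+", "rna")
    with pytest.raises(ValueError):
        GenomicFeature("f", "r", 0, 30, "+", "protein_coding")  # no translation
    with pytest.raises(ValueError):
        AnnotatedGenome([Replicon("r1", "ACGT")], [GenomicFeature("f", "rX", 0, 2, "+", "rna")])
    genome = AnnotatedGenome([Replicon("r1", "ACGT" * 100)], [])
    genome.add_feature(GenomicFeature("b", "r1", 50, 90, "+", "rna"))
    genome.add_feature(GenomicFeature("a", "r1", 10, 40, "+", "rna"))
    assert [f.feature_id for f in genome.features] == ["a", "b"]  # kept sorted


def test_all_generated_features_stay_zero_based_in_bounds(standard_bundle):
    """Downstream code only ever sees 0-based half-open in-bounds intervals."""
    genome, _, mges, _ = standard_bundle
    for f in genome.features:
        assert 0 <= f.start < f.end <= len(genome.replicon(f.replicon_id))
    for m in mges:
        assert 0 <= m.start < m.end <= len(genome.replicon(m.replicon_id))
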