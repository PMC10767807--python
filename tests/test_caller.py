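"""Type-specific pairing rules, distance convention, overlap resolution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taloci.caller import (
    call_loci,
    intergenic_distance,
    load_rules,
    loci_to_tsv,
    read_loci_tsv,
    resolve_overlaps,
)
from tests.conftest import make_candidate, make_feature, oracle_call, random_candidates

RULES = load_rules()


class TestIntergenicDistance:
    @pytest.mark.parametrize(
        "a_span, b_span, expected",
        [
            ((100, 200), (350, 450), 150),  # upper edge of the tandem window
            ((100, 200), (180, 300), -20),  # 20 bp overlap = lower edge
            ((100, 200), (100, 200), -100),  # full overlap
            ((100, 200), (200, 300), 0),  # abutting genes
        ],
    )
    def test_edge_gap_convention(self, a_span, b_span, expected):
        a = make_feature("a", *a_span)
        b = make_feature("b", *b_span)
        assert intergenic_distance(a, b) == expected
        assert intergenic_distance(b, a) == expected  # symmetric

    def test_cross_replicon_is_an_error(self):
        a = make_feature("a", 0, 100, replicon_id="chr1")
        b = make_feature("b", 0, 100, replicon_id="chr2")
        with pytest.raises(ValueError):
            intergenic_distance(a, b)

    @given(st.integers(0, 5000), st.integers(1, 800), st.integers(0, 5000), st.integers(1, 800))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_property(self, s1, l1, s2, l2):
        a = make_feature("a", s1, s1 + l1)
        b = make_feature("b", s2, s2 + l2)
        assert intergenic_distance(a, b) == intergenic_distance(b, a)


def _pair(ta_type, distance, strands=("+", "+"), family=None, order="toxin_first", h=0.9):
    """Toxin gene [1000,1300) and a partner at the requested edge gap."""
    t0, t1 = 1000, 1300
    a0 = t1 + distance
    a1 = a0 + 230
    tox_span, anti_span = ((t0, t1), (a0, a1)) if order == "toxin_first" else ((a0, a1), (t0, t1))
    tox = make_candidate("tox", *tox_span, "toxin", ta_type, strands[0], family, h=h)
    anti = make_candidate("anti", *anti_span, "antitoxin", ta_type, strands[1], family, h=h)
    return [tox, anti]


class TestCallLoci:
    def test_type_ii_tandem_pair_called(self):
        (locus,) = call_loci(_pair("II", 30), RULES)
        assert locus.ta_type == "II" and locus.distance == 30
        assert locus.score == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "ta_type, distance, strands, called",
        [
            ("II", 150, ("+", "+"), True),  # window edges for tandem types
            ("II", 151, ("+", "+"), False),
            ("II", -20, ("+", "+"), True),
            ("II", -21, ("+", "+"), False),
            ("II", 30, ("+", "-"), False),  # tandem types need the same strand
            ("I", 200, ("+", "-"), True),  # type I distance ceiling
            ("I", 201, ("+", "-"), False),
            ("I", -100, ("+", "-"), True),  # overlap depth unlimited
            ("I", 50, ("+", "+"), False),  # type I needs opposite strands
        ],
    )
    def test_window_boundaries(self, ta_type, distance, strands, called):
        loci = call_loci(_pair(ta_type, distance, strands), RULES)
        assert (len(loci) == 1) is called

    @pytest.mark.parametrize(
        "family, distance, strands, called, variant",
        [
            ("creTA", 200, ("+", "+"), True, "VIII-creTA"),
            ("creTA", 200, ("+", "-"), True, "VIII-creTA"),  # either strand
            ("creTA", 201, ("+", "+"), False, None),
            ("sdsR-ryeA", -1, ("+", "-"), True, "VIII-sdsr"),
            ("sdsR-ryeA", -10, ("-", "+"), True, "VIII-sdsr"),
            ("sdsR-ryeA", 0, ("+", "-"), False, None),  # must strictly overlap
            ("sdsR-ryeA", -10, ("+", "+"), False, None),  # and be antisense
        ],
    )
    def test_type_viii_variants(self, family, distance, strands, called, variant):
        loci = call_loci(_pair("VIII", distance, strands, family=family), RULES)
        assert (len(loci) == 1) is called
        if called:
            assert loci[0].variant == variant

    def test_both_gene_orders_admissible_for_tandem_types(self):
        for order in ("toxin_first", "antitoxin_first"):
            (locus,) = call_loci(_pair("IV", 40, order=order), RULES)
            assert locus.ta_type == "IV"

    def test_family_conflict_is_flagged_not_dropped(self):
        tox = make_candidate("tox", 1000, 1300, "toxin", "II", family="relBE")
        anti = make_candidate("anti", 1330, 1560, "antitoxin", "II", family="mazEF")
        (locus,) = call_loci([tox, anti], RULES)
        assert locus.family == "relBE" and locus.family_conflict

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_pair_oracle(self, seed):
        """call_loci equals a brute-force double loop applying the published
        windows on random candidate sets."""
        candidates = random_candidates(seed)
        got = {(l.variant, l.toxin.feature.feature_id, l.antitoxin.feature.feature_id)
               for l in call_loci(candidates, RULES)}
        assert got == oracle_call(candidates)

    def test_mirror_symmetry(self):
        """Reverse-complementing the replicon (mirroring coordinates and
        flipping strands) yields the same loci, mirrored."""
        L = 100_000
        candidates = random_candidates(4)
        flip = {"+": "-", "-": "+"}
        mirrored = []
        for c in candidates:
            f = c.feature
            mf = make_feature(f.feature_id, L - f.end, L - f.start, flip[f.strand], f.molecule)
            mirrored.append(type(c)(mf, c.role, c.ta_type, c.family, c.best_hit, c.evidence_kind))
        key = lambda loci: sorted((l.variant, l.toxin.feature.feature_id, l.antitoxin.feature.feature_id, l.distance) for l in loci)
        assert key(call_loci(candidates, RULES)) == key(call_loci(mirrored, RULES))


class TestResolveOverlaps:
    def test_same_pair_keeps_best_score(self):
        tox = make_candidate("tox", 1000, 1300, "toxin", "II", family="relBE", h=0.9)
        anti = make_candidate("anti", 1330, 1560, "antitoxin", "II", family="relBE", h=0.9)
        strong = call_loci([tox, anti], RULES)[0]
        weak_tox = make_candidate("tox", 1000, 1300, "toxin", "II", family="higBA", h=0.5)
        weak = call_loci([weak_tox, make_candidate("anti", 1330, 1560, "antitoxin", "II", family="higBA", h=0.5)], RULES)[0]
        resolved = resolve_overlaps([strong, weak])
        assert len(resolved) == 1 and resolved[0].family == "relBE"

    def test_shared_single_feature_keeps_both(self):
        anti = make_candidate("anti", 2000, 2230, "antitoxin", "II")
        tox1 = make_candidate("tox1", 1700, 1980, "toxin", "II")
        tox2 = make_candidate("tox2", 2260, 2500, "toxin", "II")
        loci = call_loci([anti, tox1, tox2], RULES)
        assert len(resolve_overlaps(loci)) == 2

    def test_empty_input(self):
        assert resolve_overlaps([]) == []

    def test_output_sorted_by_position(self):
        c = []
        for i, start in enumerate((9000, 1000, 5000)):
            c += [
                make_candidate(f"t{i}", start, start + 280, "toxin", "II"),
                make_candidate(f"a{i}", start + 300, start + 520, "antitoxin", "II"),
            ]
        resolved = resolve_overlaps(call_loci(c, RULES))
        assert [l.start for l in resolved] == sorted(l.start for l in resolved)


def test_loci_tsv_round_trip(tmp_path):
    cands = _pair("II", 30)
    loci = resolve_overlaps(call_loci(cands, RULES))
    path = tmp_path / "loci.tsv"
    loci_to_tsv(loci, path)
    (rec,) = read_loci_tsv(path)
    assert rec.ta_type == "II" and (rec.start, rec.end) == (loci[0].start, loci[0].end)
    # missing columns are reported by name
    (tmp_path / "bad.tsv").write_text("locus_id\treplicon_id\n")
    with pytest.raises(ValueError, match="toxin_start"):
        read_loci_tsv(tmp_path / "bad.tsv")


def test_rule_table_encodes_published_windows():
    by_variant = {r.variant: r for r in RULES}
    assert (by_variant["II"].distance_min, by_variant["II"].distance_max) == (-20, 150)
    assert all(by_variant[v].strand_constraint == "same" for v in ("II", "III", "IV", "V", "VI", "VII"))
    assert by_variant["I"].strand_constraint == "opposite"
    assert by_variant["I"].distance_min is None and by_variant["I"].distance_max == 200
    assert by_variant["VIII-creTA"].strand_constraint == "either"
    assert by_variant["VIII-sdsr"].distance_max == -1  # strict 'distance < 0' over integer bp
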