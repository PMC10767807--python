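"""H-value filtering, alignment searches and domain scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taloci import homology
from taloci.genome_io import AnnotatedGenome, FormatError, GenomicFeature, Replicon
from taloci.homology import (
    HomologyHit,
    ReferenceEntry,
    build_candidates,
    h_value,
    passes_h,
    scan_domains,
    search_protein,
    search_rna,
)
from taloci.synthetic_data import _revcomp, mutate_to_identity
from tests.conftest import dp_local_score, make_feature

AA = "ACDEFGHIKLMNPQRSTVWY"


def _genome_with_proteins(translations: dict[str, str]) -> AnnotatedGenome:
    features = []
    pos = 100
    for fid, aa in translations.items():
        end = pos + 3 * len(aa)
        features.append(GenomicFeature(fid, "chr1", pos, end, "+", "protein_coding", "", aa))
        pos = end + 500
    return AnnotatedGenome([Replicon("chr1", "ACGT" * ((pos + 400) // 4 + 1))], features)


class TestHValue:
    def test_identity_cases_and_boundary(self):
        assert h_value(1.0, 1.0) == 1.0
        assert h_value(0.9, 0.5) == pytest.approx(0.45)
        # 60% identity x 60% coverage sits exactly on the cut-off and fails
        assert not passes_h(h_value(0.6, 0.6))
        assert passes_h(h_value(0.9, 0.5))
        assert passes_h(0.37) and not passes_h(0.36)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2), (2.0, 2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            h_value(*bad)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_product_stays_in_unit_interval(self, ident, cov):
        assert 0.0 <= h_value(ident, cov) <= 1.0


class TestProteinSearch:
    def test_planted_reference_is_a_perfect_self_hit(self, refs):
        ref = next(r for r in refs if r.molecule == "protein" and r.role == "toxin")
        genome = _genome_with_proteins({"g1": ref.sequence})
        hits = search_protein(genome, refs)
        best = max((h for h in hits if h.ref_id == ref.ref_id), key=lambda h: h.h_value)
        assert best.identity == 1.0 and best.query_coverage == 1.0 and best.h_value == 1.0

    def test_shuffled_sequence_gives_no_hit_at_ceiling(self, refs):
        ref = next(r for r in refs if r.ref_id == "vapBC_T")  # 132 aa
        rng = np.random.default_rng(11)
        shuffled = "".join(rng.permutation(list(ref.sequence)))
        genome = _genome_with_proteins({"g1": shuffled})
        hits = search_protein(genome, [ref])
        assert hits == []

    def test_half_length_chimera_has_half_coverage(self, refs):
        """A feature carrying the first half of a 100-residue reference at
        80% identity aligns over ~50 columns: coverage 0.5, H ~= 0.40."""
        rng = np.random.default_rng(5)
        ref_seq = "M" + "".join(rng.choice(list(AA), size=99))
        ref = ReferenceEntry("half_T", "toxin", "II", "halfFam", "protein", ref_seq)
        half = list(ref_seq[:50])
        for pos in rng.choice(np.arange(3, 47), size=10, replace=False):  # interior, ends intact
            half[pos] = next(c for c in AA if c != half[pos])
        tail = "".join(rng.choice(list("PG"), size=50))  # low-complexity, non-matching
        genome = _genome_with_proteins({"g1": "".join(half) + tail})
        (hit,) = search_protein(genome, [ref])
        assert hit.query_coverage == pytest.approx(0.5, abs=0.01)
        assert hit.identity == pytest.approx(0.8, abs=0.02)
        assert hit.h_value == pytest.approx(0.40, abs=0.02)

    def test_empty_reference_set_is_a_config_error(self):
        genome = _genome_with_proteins({"g1": "M" + "A" * 40})
        with pytest.raises(homology.ConfigError):
            search_protein(genome, [])

    def test_aligner_score_matches_dp_oracle(self):
        """The production local aligner agrees exactly with a hand-written
        Gotoh dynamic-programming oracle."""
        aligner = homology.make_protein_aligner()
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(20, 120))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(20, 120))))
            assert aligner.score(a, b) == pytest.approx(dp_local_score(a, b))


class TestRnaSearch:
    def _genome_with_rna(self, rna: str, strand: str, annotate: bool = False) -> AnnotatedGenome:
        rng = np.random.default_rng(17)
        background = "".join(rng.choice(list("ACGT"), size=4000))
        payload = rna if strand == "+" else _revcomp(rna)
        seq = background[:1500] + payload + background[1500 + len(rna) :]
        features = []
        if annotate:
            features.append(GenomicFeature("r1", "chr1", 1500, 1500 + len(rna), strand, "rna"))
        return AnnotatedGenome([Replicon("chr1", seq)], features)

    def test_exact_copy_found_on_minus_strand(self, refs):
        ref = next(r for r in refs if r.molecule == "rna" and r.ta_type == "I")
        genome = self._genome_with_rna(ref.sequence, "-")
        hits = search_rna(genome, [ref])
        assert len(hits) == 1 and hits[0].identity == 1.0
        feat = next(f for f in genome.features if f.feature_id == hits[0].feature_id)
        assert (feat.start, feat.end, feat.strand) == (1500, 1500 + len(ref.sequence), "-")

    def test_reverse_complement_symmetry(self, refs):
        """Forward and reverse-complement placements are detected identically,
        on opposite strands."""
        ref = next(r for r in refs if r.ref_id == "creTA_T")
        fwd = self._genome_with_rna(ref.sequence, "+")
        rev = self._genome_with_rna(ref.sequence, "-")
        (h_fwd,) = search_rna(fwd, [ref])
        (h_rev,) = search_rna(rev, [ref])
        assert h_fwd.h_value == h_rev.h_value == 1.0
        f_fwd = next(f for f in fwd.features if f.feature_id == h_fwd.feature_id)
        f_rev = next(f for f in rev.features if f.feature_id == h_rev.feature_id)
        assert (f_fwd.start, f_fwd.end) == (f_rev.start, f_rev.end)
        assert {f_fwd.strand, f_rev.strand} == {"+", "-"}

    def test_hit_attaches_to_annotated_feature(self, refs):
        ref = next(r for r in refs if r.ref_id == "hok-sok_A")
        genome = self._genome_with_rna(ref.sequence, "-", annotate=True)
        (hit,) = search_rna(genome, [ref])
        assert hit.feature_id == "r1"
        assert len(genome.features) == 1  # no synthetic feature added

    def test_heavily_mutated_copy_is_dropped(self, refs):
        """A copy with 40% of positions substituted yields no retainable
        candidate: its best alignment falls below the E-value ceiling."""
        ref = next(r for r in refs if r.ref_id == "hok-sok_A")
        mutated = mutate_to_identity(ref.sequence, 0.6, seed=1)
        genome = self._genome_with_rna(mutated, "+")
        hits = search_rna(genome, [ref])
        assert all(not passes_h(h.h_value) for h in hits)


@pytest.fixture(scope="module")
def profile_file(tmp_path_factory, refs):
    import pyhmmer

    tox = next(r for r in refs if r.ref_id == "relBE_T")
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=mutate_to_identity(tox.sequence, 0.9, 100 + i))
        for i in range(6)
    ]
    msa = pyhmmer.easel.TextMSA(name=b"relBE_T|toxin|II|relBE", sequences=seqs)
    hmm, _, _ = pyhmmer.plan7.Builder(alphabet).build_msa(
        msa.digitize(alphabet), pyhmmer.plan7.Background(alphabet)
    )
    path = tmp_path_factory.mktemp("hmm") / "toxins.hmm"
    with open(path, "wb") as fh:
        hmm.write(fh, binary=False)
    return path, hmm.consensus.upper()


class TestDomainScan:
    def test_consensus_sequence_hits_its_profile(self, profile_file):
        path, consensus = profile_file
        genome = _genome_with_proteins({"g1": consensus})
        hits = scan_domains(genome, path)
        assert len(hits) == 1
        assert (hits[0].role, hits[0].ta_type, hits[0].family) == ("toxin", "II", "relBE")
        assert hits[0].evalue <= 1e-5

    def test_empty_profile_file_is_a_format_error(self, tmp_path):
        empty = tmp_path / "empty.hmm"
        empty.write_text("")
        genome = _genome_with_proteins({"g1": "M" + "A" * 40})
        with pytest.raises(FormatError):
            scan_domains(genome, empty)

    def test_no_proteins_gives_empty_list(self, profile_file):
        path, _ = profile_file
        genome = AnnotatedGenome([Replicon("chr1", "ACGT" * 100)], [])
        assert scan_domains(genome, path) == []


class TestBuildCandidates:
    def _one_hit_genome(self, aa_len: int, h: float):
        ref = ReferenceEntry("fam_T", "toxin", "II", "fam", "protein", "M" + "C" * 99)
        genome = _genome_with_proteins({"g1": "M" + "A" * (aa_len - 1)})
        hit = HomologyHit("g1", "fam_T", h, 1.0, 100.0, 1e-20)
        return hit, genome, [ref]

    @pytest.mark.parametrize(
        "aa_len, h, kept",
        [
            (29, 0.9, False),  # below the 30-residue floor despite strong H
            (30, 0.37, True),  # both boundaries on the passing side
            (500, 0.37, True),
            (501, 0.9, False),  # above the 500-residue ceiling
            (100, 0.36, False),  # H not strictly above the cut-off
        ],
    )
    def test_length_and_h_filters(self, aa_len, h, kept):
        hit, genome, refs = self._one_hit_genome(aa_len, h)
        out = build_candidates([hit], [], genome, refs)
        assert (len(out) == 1) is kept

    def test_hmm_only_candidate_kept_unless_blast_required(self, refs):
        genome = _genome_with_proteins({"g1": "M" + "A" * 90})
        dhit = homology.DomainHit("g1", "p1", "toxin", "II", "relBE", 1e-10, 80.0)
        assert len(build_candidates([], [dhit], genome, refs)) == 1
        assert build_candidates([], [dhit], genome, refs, require_blast=True) == []

    def test_threshold_monotonicity(self, refs):
        """Raising the H threshold never enlarges the candidate set."""
        rng = np.random.default_rng(9)
        genome = _genome_with_proteins({f"g{i}": "M" + "A" * 60 for i in range(12)})
        protein_refs = [r for r in refs if r.molecule == "protein"]
        hits = [
            HomologyHit(f"g{i}", protein_refs[i % len(protein_refs)].ref_id,
                        float(rng.uniform(0.1, 1.0)), float(rng.uniform(0.1, 1.0)), 50.0, 1e-10)
            for i in range(12)
        ]
        previous = None
        for thr in np.arange(0.1, 0.95, 0.1):
            kept = {(c.feature.feature_id, c.role, c.ta_type)
                    for c in build_candidates(hits, [], genome, refs, h_threshold=float(thr))}
            if previous is not None:
                assert kept <= previous
            previous = kept
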