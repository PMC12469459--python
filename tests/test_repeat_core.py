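"""Run decomposition, translation and cryptic-simplicity scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatlife import repeat_core as rc
from msatlife.errors import InvalidAlphabetError, UndefinedScoreError

from conftest import (
    AXOLOTL_EXON_REGION,
    CSS_PAGUMA,
    CSS_PARADOXURUS,
    PREDOMINANT_EXON_ALLELE,
    random_dna,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=100)
motifs = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("GAA", ("AAG", 2)),
            ("AAA", ("A", 0)),
            ("GCT", ("CTG", 2)),
            ("AGAG", ("AG", 0)),
            ("A", ("A", 0)),
        ],
    )
    def test_examples(self, motif, expected):
        assert rc.canonicalize_motif(motif) == expected

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            rc.canonicalize_motif("GAN")

    @given(motifs)
    @settings(deadline=None)
    def test_rotation_invariance(self, motif):
        """All rotations of a motif share one canonical form, and the phase
        reconstructs the observed primitive root."""
        canonical, _ = rc.canonicalize_motif(motif)
        for i in range(len(motif)):
            rotated = motif[i:] + motif[:i]
            c2, phase = rc.canonicalize_motif(rotated)
            assert c2 == canonical
            assert c2[phase:] + c2[:phase] == rc.primitive_root(rotated)


class TestDecompose:
    def test_predominant_exon_allele(self):
        """The predominant exonic allele decomposes into the published
        five-run compound structure."""
        s = rc.decompose(PREDOMINANT_EXON_ALLELE, 3, 1)
        assert s.notation() == "(GAA)1(GAG)2(GAA)1(GAG)7(GAA)1"
        assert [r.count for r in s.runs] == [1, 2, 1, 7, 1]
        assert s.major_motif == "AGG"  # canonical class of GAG
        assert s.longest_pure_run == 7

    def test_css_retains_one_gaa(self):
        for css in (CSS_PARADOXURUS, CSS_PAGUMA):
            assert rc.longest_pure_run(css, "GAA") == 1

    def test_axolotl_degenerated_structure(self):
        s = rc.decompose(AXOLOTL_EXON_REGION, 3, 1)
        assert (
            s.notation() == "(GAG)1(GAA)1(GAG)1(GAA)1(GAG)1(GAT)2GAC(GAG)1"
        )
        # lone GAC is interstitial, not a run
        assert s.interstitial == [(21, "GAC")]

    def test_empty_region(self):
        s = rc.decompose("", 3, 1)
        assert s.runs == [] and s.major_motif is None

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            rc.decompose("GANGAN", 3)

    @given(dna, st.integers(1, 6), st.integers(1, 3))
    @settings(deadline=None, max_examples=200)
    def test_reconstruction(self, region, motif_len, min_units):
        """Runs plus interstitial segments tile the input exactly."""
        s = rc.decompose(region, motif_len, min_units)
        assert s.reconstruct() == region
        for a, b in zip(s.runs, s.runs[1:]):
            assert a.end <= b.start

    def test_min_units_filters_short_runs(self):
        s = rc.decompose("GAAGAAGAACTG", 3, min_units=2)
        assert [(r.motif, r.count) for r in s.runs] == [("GAA", 3)]


def oracle_longest_run(region, motif):
    """Exhaustive O(n^2) scan over every start and rotation."""
    root = rc.primitive_root(motif)
    L = len(root)
    rots = {root[i:] + root[:i] for i in range(L)}
    best = 0
    for p in range(len(region)):
        word = region[p : p + L]
        if word in rots:
            k = 0
            while region[p + k * L : p + (k + 1) * L] == word:
                k += 1
            best = max(best, k)
    return best


class TestLongestPureRun:
    def test_published_gag_run(self):
        assert rc.longest_pure_run(PREDOMINANT_EXON_ALLELE, "GAG") == 7

    def test_empty_region(self):
        assert rc.longest_pure_run("", "GAA") == 0

    def test_axolotl_runs(self):
        assert rc.longest_pure_run(AXOLOTL_EXON_REGION, "GAT") == 2
        assert rc.longest_pure_run(AXOLOTL_EXON_REGION, "GAG") == 1

    def test_matches_oracle_on_random_strings(self, rng):
        for _ in range(300):
            region = random_dna(rng, int(rng.integers(0, 100)))
            motif = random_dna(rng, int(rng.integers(1, 7)))
            assert rc.longest_pure_run(region, motif) == oracle_longest_run(
                region, motif
            )

    @given(dna, motifs)
    @settings(deadline=None, max_examples=150)
    def test_rotation_invariant(self, region, motif):
        vals = {
            rc.longest_pure_run(region, motif[i:] + motif[:i])
            for i in range(len(motif))
        }
        assert len(vals) == 1


class TestTranslateRuns:
    def test_polyE_run(self):
        # 11 in-frame GAA/GAG codons, all glutamic acid
        s = rc.translate_runs("GAAGAGGAGGAAGAGGAGGAGGAGGAGGAGGAA", 0)
        assert s.longest_run("E") == 11
        assert not s.has_stop

    def test_polyD_run(self):
        s = rc.translate_runs("GATGATGAC", 0)
        assert s.longest_run("D") == 3

    def test_valine_interruption(self):
        s = rc.translate_runs("GTGGAGGAG", 0)
        assert s.peptide == "VEE"

    def test_stop_flagged_not_raised(self):
        s = rc.translate_runs("GAATAAGAA", 0)
        assert s.has_stop

    def test_polyE_equals_gaa_gag_units(self, rng):
        """Frame-aligned: total E residues equal total GAA+GAG codon units."""
        for _ in range(50):
            codons = rng.choice(
                ["GAA", "GAG", "GAT", "GCT", "TTT"], size=int(rng.integers(3, 20))
            )
            region = "".join(codons)
            s = rc.translate_runs(region, 0)
            n_e = sum(c for res, c, _ in s.runs if res == "E")
            assert n_e == sum(c in ("GAA", "GAG") for c in codons)


class TestCrypticSimplicity:
    def test_pure_repeat_scores_high(self):
        score = rc.cryptic_simplicity("GAA" * 10, seed=1).score
        assert score > 1

    def test_published_css_scores_above_background(self):
        for css in (CSS_PARADOXURUS, CSS_PAGUMA):
            assert rc.cryptic_simplicity(css, seed=1).score > 1

    def test_random_sequence_near_one(self, rng):
        region = random_dna(rng, 200)
        score = rc.cryptic_simplicity(region, n_shuffles=100, seed=2).score
        assert 0.5 <= score <= 2.0

    def test_deterministic_for_fixed_seed(self):
        a = rc.cryptic_simplicity(CSS_PAGUMA, seed=7)
        b = rc.cryptic_simplicity(CSS_PAGUMA, seed=7)
        assert a == b

    def test_short_region_rejected(self):
        with pytest.raises(UndefinedScoreError):
            rc.cryptic_simplicity("GAAGAAGA", seed=0)
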