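"""Flank anchoring and repeat-region extraction."""

import pytest

from msatlife import orthology as orth
from msatlife.errors import AnchorTooShortError

from conftest import mutate, random_dna


class TestAlignFlank:
    def test_exact_containment(self, flanks, rng):
        left, _ = flanks
        target = random_dna(rng, 100) + left + random_dna(rng, 100)
        hits = orth.align_flank(left, target)
        top = hits[0]
        assert top.identity == 1.0
        assert top.query_coverage == 1.0
        assert top.strand == "+"
        assert target[top.target_start : top.target_end] == left

    def test_reverse_complement_hit(self, flanks, rng):
        left, _ = flanks
        target = random_dna(rng, 50) + orth.revcomp(left) + random_dna(rng, 50)
        top = orth.align_flank(left, target)[0]
        assert top.strand == "-"
        assert top.identity == 1.0
        assert orth.revcomp(target[top.target_start : top.target_end]) == left

    def test_divergent_flank_located(self, rng):
        """A flank with 10% substitutions embedded in 2 kb of background is
        found at the right place with the expected identity."""
        flank = random_dna(rng, 60)
        background = random_dna(rng, 2000)
        positions = rng.choice(60, size=6, replace=False)  # exactly 10%
        mutated = list(flank)
        for p in positions:
            mutated[p] = str(rng.choice([x for x in "ACGT" if x != flank[p]]))
        target = background[:1000] + "".join(mutated) + background[1000:]
        top = orth.align_flank(flank, target)[0]
        assert abs(top.target_start - 1000) <= 2
        assert 0.85 <= top.identity <= 0.95

    def test_short_flank_rejected(self):
        with pytest.raises(AnchorTooShortError):
            orth.align_flank("ACGTACGT", "ACGT" * 100)


class TestExtractOrtholog:
    def test_exact_anchors(self, flanks):
        left, right = flanks
        region = "GAA" * 12
        res = orth.extract_ortholog(left, right, left + region + right)
        assert res.accepted
        assert res.region == region

    def test_missing_right_flank(self, flanks, rng):
        left, right = flanks
        target = random_dna(rng, 30) + left + random_dna(rng, 10)
        res = orth.extract_ortholog(left, right, target)
        assert not res.accepted
        assert res.rejection_reason == "no_right_flank"

    def test_missing_left_flank(self, flanks, rng):
        left, right = flanks
        target = random_dna(rng, 30) + right + random_dna(rng, 10)
        res = orth.extract_ortholog(left, right, target)
        assert not res.accepted
        assert res.rejection_reason == "no_left_flank"

    def test_wrong_order(self, flanks):
        left, right = flanks
        res = orth.extract_ortholog(left, right, right + "GAA" * 5 + left)
        assert not res.accepted
        assert res.rejection_reason == "wrong_order"

    def test_region_too_long(self, flanks, rng):
        left, right = flanks
        target = left + random_dna(rng, 500) + right
        res = orth.extract_ortholog(left, right, target, max_region=100)
        assert not res.accepted
        assert res.rejection_reason == "region_too_long"

    def test_below_identity(self, flanks, rng):
        left, right = flanks
        degraded = mutate(rng, left, 0.25)  # ~75% identity
        target = degraded + "GAA" * 8 + right
        res = orth.extract_ortholog(left, right, target, min_identity=0.9)
        assert not res.accepted
        assert res.rejection_reason == "below_identity"

    def test_minus_strand_region_reoriented(self, flanks):
        left, right = flanks
        target = orth.revcomp(left + "GCT" * 5 + right)
        res = orth.extract_ortholog(left, right, target)
        assert res.accepted
        assert res.region == "GCT" * 5

    def test_orientation_round_trip(self, flanks, rng):
        """Extraction from a target and its reverse complement yields the
        identical region string."""
        left, right = flanks
        for _ in range(10):
            region = random_dna(rng, int(rng.integers(10, 60)))
            target = (
                random_dna(rng, 40) + left + region + right + random_dna(rng, 40)
            )
            fwd = orth.extract_ortholog(left, right, target)
            rev = orth.extract_ortholog(left, right, orth.revcomp(target))
            assert fwd.accepted and rev.accepted
            assert fwd.region == rev.region == region

    def test_threshold_monotonicity(self, flanks, rng):
        """Raising min_identity never turns a rejection into an acceptance."""
        left, right = flanks
        for _ in range(20):
            target = (
                random_dna(rng, 30)
                + mutate(rng, left, 0.15)
                + "GAA" * 6
                + mutate(rng, right, 0.15)
                + random_dna(rng, 30)
            )
            accepted = [
                orth.extract_ortholog(
                    left, right, target, min_identity=t
                ).accepted
                for t in (0.7, 0.8, 0.9, 0.99)
            ]
            # once rejected, stays rejected at stricter thresholds
            for lo, hi in zip(accepted, accepted[1:]):
                assert lo or not hi

    def test_recovery_rate_on_simulated_targets(self, rng):
        """>= 95% of true regions recovered exactly from 200 simulated
        targets with 5% flank divergence."""
        recovered = 0
        n = 200
        for _ in range(n):
            left = random_dna(rng, 40)
            right = random_dna(rng, 40)
            region = "GAA" * int(rng.integers(3, 15))
            target = (
                random_dna(rng, int(rng.integers(50, 300)))
                + mutate(rng, left, 0.05)
                + region
                + mutate(rng, right, 0.05)
                + random_dna(rng, int(rng.integers(50, 300)))
            )
            res = orth.extract_ortholog(left, right, target)
            recovered += res.accepted and res.region == region
        assert recovered / n >= 0.95
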