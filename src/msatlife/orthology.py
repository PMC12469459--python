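"""Flank-anchored orthology: locate a microsatellite locus in a target
sequence by aligning its two conserved flanks and extracting the enclosed
repeat region.

The anchoring criteria follow the standard coverage/identity rules for
cross-species locus validation: every flank base must be aligned (100% query
coverage) and identity must exceed a threshold (default 80%), computed over
alignment columns including internal gaps.  Alignment is query-global with
free end gaps on the target (the flank floats inside the target), scored
BLASTN-like: match +2, mismatch -3, gap open -5, gap extend -2.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .errors import AnchorTooShortError

MIN_FLANK_LEN = 20

REJECTION_REASONS = (
    "no_left_flank",
    "no_right_flank",
    "wrong_order",
    "strand_conflict",
    "below_identity",
    "below_coverage",
    "region_too_long",
)


@dataclass(frozen=True)
class FlankHit:
    """Best placement of one flank on one strand of a target."""

    target_id: str
    target_start: int
    target_end: int
    identity: float
    query_coverage: float
    strand: str
    score: float


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # epsilon surcharge on internal gap opening: breaks exact score ties
    # between a terminal mismatch and an equivalent gap+match, keeping
    # anchor boundaries at the substitution interpretation
    aligner.open_internal_insertion_score = gap_open - 1e-4
    aligner.open_internal_deletion_score = gap_open - 1e-4
    # target overhangs are free (flank floats inside the target) ...
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    # ... but dropping flank ends is forbidden: 100% query coverage
    aligner.open_end_insertion_score = -1e7
    aligner.extend_end_insertion_score = -1e7
    return aligner


def _best_hit_oriented(
    aligner: Align.PairwiseAligner,
    flank: str,
    oriented_target: str,
    target_id: str,
    strand: str,
) -> FlankHit | None:
    """Best query-global placement of *flank* on an already-oriented target."""
    if len(oriented_target) < len(flank):
        return None
    alignment = aligner.align(oriented_target, flank)[0]
    target_blocks, query_blocks = alignment.aligned
    if len(query_blocks) == 0:
        return None
    t_start = int(target_blocks[0][0])
    t_end = int(target_blocks[-1][1])
    # span-based coverage (BLAST qcovs semantics): fraction of the flank
    # between the first and last aligned flank positions
    q_span = int(query_blocks[-1][1] - query_blocks[0][0])
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identity = counts.identities / columns if columns else 0.0
    coverage = q_span / len(flank)
    score = float(alignment.score)
    if score <= 0:
        return None
    return FlankHit(
        target_id=target_id,
        target_start=t_start,
        target_end=t_end,
        identity=identity,
        query_coverage=coverage,
        strand=strand,
        score=score,
    )


def align_flank(
    flank: str,
    target: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    target_id: str = "target",
) -> list[FlankHit]:
    """Align *flank* against both strands of *target*.

    Returns up to one hit per strand (the optimal placement), sorted by
    score descending.  Coordinates are always on the forward strand of
    *target*.  Raises :class:`AnchorTooShortError` for flanks under
    ``MIN_FLANK_LEN`` bp, which cannot satisfy the coverage criterion
    meaningfully.
    """
    if len(flank) < MIN_FLANK_LEN:
        raise AnchorTooShortError(
            f"flank length {len(flank)} < {MIN_FLANK_LEN}"
        )
    if not target:
        return []
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    hits: list[FlankHit] = []
    fwd = _best_hit_oriented(aligner, flank, target, target_id, "+")
    if fwd is not None:
        hits.append(fwd)
    rev = _best_hit_oriented(aligner, flank, revcomp(target), target_id, "-")
    if rev is not None:
        # map coordinates back to the forward strand
        n = len(target)
        hits.append(
            FlankHit(
                target_id=target_id,
                target_start=n - rev.target_end,
                target_end=n - rev.target_start,
                identity=rev.identity,
                query_coverage=rev.query_coverage,
                strand="-",
                score=rev.score,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.strand))
    return hits


@dataclass
class OrthologRegion:
    """Extraction outcome for one locus on one target.

    ``region`` is the inter-flank segment, reverse-complemented into locus
    orientation when the anchors lie on the minus strand.  All failure modes
    are encoded in ``rejection_reason`` rather than raised.
    """

    left_hit: FlankHit | None
    right_hit: FlankHit | None
    region: str
    locus: str
    accepted: bool
    rejection_reason: str | None = None


def extract_ortholog(
    left_flank: str,
    right_flank: str,
    target: str,
    min_identity: float = 0.80,
    min_coverage: float = 1.00,
    max_region: int = 2000,
    locus: str = "locus",
    target_id: str = "target",
) -> OrthologRegion:
    """Anchor both flanks and extract the enclosed repeat region.

    Both flanks must land on the same strand, in order, passing identity and
    coverage thresholds, with an enclosed region no longer than
    ``max_region``.  Of the strand candidates, the one with the greater
    summed score (ties: shorter region, then plus strand) wins.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    aligner = _make_aligner(2.0, -3.0, -5.0, -2.0)

    # A placement only counts as "found" above a score floor: a random
    # query-global placement scores near (or below) zero, so 30% of the
    # maximum attainable score cleanly separates spurious placements
    # (which should report an absent flank) from genuine but divergent ones
    # (which should report below_identity / below_coverage).
    def found(hit: FlankHit | None, flank: str) -> bool:
        return hit is not None and hit.score >= 0.3 * 2.0 * len(flank)

    candidates = []  # (strand, oriented_target, left_hit, right_hit)
    for strand in "+-":
        oriented = target if strand == "+" else revcomp(target)
        lh = _best_hit_oriented(aligner, left_flank, oriented, target_id, strand)
        rh = _best_hit_oriented(aligner, right_flank, oriented, target_id, strand)
        if not found(lh, left_flank):
            lh = None
        if not found(rh, right_flank):
            rh = None
        candidates.append((strand, oriented, lh, rh))

    def reject(reason: str, lh=None, rh=None) -> OrthologRegion:
        return OrthologRegion(
            left_hit=lh, right_hit=rh, region="", locus=locus,
            accepted=False, rejection_reason=reason,
        )

    paired = [(s, o, lh, rh) for s, o, lh, rh in candidates if lh and rh]
    if not paired:
        if all(lh is None for _, _, lh, _ in candidates):
            return reject("no_left_flank")
        if all(rh is None for _, _, _, rh in candidates):
            return reject("no_right_flank")
        return reject("strand_conflict")

    evaluated = []
    for strand, oriented, lh, rh in paired:
        # hit coordinates are already in the oriented frame
        l_end, r_start = lh.target_end, rh.target_start
        if l_end > r_start:
            evaluated.append((strand, "wrong_order", lh, rh, "", -1.0))
            continue
        region = oriented[l_end:r_start]
        reason = None
        if lh.query_coverage < min_coverage or rh.query_coverage < min_coverage:
            reason = "below_coverage"
        elif lh.identity < min_identity or rh.identity < min_identity:
            reason = "below_identity"
        elif len(region) > max_region:
            reason = "region_too_long"
        evaluated.append((strand, reason, lh, rh, region, lh.score + rh.score))

    accepted = [e for e in evaluated if e[1] is None]
    if accepted:
        strand, _, lh, rh, region, _ = max(
            accepted, key=lambda e: (e[5], -len(e[4]), e[0] == "+")
        )
        return OrthologRegion(
            left_hit=lh, right_hit=rh, region=region, locus=locus,
            accepted=True, rejection_reason=None,
        )
    strand, reason, lh, rh, region, _ = max(evaluated, key=lambda e: e[5])
    return reject(reason, lh, rh)
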