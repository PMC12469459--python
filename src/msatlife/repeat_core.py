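"""Run-length decomposition of compound microsatellite repeat regions.

A compound microsatellite is a stretch of DNA built from tandem runs of more
than one short motif, e.g. ``(GAA)1(GAG)2(GAA)1(GAG)7(GAA)1``.  This module
decomposes a repeat region into an ordered list of motif runs, computes
pure-run statistics (the quantity slippage acts on), translates coding
repeats into amino-acid runs, and scores "cryptic simplicity" -- the excess
of short tandem structure over what the base composition alone would give,
the signature of degenerated (dead) repeat regions.

Coordinates are 0-based, half-open throughout.  Motifs are grouped into
rotation classes: GAA, AAG and AGA all belong to the canonical class AAG
(lexicographically smallest rotation), so counts are comparable across
species that happen to break the repeat at different phases.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .errors import InvalidAlphabetError, UndefinedScoreError

_DNA = frozenset("ACGT")


def _check_alphabet(seq: str) -> None:
    if not _DNA.issuperset(seq):
        bad = sorted(set(seq) - _DNA)
        raise InvalidAlphabetError(f"non-ACGT characters: {bad}")


def primitive_root(motif: str) -> str:
    """Smallest unit whose repetition gives *motif* (e.g. ``AGAG`` -> ``AG``)."""
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif  # pragma: no cover


def canonicalize_motif(motif: str) -> tuple[str, int]:
    """Reduce *motif* to its primitive root and canonical rotation.

    Returns ``(canonical, phase)`` where *canonical* is the lexicographically
    smallest rotation of the primitive root and *phase* is the left-rotation
    of *canonical* that reproduces the observed motif:
    ``canonical[phase:] + canonical[:phase] == primitive_root(motif)``.

    >>> canonicalize_motif("GAA")
    ('AAG', 2)
    """
    if not motif:
        raise InvalidAlphabetError("empty motif")
    _check_alphabet(motif)
    root = primitive_root(motif)
    rotations = [root[i:] + root[:i] for i in range(len(root))]
    canonical = min(rotations)
    phase = next(
        k for k in range(len(root)) if canonical[k:] + canonical[:k] == root
    )
    return canonical, phase


def _rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


@dataclass(frozen=True)
class MotifRun:
    """One maximal tandem run of a single motif."""

    motif: str
    count: int
    start: int
    canonical: str
    phase: int

    @property
    def end(self) -> int:
        return self.start + self.count * len(self.motif)

    def __str__(self) -> str:  # the field's parenthetical unit-count notation
        return f"({self.motif}){self.count}"


@dataclass
class RepeatStructure:
    """Ordered run decomposition of a repeat region.

    ``runs`` and ``interstitial`` segments are non-overlapping and jointly
    tile ``region`` exactly; ``major_motif`` is the canonical rotation class
    with the greatest total unit count (``None`` if no runs were found).
    """

    region: str
    runs: list[MotifRun] = field(default_factory=list)
    interstitial: list[tuple[int, str]] = field(default_factory=list)
    major_motif: str | None = None
    longest_pure_run: int = 0
    major_ties: list[str] = field(default_factory=list)

    def total_units(self, canonical: str) -> int:
        return sum(r.count for r in self.runs if r.canonical == canonical)

    def notation(self) -> str:
        """Parenthetical notation, interstitial bases written bare."""
        parts: list[tuple[int, str]] = [(r.start, str(r)) for r in self.runs]
        parts += [(off, seg) for off, seg in self.interstitial]
        return "".join(s for _, s in sorted(parts))

    def reconstruct(self) -> str:
        parts = [(r.start, r.motif * r.count) for r in self.runs]
        parts += self.interstitial
        return "".join(s for _, s in sorted(parts))


def _tandem_count(region: str, pos: int, motif: str) -> int:
    """Units of *motif* repeated in-phase starting exactly at *pos*."""
    L = len(motif)
    k = 0
    while region[pos + k * L : pos + (k + 1) * L] == motif:
        k += 1
    return k


def _class_occurrences(region: str, motif_len: int) -> dict[str, int]:
    """Non-overlapping unit occurrences per canonical class, any phase.

    Used to decide whether a solitary unit counts as a run: a lone GAC in a
    GAG/GAA-dominated region is interstitial noise, but a lone GAA next to
    other GAA-class units is a genuine one-unit run (the paper-style
    ``(GAA)1`` notation).
    """
    positions: dict[str, list[int]] = defaultdict(list)
    for p in range(len(region) - motif_len + 1):
        word = region[p : p + motif_len]
        canonical, _ = canonicalize_motif(word)
        positions[canonical].append(p)
    counts: dict[str, int] = {}
    for canonical, pos_list in positions.items():
        n, last_end = 0, -1
        for p in pos_list:
            if p >= last_end:
                n += 1
                last_end = p + motif_len
        counts[canonical] = n
    return counts


def decompose(region: str, motif_len: int, min_units: int = 1) -> RepeatStructure:
    """Greedy left-to-right maximal-run decomposition.

    At each position the longest tandem run of the ``motif_len``-mer starting
    there is taken; positions not opening a qualifying run become
    interstitial.  A solitary unit (count 1, when ``min_units == 1``)
    qualifies only if its rotation class occurs at least twice in the region,
    which keeps one-off words out of the run list while preserving the
    conventional ``(GAA)1`` bookends of compound repeats.
    """
    _check_alphabet(region)
    if not 1 <= motif_len <= 6:
        raise ValueError("motif_len must be in 1..6")
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    structure = RepeatStructure(region=region)
    if not region:
        return structure

    class_occ = _class_occurrences(region, motif_len) if region else {}
    runs: list[MotifRun] = []
    inter: list[tuple[int, str]] = []
    p = 0
    seg_start: int | None = None
    n = len(region)
    while p < n:
        emitted = False
        if p + motif_len <= n:
            motif = region[p : p + motif_len]
            k = _tandem_count(region, p, motif)
            canonical, phase = canonicalize_motif(motif)
            if k >= min_units and (k >= 2 or class_occ.get(canonical, 0) >= 2):
                if seg_start is not None:
                    inter.append((seg_start, region[seg_start:p]))
                    seg_start = None
                runs.append(MotifRun(motif, k, p, canonical, phase))
                p += k * motif_len
                emitted = True
        if not emitted:
            if seg_start is None:
                seg_start = p
            p += 1
    if seg_start is not None:
        inter.append((seg_start, region[seg_start:]))

    structure.runs = runs
    structure.interstitial = inter
    if runs:
        totals: dict[str, int] = defaultdict(int)
        best_run: dict[str, int] = defaultdict(int)
        for r in runs:
            totals[r.canonical] += r.count
            best_run[r.canonical] = max(best_run[r.canonical], r.count)
        top = max(totals.values())
        tied = sorted(c for c, t in totals.items() if t == top)
        # ties: longest single pure run, then lexicographic canonical form
        tied.sort(key=lambda c: (-best_run[c], c))
        structure.major_motif = tied[0]
        structure.major_ties = tied if len(tied) > 1 else []
        structure.longest_pure_run = longest_pure_run(
            region, structure.major_motif
        )
    return structure


def longest_pure_run(region: str, motif: str) -> int:
    """Longest uninterrupted tandem array of *motif*, any rotation phase.

    Returns the maximum ``k`` such that some rotation of *motif* repeated
    ``k`` times occurs as a substring of *region*; 0 if absent.
    """
    if not motif:
        raise InvalidAlphabetError("empty motif")
    _check_alphabet(motif)
    _check_alphabet(region)
    root = primitive_root(motif)
    L = len(root)
    rots = _rotations(root)
    best = 0
    for p in range(len(region) - L + 1):
        word = region[p : p + L]
        if word in rots:
            best = max(best, _tandem_count(region, p, word))
    return best


def unit_count(region: str, motif: str) -> int:
    """Total non-overlapping units of *motif* (any phase) across *region*."""
    _check_alphabet(region)
    root = primitive_root(motif)
    L = len(root)
    rots = _rotations(root)
    n, p = 0, 0
    while p + L <= len(region):
        if region[p : p + L] in rots:
            n += 1
            p += L
        else:
            p += 1
    return n


@dataclass
class AminoRunStructure:
    """Translated repeat region with maximal same-residue runs."""

    peptide: str
    runs: list[tuple[str, int, int]]  # (residue, count, start)
    has_stop: bool

    def longest_run(self, residue: str) -> int:
        return max((c for r, c, _ in self.runs if r == residue), default=0)


def translate_runs(region: str, frame: int = 0) -> AminoRunStructure:
    """Translate *region* in *frame* and report maximal amino-acid runs.

    An in-frame stop codon is flagged (``has_stop``), not raised: dead repeat
    regions in non-coding orthologs routinely contain stops.
    """
    _check_alphabet(region)
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    coding = region[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        raise ValueError("no complete codon in frame")
    peptide = str(Seq(coding).translate())
    runs: list[tuple[str, int, int]] = []
    i = 0
    while i < len(peptide):
        j = i
        while j < len(peptide) and peptide[j] == peptide[i]:
            j += 1
        runs.append((peptide[i], j - i, i))
        i = j
    return AminoRunStructure(peptide=peptide, runs=runs, has_stop="*" in peptide)


@dataclass(frozen=True)
class SimplicityScore:
    """Tandem coverage of the observed sequence relative to shuffled copies."""

    score: float
    n_shuffles: int
    seed: int


def tandem_coverage(seq: str, max_motif_len: int = 6) -> float:
    """Fraction of positions inside a tandem run of >= 2 units (motif 1..L)."""
    n = len(seq)
    if n == 0:
        return 0.0
    covered = np.zeros(n, dtype=bool)
    for L in range(1, max_motif_len + 1):
        for p in range(n - 2 * L + 1):
            if seq[p : p + L] == seq[p + L : p + 2 * L]:
                covered[p : p + 2 * L] = True
    return float(covered.mean())


def cryptic_simplicity(
    region: str,
    max_motif_len: int = 6,
    n_shuffles: int = 100,
    seed: int = 0,
) -> SimplicityScore:
    """Tautz-style cryptic-simplicity ratio.

    The observed tandem-run coverage is divided by its mean over
    ``n_shuffles`` seeded i.i.d.-uniform random sequences of the same
    length.  A ratio well above 1 marks a low-complexity region -- either a
    true tandem repeat or a cryptic simple sequence (CSS) whose simplicity
    is driven by biased base composition.  The null is deliberately
    composition-free: CSS regions are simple *because* of their composition
    bias, so a composition-preserving permutation null would erase exactly
    the signal this score exists to detect.
    """
    _check_alphabet(region)
    if len(region) < 10:
        raise UndefinedScoreError("region shorter than 10 bp")
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    observed = tandem_coverage(region, max_motif_len)
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    background = np.empty(n_shuffles)
    for i in range(n_shuffles):
        random_seq = "".join(rng.choice(alphabet, size=len(region)))
        background[i] = tandem_coverage(random_seq, max_motif_len)
    mean_bg = float(background.mean())
    if mean_bg == 0.0:
        score = float("inf") if observed > 0 else 1.0
    else:
        score = observed / mean_bg
    return SimplicityScore(score=score, n_shuffles=n_shuffles, seed=seed)
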