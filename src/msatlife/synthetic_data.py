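"""Forward simulator of microsatellite evolution along a phylogeny.

Each locus is a triple (left flank, repeat region, right flank) evolving
along a tree with branch lengths.  Mutational processes, each a Poisson
process in branch-length time (Gillespie event placement per branch):

* **slippage** -- whole-unit +-1 changes per run, with a rate proportional
  to how far the run exceeds a minimum slippable length (length-dependent
  slippage), and a configurable expansion bias;
* **point mutations** -- per-site substitutions inside the repeat region,
  which interrupt runs and drive degeneration toward cryptic simplicity;
* **flank point mutations** -- per-site substitutions in the flanks at a
  (much lower) independent rate, so flanks stay anchorable while repeat
  lengths churn;
* **large deletions** -- removal of several units in one event, optionally
  overrunning into the right flank by a bounded number of bp, the
  mechanism behind sudden locus death.

The run structure is re-decomposed after every event because slippage
rates depend on current run lengths.  Every event is recorded in an
:class:`EventLog`; replaying the log from the root sequence must reproduce
every tip exactly, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidRootError
from .repeat_core import decompose

BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Mutational rates, all per unit branch length.

    Defaults are order-of-magnitude choices for a slippage-dominated
    trinucleotide locus: repeat-length changes are far more frequent than
    flank substitutions, and large deletions are rare single events.
    """

    slippage_rate_per_unit: float = 0.02
    expansion_bias: float = 0.5
    min_slippage_units: int = 1
    point_rate: float = 1e-3
    flank_point_rate: float = 2e-4
    large_del_rate: float = 5e-3
    large_del_span: tuple[int, int] = (2, 6)
    large_del_flank_overrun: int = 10
    motif_len: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "slippage_rate_per_unit",
            "point_rate",
            "flank_point_rate",
            "large_del_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.expansion_bias <= 1:
            raise ValueError("expansion_bias must be in [0, 1]")


@dataclass(frozen=True)
class Event:
    branch: str
    kind: str  # slip+, slip-, point, large_del, flank_point
    position: int
    detail: dict


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "branch": e.branch,
                "kind": e.kind,
                "position": e.position,
                **e.detail,
            }
            for e in self.events
        ]


Locus = tuple[str, str, str]  # (left flank, repeat region, right flank)


def _apply_event(locus: Locus, event: Event) -> Locus:
    """Deterministically apply one recorded event to a locus state."""
    lf, region, rf = locus
    kind, pos, det = event.kind, event.position, event.detail
    if kind in ("slip+", "slip-"):
        motif = det["motif"]
        if kind == "slip+":
            region = region[:pos] + motif + region[pos:]
        else:
            assert region[pos : pos + len(motif)] == motif
            region = region[:pos] + region[pos + len(motif) :]
    elif kind == "point":
        region = region[:pos] + det["new"] + region[pos + 1 :]
    elif kind == "flank_point":
        if det["flank"] == "left":
            lf = lf[:pos] + det["new"] + lf[pos + 1 :]
        else:
            rf = rf[:pos] + det["new"] + rf[pos + 1 :]
    elif kind == "large_del":
        end = pos + det["length"]
        overrun = det["overrun"]
        region = region[:pos] + (region[end:] if end <= len(region) else "")
        if overrun:
            rf = rf[overrun:]
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {kind}")
    return lf, region, rf


def _branch_events(
    locus: Locus,
    blen: float,
    branch: str,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[Locus, list[Event]]:
    """Gillespie event placement on one branch."""
    events: list[Event] = []
    t = 0.0
    while True:
        lf, region, rf = locus
        structure = decompose(region, params.motif_len, min_units=1)
        run_rates = np.array(
            [
                params.slippage_rate_per_unit
                * max(0, r.count - params.min_slippage_units)
                for r in structure.runs
            ]
        )
        r_slip = run_rates.sum()
        r_point = params.point_rate * len(region)
        r_flank = params.flank_point_rate * (len(lf) + len(rf))
        r_del = params.large_del_rate if region else 0.0
        total = r_slip + r_point + r_flank + r_del
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > blen:
            break
        u = rng.random() * total
        if u < r_slip:
            idx = rng.choice(len(run_rates), p=run_rates / r_slip)
            run = structure.runs[idx]
            expand = rng.random() < params.expansion_bias
            kind = "slip+" if expand else "slip-"
            event = Event(
                branch, kind, run.start, {"motif": run.motif}
            )
        elif u < r_slip + r_point:
            pos = int(rng.integers(len(region)))
            new = rng.choice([c for c in BASES if c != region[pos]])
            event = Event(
                branch, "point", pos, {"old": region[pos], "new": str(new)}
            )
        elif u < r_slip + r_point + r_flank:
            pos = int(rng.integers(len(lf) + len(rf)))
            which, fpos = ("left", pos) if pos < len(lf) else ("right", pos - len(lf))
            seq = lf if which == "left" else rf
            new = rng.choice([c for c in BASES if c != seq[fpos]])
            event = Event(
                branch,
                "flank_point",
                fpos,
                {"flank": which, "old": seq[fpos], "new": str(new)},
            )
        else:
            lo, hi = params.large_del_span
            span_bp = int(rng.integers(lo, hi + 1)) * params.motif_len
            pos = int(rng.integers(len(region)))
            overrun = 0
            if pos + span_bp > len(region):
                overrun = min(
                    pos + span_bp - len(region),
                    params.large_del_flank_overrun,
                    len(rf),
                )
            event = Event(
                branch,
                "large_del",
                pos,
                {"length": span_bp, "overrun": overrun},
            )
        locus = _apply_event(locus, event)
        events.append(event)
    return locus, events


def _label_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and node.label is None:
            node.label = f"n{i}"
            i += 1


def simulate_locus(
    tree: dendropy.Tree | str,
    root_locus: Locus,
    params: SimParams,
) -> tuple[dict[str, Locus], EventLog]:
    """Evolve *root_locus* down *tree*; return tip states and the event log.

    Deterministic for a fixed ``params.seed``: branches are visited in
    preorder and all randomness flows from one generator.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    lf, region, rf = root_locus
    root_structure = decompose(region, params.motif_len, min_units=1)
    if not root_structure.runs:
        raise InvalidRootError(
            "root repeat region has no runs of the configured motif length"
        )
    _label_nodes(tree)
    rng = np.random.default_rng(params.seed)
    log = EventLog()
    tips: dict[str, Locus] = {}
    states: dict[int, Locus] = {id(tree.seed_node): root_locus}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        blen = node.edge.length if node.edge.length is not None else 1.0
        label = node.taxon.label if node.taxon else node.label
        state, events = _branch_events(parent_state, blen, label, params, rng)
        log.events.extend(events)
        states[id(node)] = state
        if node.is_leaf():
            tips[label] = state
    return tips, log


def replay(
    tree: dendropy.Tree | str, root_locus: Locus, log: EventLog
) -> dict[str, Locus]:
    """Re-derive every tip state by replaying the event log from the root.

    Independent of the simulator's random path: only recorded event details
    are applied.  Serves as the ground-truth oracle for the simulator.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    _label_nodes(tree)
    by_branch: dict[str, list[Event]] = {}
    for e in log.events:
        by_branch.setdefault(e.branch, []).append(e)
    tips: dict[str, Locus] = {}
    states: dict[int, Locus] = {id(tree.seed_node): root_locus}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label = node.taxon.label if node.taxon else node.label
        state = states[id(node.parent_node)]
        for event in by_branch.get(label, []):
            state = _apply_event(state, event)
        states[id(node)] = state
        if node.is_leaf():
            tips[label] = state
    return tips


def tips_to_fasta(
    tips: dict[str, Locus], locus: str = "locus1", path=None
) -> str:
    """FASTA text for tip sequences, ids ``species|individual|locus|allele``."""
    lines = []
    for name in sorted(tips):
        lf, region, rf = tips[name]
        lines.append(f">{name}|1|{locus}|1")
        lines.append(lf + region + rf)
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def generate_observations(
    n: int,
    p_high: float,
    p_low: float,
    T: int = 1,
    repeat_number_distribution=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Observation table (species, locus, repeat_number, dead) from the
    two-regime death model.

    ``repeat_number_distribution`` may be ``None`` (default: uniform
    integers 0..12), a tuple ``("uniform", lo, hi)`` (inclusive),
    ``("poisson", mu)``, ``("two_group", mass_le_T, hi)`` placing
    ``mass_le_T`` probability uniformly on 0..T and the rest uniformly on
    T+1..hi, or a callable ``f(rng, n) -> int array``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, p in (("p_high", p_high), ("p_low", p_low)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dist = repeat_number_distribution
    if dist is None:
        r = rng.integers(0, 13, size=n)
    elif callable(dist):
        r = np.asarray(dist(rng, n), dtype=int)
    elif dist[0] == "uniform":
        r = rng.integers(dist[1], dist[2] + 1, size=n)
    elif dist[0] == "poisson":
        r = rng.poisson(dist[1], size=n)
    elif dist[0] == "two_group":
        low = rng.random(n) < dist[1]
        r = np.where(
            low,
            rng.integers(0, T + 1, size=n),
            rng.integers(T + 1, dist[2] + 1, size=n),
        )
    else:
        raise ValueError(f"unknown distribution spec {dist!r}")
    p = np.where(r <= T, p_high, p_low)
    d = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in range(n)],
            "locus": "locus1",
            "repeat_number": r.astype(int),
            "dead": d,
        }
    )
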