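"""Microsatellite life-cycle classification and phylogenetic state mapping.

A locus is *dead* in a species when the longest uninterrupted run of the
reference major motif has fallen to at most a threshold number of units
(default one): slippage operates on uninterrupted arrays, so a locus reduced
to a solitary unit can no longer expand.  Dead loci are further labelled
with a death mechanism:

``complete_loss``
    the major motif is gone and the region has shortened by at least one
    motif-unit equivalent (large deletion).
``solitary_residual``
    exactly one unit of the major motif survives.
``css_replacement``
    the region retains its length but has degenerated into a cryptic simple
    sequence (high simplicity score, <=1 residual unit).
``interruption_degeneration``
    two or more major-motif units survive in total, but point interruptions
    have broken every pure run down to single units.

Independently of the primary label, a ``motif_replacement`` flag marks the
emergence of a novel repeat run (rebirth at the same genomic position).

Alive/dead tip states are mapped onto a phylogeny by small parsimony
(unit-cost Sankoff, equivalent to Fitch on binary characters), yielding the
minimum number of death/resurrection transitions and the set of branches on
which a most-parsimonious reconstruction can place them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

from .errors import ContractViolationError, DegenerateTreeError, UnknownTipError
from .repeat_core import (
    RepeatStructure,
    SimplicityScore,
    canonicalize_motif,
    decompose,
    longest_pure_run,
)

STATES = ("alive", "dead")
MECHANISMS = (
    "none",
    "unclassified",
    "complete_loss",
    "solitary_residual",
    "css_replacement",
    "interruption_degeneration",
    "motif_replacement",
)


@dataclass
class LifecycleCall:
    species: str
    locus: str
    major_count: int
    state: str
    mechanism: str
    motif_replacement: bool = False
    evidence: str = ""


def classify_state(
    structure: RepeatStructure,
    reference_major: str,
    threshold: int = 1,
    species: str = "",
    locus: str = "",
) -> LifecycleCall:
    """Alive/dead call from the longest pure run of the reference motif.

    ``major_count`` is the longest uninterrupted run of *reference_major*
    (any rotation phase) in the observed region; the locus is dead iff
    ``major_count <= threshold``.  The mechanism of a dead call is left
    ``unclassified`` until :func:`classify_mechanism` resolves it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    major_count = longest_pure_run(structure.region, reference_major)
    dead = major_count <= threshold
    return LifecycleCall(
        species=species,
        locus=locus,
        major_count=major_count,
        state="dead" if dead else "alive",
        mechanism="unclassified" if dead else "none",
        evidence=f"longest pure {reference_major} run = {major_count}, "
        f"threshold = {threshold}",
    )


@dataclass(frozen=True)
class MechanismCall:
    primary: str
    motif_replacement: bool
    evidence: str


def _novel_runs(
    ref: RepeatStructure, obs: RepeatStructure, birth_length: int
) -> list[str]:
    """Canonical motifs (lengths 1-6) with a run >= birth_length in obs only."""
    novel = []
    for L in range(1, 7):
        for run in decompose(obs.region, L, min_units=2).runs:
            if run.count >= birth_length:
                if longest_pure_run(ref.region, run.canonical) < 2:
                    if run.canonical not in novel:
                        novel.append(run.canonical)
    return novel


def _written_major(ref: RepeatStructure) -> str:
    """The reference major motif in its as-written orientation.

    The compound structure of the reference allele fixes the reading phase
    (felid Ptia5 is written (GAA)n, not (AAG)n); residual-unit bookkeeping
    in death calls follows that phase, matching how surviving units are
    counted against the reference structure.
    """
    major_runs = [r for r in ref.runs if r.canonical == ref.major_motif]
    if major_runs:
        return max(major_runs, key=lambda r: r.count).motif
    return ref.major_motif


def _literal_count(region: str, motif: str) -> int:
    """Non-overlapping occurrences of the exact *motif* string."""
    n, p, L = 0, 0, len(motif)
    while p + L <= len(region):
        if region[p : p + L] == motif:
            n += 1
            p += L
        else:
            p += 1
    return n


def classify_mechanism(
    ref: RepeatStructure,
    obs: RepeatStructure,
    region_len_ref: int | None = None,
    region_len_obs: int | None = None,
    simplicity: SimplicityScore | None = None,
    threshold: int = 1,
    length_tolerance: float = 0.5,
    simplicity_cutoff: float = 1.2,
    birth_length: int = 5,
) -> MechanismCall:
    """Resolve the death mechanism of *obs* against the alive reference *ref*.

    Precondition: *obs* must be dead with respect to the reference major
    motif (longest pure run <= *threshold*); calling this on an alive
    structure raises :class:`ContractViolationError`.

    The CSS label requires the region length to be within
    ``length_tolerance`` (fractional) of the reference and the cryptic
    simplicity score to reach ``simplicity_cutoff``.  The cutoff default of
    1.2 sits above the uniform-random background (mean ~1.0) but below pure
    tandem repeats (~1.7 at these lengths); a run of at least
    ``birth_length`` units of a motif absent from the reference raises the
    ``motif_replacement`` flag.
    """
    if ref.major_motif is None:
        raise ContractViolationError("reference structure has no major motif")
    major = ref.major_motif
    if region_len_ref is None:
        region_len_ref = len(ref.region)
    if region_len_obs is None:
        region_len_obs = len(obs.region)

    longest = longest_pure_run(obs.region, major)
    if longest > threshold:
        raise ContractViolationError(
            f"observed structure is alive (longest run {longest} > {threshold})"
        )
    written = _written_major(ref)
    total = _literal_count(obs.region, written)
    novel = _novel_runs(ref, obs, birth_length)
    motif_replacement = bool(novel)

    length_ok = abs(region_len_obs - region_len_ref) <= (
        length_tolerance * region_len_ref
    )
    shortened = region_len_obs <= region_len_ref - len(
        canonicalize_motif(major)[0]
    )
    css_like = (
        simplicity is not None
        and simplicity.score >= simplicity_cutoff
        and length_ok
        and total <= 1
    )

    if total >= 2 and longest <= threshold:
        primary = "interruption_degeneration"
    elif css_like:
        primary = "css_replacement"
    elif total == 0 and shortened:
        primary = "complete_loss"
    elif total == 1:
        primary = "solitary_residual"
    else:
        # zero units but no length loss and no CSS signal: the motif was
        # substituted in place -- treat as complete loss of the repeat
        primary = "complete_loss"

    evidence = (
        f"total {written} units = {total}, longest pure run = {longest}, "
        f"region {region_len_obs}/{region_len_ref} bp"
    )
    if simplicity is not None:
        evidence += f", simplicity = {simplicity.score:.2f}"
    if novel:
        evidence += f", novel runs: {','.join(novel)}"
    return MechanismCall(
        primary=primary, motif_replacement=motif_replacement, evidence=evidence
    )


def annotate_fixation(regions_by_species: dict[str, list[str]]) -> dict[str, bool]:
    """Whether each species' observed regions are identical across inputs.

    String equality of dead regions across conspecific genomes corroborates
    that a death is fixed rather than a polymorphism or artifact.
    """
    return {
        sp: len(set(regions)) == 1 for sp, regions in regions_by_species.items()
    }


@dataclass
class TreeStateMap:
    tree: dendropy.Tree
    tip_states: dict[str, str]
    ancestral_states: dict[str, set] = field(default_factory=dict)
    n_transitions: int = 0
    transition_edges: list[tuple[str, str, str]] = field(default_factory=list)


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def map_states(
    tree: dendropy.Tree | str, tip_states: dict[str, str]
) -> TreeStateMap:
    """Small-parsimony mapping of a binary alive/dead character onto a tree.

    Tips not present in *tip_states* are pruned; a state for a taxon absent
    from the tree raises :class:`UnknownTipError`.  Returns the minimum
    transition count together with every edge on which some
    most-parsimonious reconstruction places a transition, labelled ``loss``
    (alive -> dead) or ``gain`` (dead -> alive).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    else:
        tree = tree.clone(depth=1)
    labels = {t.label for t in tree.taxon_namespace}
    for name, state in tip_states.items():
        if state not in STATES:
            raise ValueError(f"state must be one of {STATES}: {state}")
        if name not in labels:
            raise UnknownTipError(name)
    keep = [t for t in tree.taxon_namespace if t.label in tip_states]
    if len(keep) < 2:
        raise DegenerateTreeError("fewer than 2 tips with states")
    if len(keep) < len(labels):
        tree.retain_taxa(keep)

    # unit-cost Sankoff over the two states (exact for any tree shape,
    # multifurcations included)
    INF = float("inf")
    down: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            down[node] = [0.0 if STATES[i] == s else INF for i in range(2)]
        else:
            cost = [0.0, 0.0]
            for child in node.child_nodes():
                for s in range(2):
                    cost[s] += min(
                        down[child][t] + (s != t) for t in range(2)
                    )
            down[node] = cost

    root = tree.seed_node
    best = min(down[root])

    up: dict[dendropy.Node, list[float]] = {root: [0.0, 0.0]}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        up_cost = []
        for s_child in range(2):
            up_cost.append(
                min(
                    up[parent][s_par]
                    + (s_par != s_child)
                    + sum(
                        min(down[sib][t] + (s_par != t) for t in range(2))
                        for sib in siblings
                    )
                    for s_par in range(2)
                )
            )
        up[node] = up_cost

    internal_index = 0
    ancestral: dict[str, set] = {}
    for node in tree.preorder_node_iter():
        if _node_label(node) is None:
            node.label = f"node{internal_index}"
            internal_index += 1
        states = {
            STATES[s]
            for s in range(2)
            if up[node][s] + down[node][s] == best
        }
        ancestral[_node_label(node)] = states

    transition_edges: list[tuple[str, str, str]] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        for s_par, s_child in itertools.product(range(2), range(2)):
            if s_par == s_child:
                continue
            total = (
                up[parent][s_par]
                + 1
                + down[node][s_child]
                + sum(
                    min(down[sib][t] + (s_par != t) for t in range(2))
                    for sib in siblings
                )
            )
            if total == best:
                direction = "loss" if STATES[s_child] == "dead" else "gain"
                transition_edges.append(
                    (_node_label(parent), _node_label(node), direction)
                )

    return TreeStateMap(
        tree=tree,
        tip_states=dict(tip_states),
        ancestral_states=ancestral,
        n_transitions=int(best),
        transition_edges=transition_edges,
    )
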