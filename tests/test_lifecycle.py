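"""Life-cycle state calls, death mechanisms and parsimony state mapping."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from msatlife import lifecycle as lc
from msatlife import repeat_core as rc
from msatlife.errors import (
    ContractViolationError,
    DegenerateTreeError,
    UnknownTipError,
)

from conftest import CSS_PARADOXURUS, AXOLOTL_EXON_REGION, PREDOMINANT_EXON_ALLELE


@pytest.fixture
def felid_ref():
    return rc.decompose("GAA" * 12, 3, 1)


class TestClassifyState:
    def test_two_units_is_alive(self, felid_ref):
        s = rc.decompose("GGG" + "GAA" * 2 + "CCT", 3, 1)
        call = lc.classify_state(s, "GAA")
        assert call.state == "alive" and call.major_count == 2

    def test_zero_units_is_dead(self):
        s = rc.decompose("GCTGCTGCT", 3, 1)
        call = lc.classify_state(s, "GAA")
        assert call.state == "dead"
        assert call.mechanism == "unclassified"

    def test_long_run_is_alive(self, felid_ref):
        call = lc.classify_state(felid_ref, "GAA")
        assert call.state == "alive" and call.major_count == 12

    def test_monotone_in_threshold(self):
        """Raising the death threshold never flips dead back to alive."""
        s = rc.decompose("GAA" * 3 + "C" + "GAA" * 2, 3, 1)
        states = [
            lc.classify_state(s, "GAA", threshold=t).state for t in range(6)
        ]
        seen_dead = False
        for st in states:
            if st == "dead":
                seen_dead = True
            assert st == "dead" if seen_dead else True


class TestClassifyMechanism:
    def test_css_replacement(self, felid_ref):
        obs = rc.decompose(CSS_PARADOXURUS, 3, 1)
        simp = rc.cryptic_simplicity(CSS_PARADOXURUS, seed=1)
        mech = lc.classify_mechanism(felid_ref, obs, simplicity=simp)
        assert mech.primary == "css_replacement"

    def test_motif_replacement_flag(self, felid_ref):
        """A novel dinucleotide run >= 5 units beside a solitary residual
        trinucleotide unit marks simultaneous death and rebirth."""
        panda_region = "GA" * 7 + "CT" + "GAA" + "TACGT" * 3
        obs = rc.decompose(panda_region, 3, 1)
        mech = lc.classify_mechanism(felid_ref, obs, simplicity=None)
        assert mech.motif_replacement
        assert mech.primary == "solitary_residual"

    def test_interruption_degeneration(self):
        ref = rc.decompose(PREDOMINANT_EXON_ALLELE, 3, 1)
        obs = rc.decompose(AXOLOTL_EXON_REGION, 3, 1)
        mech = lc.classify_mechanism(ref, obs, simplicity=None)
        assert mech.primary == "interruption_degeneration"

    def test_complete_loss_after_deletion(self, felid_ref):
        obs = rc.decompose("GCTTCAAC", 3, 1)  # short, no GAA
        mech = lc.classify_mechanism(felid_ref, obs, simplicity=None)
        assert mech.primary == "complete_loss"

    def test_alive_structure_rejected(self, felid_ref):
        with pytest.raises(ContractViolationError):
            lc.classify_mechanism(felid_ref, felid_ref)


def brute_force_min_changes(tree, tip_states):
    """Enumerate all internal labelings; exact minimum for small trees."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = float("inf")
    for combo in itertools.product(range(2), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        for n in tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            s_par = assign[id(n.parent_node)]
            if n.is_leaf():
                s = 0 if tip_states[n.taxon.label] == "alive" else 1
            else:
                s = assign[id(n)]
            cost += s_par != s
        best = min(best, cost)
    return best


class TestMapStates:
    def test_constant_character(self):
        tm = lc.map_states("((A,B),(C,D));", {t: "alive" for t in "ABCD"})
        assert tm.n_transitions == 0
        assert tm.transition_edges == []

    def test_single_dead_lineage(self):
        """One dead tip on an otherwise alive tree: a single loss on that
        terminal branch."""
        nwk = "((((BayCat,Panthera),Caracal),Ocelot),Outgroup);"
        states = {
            "BayCat": "dead",
            "Panthera": "alive",
            "Caracal": "alive",
            "Ocelot": "alive",
            "Outgroup": "alive",
        }
        tm = lc.map_states(nwk, states)
        assert tm.n_transitions == 1
        assert tm.transition_edges == [
            (tm.transition_edges[0][0], "BayCat", "loss")
        ]

    def test_unknown_tip_raises(self):
        with pytest.raises(UnknownTipError):
            lc.map_states("(A,B);", {"A": "alive", "Z": "dead"})

    def test_degenerate_tree_raises(self):
        with pytest.raises(DegenerateTreeError):
            lc.map_states("(A,B,C);", {"A": "alive"})

    def test_tips_without_states_pruned(self):
        tm = lc.map_states(
            "((A,B),(C,D));", {"A": "alive", "B": "dead", "C": "alive"}
        )
        assert set(tm.tip_states) == {"A", "B", "C"}
        assert tm.n_transitions == 1

    def test_matches_brute_force_on_random_trees(self):
        """Parsimony count equals exhaustive enumeration on trees <= 10
        tips with random binary states."""
        rng = np.random.default_rng(17)
        for trial in range(25):
            ntips = int(rng.integers(4, 11))
            taxa = [f"t{i}" for i in range(ntips)]
            tns = dendropy.TaxonNamespace(taxa)
            tree = dendropy.simulate.treesim.birth_death_tree(
                1.0,
                0.0,
                num_extant_tips=ntips,
                taxon_namespace=tns,
                rng=random.Random(trial),
            )
            states = {
                t: "alive" if rng.random() < 0.5 else "dead" for t in taxa
            }
            tm = lc.map_states(tree, states)
            assert tm.n_transitions == brute_force_min_changes(
                tm.tree, states
            )

    def test_transition_edges_support_optimum(self):
        """Every reported edge admits a most-parsimonious reconstruction
        placing a transition there, and at least n_transitions edges exist."""
        nwk = "(((A,B),(C,D)),(E,F));"
        states = {
            "A": "dead",
            "B": "dead",
            "C": "alive",
            "D": "alive",
            "E": "alive",
            "F": "dead",
        }
        tm = lc.map_states(nwk, states)
        assert tm.n_transitions == 2
        assert len(tm.transition_edges) >= tm.n_transitions
        children = {child for _, child, _ in tm.transition_edges}
        assert "F" in children
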