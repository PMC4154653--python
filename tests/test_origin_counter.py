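"""Origin/HGT counting and the Sankoff engine against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from patchmap.grouping_model import OriginUnits, collapse_units, load_assumptions
from patchmap.origin_counter import (
    CostScheme,
    hgt_events,
    min_origins,
    sankoff,
    summarize,
)
from patchmap.phylo import tree_from_string
from patchmap.synthetic_data import SimParams, simulate_species_tree


def units(*labels, mode="AP", ancient=False):
    return OriginUnits(mode=mode, units=frozenset(labels), ancient=ancient)


def test_min_origins_counts_units():
    assert min_origins(units("cyanobacteria", mode="OP")) == 1
    assert min_origins(units()) == 0
    assert min_origins(units("a", "b", "c")) == 3
    assert min_origins(units("a", "b", "c", ancient=True)) == 1


def test_hgt_is_one_fewer_than_origins():
    assert hgt_events(5) == 4
    assert hgt_events(1) == 0
    assert hgt_events(0) == 0
    with pytest.raises(ValueError):
        hgt_events(-1)


def test_summary_reproduces_published_counts(trait_matrix, default_groupings):
    s = summarize(trait_matrix, default_groupings)
    assert s.total_origins == 26
    assert s.total_hgt == 17
    assert s.hgt("FO") == 4
    for mode in ("AP", "SR", "SO", "FR"):
        assert s.hgt(mode) == 3
    assert s.hgt("SfR") == 1
    for mode in ("OP", "He", "Me"):
        assert s.hgt(mode) == 0
    # identity: total transfers = total origins - number of present modes
    present = sum(1 for o, _ in s.per_mode.values() if o >= 1)
    assert s.total_hgt == s.total_origins - present
    assert present == 9


def test_single_lineage_with_all_modes(default_groupings):
    from patchmap.trait_tables import MODE_CODES, SpeciesRecord, build_trait_matrix

    records = [
        SpeciesRecord(f"Genus sp{m}", f"Ge_sp{m}"[:6] + m, "firmicutes",
                      "bacteria", m)
        for m in MODE_CODES
    ]
    matrix = build_trait_matrix(records)
    s = summarize(matrix, load_assumptions(""))
    assert s.total_origins == 9
    assert s.total_hgt == 0


# --- Sankoff engine ------------------------------------------------------


def star_tree(n):
    return tree_from_string("(" + ",".join(f"t{i}" for i in range(n)) + ");")


def test_star_tree_dollo_costs_one_gain_per_present_leaf():
    tree = star_tree(6)
    states = {f"t{i}": int(i < 3) for i in range(6)}
    res = sankoff(
        tree, states,
        CostScheme(gain_cost=2.0, loss_cost=math.inf, root_state_prior="absent"),
    )
    assert res.min_cost == pytest.approx(6.0)  # 3 gains x cost 2
    assert res.gains == 3
    assert res.losses == 0


def test_single_event_on_clade_edge():
    tree = tree_from_string("((a,b),(c,d));")
    res = sankoff(tree, {"a": 1, "b": 1, "c": 0, "d": 0}, CostScheme())
    assert res.min_cost == pytest.approx(1.0)
    assert res.gains + res.losses == 1


def _brute_force_min_cost(tree, leaf_states, costs):
    """Enumerate every assignment of states to internal nodes."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        root_state = assign[tree.seed_node]
        if costs.root_state_prior == "absent" and root_state == 1:
            continue
        if costs.root_state_prior == "present" and root_state == 0:
            continue
        total = 0.0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            child = (
                leaf_states[node.taxon.label] if node.is_leaf() else assign[node]
            )
            total += costs.edge_cost(assign[node.parent_node], child)
        best = min(best, total)
    return best


def test_sankoff_matches_exhaustive_enumeration():
    rng = np.random.default_rng(20211)
    for rep in range(100):
        n = int(rng.integers(4, 9))
        tree = simulate_species_tree(SimParams(n_leaves=n, seed=int(rng.integers(2**31))))
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        states = {l: int(rng.integers(2)) for l in labels}
        costs = CostScheme(
            gain_cost=float(rng.integers(1, 5)),
            loss_cost=float(rng.integers(1, 5)),
            root_state_prior=["absent", "present", "free"][int(rng.integers(3))],
        )
        if costs.root_state_prior == "present" and not any(states.values()):
            costs = CostScheme(costs.gain_cost, costs.loss_cost, "free")
        res = sankoff(tree, states, costs)
        assert res.min_cost == pytest.approx(
            _brute_force_min_cost(tree, states, costs)
        ), f"replicate {rep}"


def test_sankoff_missing_leaf_state_is_an_error():
    with pytest.raises(ValueError, match="t1"):
        sankoff(star_tree(3), {"t0": 1, "t2": 0}, CostScheme())


def test_star_tree_gains_equal_unit_count(trait_matrix, default_groupings):
    """The two counting paths agree: Dollo parsimony on a star over origin
    units yields exactly min_origins gains."""
    for mode in ("AP", "SO", "FO", "SfR"):
        u = collapse_units(trait_matrix, default_groupings, mode)
        labels = sorted(u.units) + [f"bg{i}" for i in range(3)]
        tree = tree_from_string("(" + ",".join(labels) + ");")
        states = {l: int(l in u.units) for l in labels}
        res = sankoff(
            tree, states,
            CostScheme(loss_cost=math.inf, root_state_prior="absent"),
        )
        assert res.gains == min_origins(u)


def test_min_cost_invariant_under_rerooting_with_symmetric_costs():
    newick = "((a,(b,c)),((d,e),f));"
    tree = tree_from_string(newick)
    states = {"a": 1, "b": 0, "c": 1, "d": 0, "e": 1, "f": 0}
    base = sankoff(tree, states, CostScheme()).min_cost
    for target in ("b", "d", "f"):
        t2 = tree_from_string(newick)
        leaf = [lf for lf in t2.leaf_node_iter() if lf.taxon.label == target][0]
        t2.reroot_at_edge(leaf.edge)
        assert sankoff(t2, states, CostScheme()).min_cost == pytest.approx(base)


def test_adding_present_leaf_never_cheapens_dollo():
    costs = CostScheme(loss_cost=math.inf, root_state_prior="absent")
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 8))
        base = star_tree(n)
        states = {f"t{i}": int(rng.integers(2)) for i in range(n)}
        before = sankoff(base, states, costs).min_cost
        grown = star_tree(n + 1)
        after = sankoff(grown, {**states, f"t{n}": 1}, costs).min_cost
        assert after >= before
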