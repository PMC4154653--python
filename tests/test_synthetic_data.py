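"""Simulator contracts: determinism, trivial regimes, ground-truth
reconciliation, and the parsimony bound."""

import math

import numpy as np
import pytest
from scipy import stats

from patchmap.origin_counter import CostScheme, hgt_events, sankoff
from patchmap.synthetic_data import (
    SimParams,
    simulate_gene_family,
    simulate_locus_evolution,
    simulate_species_tree,
    simulate_trait_history,
)
from patchmap.locus_architect import pattern_string, split_junctions, segment_blocks


def test_tree_leaf_and_internal_counts():
    tree = simulate_species_tree(SimParams(n_leaves=5, seed=1))
    leaves = [n for n in tree.leaf_node_iter()]
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    assert len(leaves) == 5
    assert len(internals) == 4  # rooted binary: n-1


def test_tree_deterministic_under_seed():
    a = simulate_species_tree(SimParams(n_leaves=12, seed=42))
    b = simulate_species_tree(SimParams(n_leaves=12, seed=42))
    assert a.as_string(schema="newick") == b.as_string(schema="newick")
    c = simulate_species_tree(SimParams(n_leaves=12, seed=43))
    assert a.as_string(schema="newick") != c.as_string(schema="newick")


def test_two_leaves_is_a_cherry():
    tree = simulate_species_tree(SimParams(n_leaves=2, seed=0))
    assert len(tree.seed_node.child_nodes()) == 2
    assert all(c.is_leaf() for c in tree.seed_node.child_nodes())


def test_trait_history_trivial_regime_all_present():
    params = SimParams(n_leaves=10, seed=3, gain_rate=0.0, loss_rate=0.0,
                       hgt_rate=0.0, root_present=True)
    tree = simulate_species_tree(params)
    states, truth = simulate_trait_history(tree, params)
    assert all(v == 1 for v in states.values())
    assert truth.events == []


def _replay(tree, truth, root_present):
    """Re-derive leaf states from the event log alone."""
    state = {tree.seed_node: int(root_present)}
    by_branch = {}
    for branch, event, _ in truth.events:
        by_branch.setdefault(branch, []).append(event)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        name = node.taxon.label if node.taxon else node.label
        s = state[node.parent_node]
        for event in by_branch.get(name, []):
            s = {"gain": 1, "transfer": 1, "loss": 0}[event]
        state[node] = s
    return {lf.taxon.label: state[lf] for lf in tree.leaf_node_iter()}


def test_event_log_replays_to_leaf_states():
    for seed in range(10):
        params = SimParams(n_leaves=15, seed=seed, gain_rate=0.3,
                           loss_rate=0.2, hgt_rate=0.2)
        tree = simulate_species_tree(params)
        states, truth = simulate_trait_history(tree, params)
        assert _replay(tree, truth, params.root_present) == states


def test_parsimony_bound_on_true_tree():
    """Unit-cost parsimony never needs more events than the true history:
    the simulated history is itself a feasible explanation, so the minimum
    cost is bounded by the total number of true events."""
    for seed in range(30):
        params = SimParams(n_leaves=12, seed=seed, gain_rate=0.2,
                           loss_rate=0.1, hgt_rate=0.15)
        tree = simulate_species_tree(params)
        states, truth = simulate_trait_history(tree, params)
        if not any(states.values()):
            continue
        res = sankoff(tree, states, CostScheme(root_state_prior="absent"))
        total_events = (
            truth.true_gains + truth.true_losses + truth.true_transfers
        )
        assert res.min_cost <= total_events


def test_transfer_rich_histories_tracked_by_inferred_events():
    """When transfers dominate gains, the inferred alternative-transfer count
    follows the true transfer count (rank correlation)."""
    inferred, truth_counts = [], []
    for seed in range(200):
        params = SimParams(n_leaves=15, seed=seed, gain_rate=0.05,
                           loss_rate=0.0, hgt_rate=0.4)
        tree = simulate_species_tree(params)
        states, truth = simulate_trait_history(tree, params)
        res = sankoff(
            tree, states,
            CostScheme(loss_cost=math.inf, root_state_prior="absent"),
        )
        inferred.append(hgt_events(res.gains))
        truth_counts.append(truth.true_transfers)
    rho = stats.spearmanr(inferred, truth_counts).statistic
    assert rho > 0.7


def test_gene_family_congruent_without_duplication():
    params = SimParams(n_leaves=9, seed=5, dup_rate=0.0)
    tree = simulate_species_tree(params)
    family, truth = simulate_gene_family(tree, params)
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    assert sorted(family.species_map.values()) == species  # one copy each
    assert truth.events == []


def test_locus_identity_without_events():
    params = SimParams(n_leaves=6, seed=2, split_prob=0.0, dup_rate=0.0,
                       gene_loss_prob=0.0)
    tree = simulate_species_tree(params)
    loci, truth = simulate_locus_evolution(tree, params)
    assert len(loci) == 6
    for locus in loci:
        assert pattern_string(locus) == "-".join(params.ancestral_order)
    assert truth.events == []


def test_forced_split_found_at_every_leaf():
    # a two-gene ancestral locus has a single junction, so split_prob=1
    # severs the same adjacency on the root branches of every lineage
    params = SimParams(n_leaves=5, seed=9, split_prob=1.0, dup_rate=0.0,
                       gene_loss_prob=0.0, ancestral_order=("0A", "0C"))
    tree = simulate_species_tree(params)
    loci, _ = simulate_locus_evolution(tree, params)
    for locus in loci:
        assert split_junctions(segment_blocks(locus), ["0A", "0C"]) == {"0A|0C"}


def test_locus_simulation_deterministic():
    params = SimParams(n_leaves=8, seed=11)
    tree = simulate_species_tree(params)
    a, _ = simulate_locus_evolution(tree, params)
    tree2 = simulate_species_tree(params)
    b, _ = simulate_locus_evolution(tree2, params)
    assert [pattern_string(l) for l in a] == [pattern_string(l) for l in b]


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(n_leaves=1)
    with pytest.raises(ValueError):
        SimParams(gain_rate=-0.1)
    with pytest.raises(ValueError):
        SimParams(split_prob=1.5)
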