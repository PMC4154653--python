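"""Simulators with known ground truth for every pipeline stage.

The generators produce rooted species trees (pure-birth topology, unit
branch lengths), binary trait histories with gains, losses and horizontal
transfers, gene families grown inside a species tree with duplications, and
locus evolution from a known ancestral gene order by splits, in-locus
duplications, ectopic relocations and gene losses.  Every simulator logs
its events so inferred quantities can be checked against the truth, and is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from patchmap.locus_architect import CANONICAL_ORDER, Gene, GenomeLocus
from patchmap.gene_tree_classifier import COPY_SEP, GeneFamily

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_species_tree",
    "simulate_trait_history",
    "simulate_gene_family",
    "simulate_locus_evolution",
]


@dataclass(frozen=True)
class SimParams:
    """Event rates and sizes shared by the simulators.

    Rates are events per unit branch length (branches default to length 1,
    so per-branch); probabilities are per branch.  The defaults give a
    sparsely patchy trait (few gains, rare loss/transfer) and a locus that
    accumulates a handful of splits and duplications across a 20-leaf tree,
    the regime the locus analyses are meant for.
    """

    n_leaves: int = 20
    seed: int = 0
    gain_rate: float = 0.1
    loss_rate: float = 0.05
    hgt_rate: float = 0.05
    dup_rate: float = 0.1
    split_prob: float = 0.2
    gene_loss_prob: float = 0.05
    ancestral_order: tuple[str, ...] = tuple(CANONICAL_ORDER)
    root_present: bool = False
    branch_length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        for name in ("gain_rate", "loss_rate", "hgt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dup_rate", "split_prob", "gene_loss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Event log and tallies of a simulation run."""

    events: list[tuple[str, str, object]] = field(default_factory=list)
    true_ancestral: object = None

    def log(self, branch: str, event: str, payload: object = None) -> None:
        self.events.append((branch, event, payload))

    def count(self, event: str) -> int:
        return sum(1 for _, e, _ in self.events if e == event)

    @property
    def true_gains(self) -> int:
        return self.count("gain")

    @property
    def true_losses(self) -> int:
        return self.count("loss")

    @property
    def true_transfers(self) -> int:
        return self.count("transfer")


def _node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else (node.label or "root")


def simulate_species_tree(params: SimParams) -> dendropy.Tree:
    """Pure-birth rooted binary tree with ``n_leaves`` labeled tips.

    At each step a uniformly chosen tip splits in two; edges get
    ``branch_length``.  Tips are named t01, t02, …; internal nodes n1, n2, …
    in creation order.  Deterministic under a fixed seed.
    """
    rng = params.rng()
    width = max(2, len(str(params.n_leaves)))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.label = "n0"
    tips = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = params.branch_length
        tree.seed_node.add_child(child)
        tips.append(child)
    internal_count = 0
    while len(tips) < params.n_leaves:
        parent = tips.pop(int(rng.integers(len(tips))))
        internal_count += 1
        parent.label = f"n{internal_count}"
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = params.branch_length
            parent.add_child(child)
            tips.append(child)
    # Name tips in a stable traversal order.
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = taxa.new_taxon(f"t{i:0{width}d}")
    return tree


def simulate_trait_history(
    tree: dendropy.Tree, params: SimParams
) -> tuple[dict[str, int], GroundTruth]:
    """Evolve a binary presence/absence trait root→tips.

    On each branch, gains and losses arrive as Poisson counts at
    ``gain_rate``/``loss_rate`` per unit length and toggle the state; a
    transfer (rate ``hgt_rate``) copies presence from a random lineage
    currently bearing the trait, if any — an undirected, donor-agnostic
    transfer model.  Returns leaf states (1 present) and the event log.
    """
    rng = params.rng()
    truth = GroundTruth()
    state: dict[dendropy.Node, int] = {tree.seed_node: int(params.root_present)}
    # Process branches in preorder; "current bearers" are the states at the
    # already-resolved frontier, a discrete stand-in for contemporaneity.
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = state[node.parent_node]
        bl = node.edge.length or params.branch_length
        name = _node_name(node)
        n_gain = rng.poisson(params.gain_rate * bl)
        n_loss = rng.poisson(params.loss_rate * bl)
        n_hgt = rng.poisson(params.hgt_rate * bl)
        for _ in range(n_gain):
            if s == 0:
                s = 1
                truth.log(name, "gain")
        for _ in range(n_loss):
            if s == 1:
                s = 0
                truth.log(name, "loss")
        if n_hgt:
            bearers = [n for n, st in state.items() if st == 1 and n is not node]
            for _ in range(n_hgt):
                if bearers and s == 0:
                    donor = bearers[int(rng.integers(len(bearers)))]
                    s = 1
                    truth.log(name, "transfer", _node_name(donor))
        state[node] = s
    leaf_states = {
        leaf.taxon.label: state[leaf] for leaf in tree.leaf_node_iter()
    }
    truth.true_ancestral = int(params.root_present)
    return leaf_states, truth


def simulate_gene_family(
    tree: dendropy.Tree,
    params: SimParams,
    forced_terminal_dup: str | None = None,
    forced_root_paralog: bool = False,
    support: tuple[float, float] = (1.0, 100.0),
) -> tuple[GeneFamily, GroundTruth]:
    """Grow a gene tree inside the species tree with per-branch duplications.

    Each species-tree branch duplicates the gene lineage with probability
    ``dup_rate``; both copies then descend through the subtree below.  Leaf
    names follow ``<species>__c<k>``.  Node supports are set to ``support``
    (posterior/bootstrap, rendered as internal-node labels); degrade them
    separately to probe threshold behaviour.

    ``forced_terminal_dup`` duplicates the gene on one terminal branch (an
    SSD by construction); ``forced_root_paralog`` duplicates at the root so
    a full paralog clade exists beside the canonical copies.
    """
    rng = params.rng()
    truth = GroundTruth()
    counters: dict[str, int] = {}
    sup_label = f"{support[0]:g}/{support[1]:g}"

    def copy_name(species: str) -> str:
        counters[species] = counters.get(species, 0) + 1
        return f"{species}{COPY_SEP}{counters[species]}"

    def grow(sp_node: dendropy.Node, origin: str) -> dendropy.Node:
        """Gene subtree tracking the species subtree below ``sp_node``."""
        if sp_node.is_leaf():
            leaf = dendropy.Node()
            leaf.label = copy_name(sp_node.taxon.label)
            return leaf
        gene = dendropy.Node(label=sup_label)
        for sp_child in sp_node.child_nodes():
            sub = descend(sp_child, origin)
            gene.add_child(sub)
        return gene

    def descend(sp_child: dendropy.Node, origin: str) -> dendropy.Node:
        if rng.random() < params.dup_rate:
            truth.log(_node_name(sp_child), "duplication", origin)
            dup = dendropy.Node(label=sup_label)
            dup.add_child(grow(sp_child, origin))
            dup.add_child(grow(sp_child, origin))
            return dup
        return grow(sp_child, origin)

    root = dendropy.Node(label=sup_label)
    if forced_root_paralog:
        truth.log("root", "duplication", "paralog")
        for origin in ("canonical", "paralog"):
            sub = dendropy.Node(label=sup_label)
            for sp_child in tree.seed_node.child_nodes():
                sub.add_child(grow(sp_child, origin))
            root.add_child(sub)
    else:
        for sp_child in tree.seed_node.child_nodes():
            root.add_child(descend(sp_child, "canonical"))

    gene_tree = dendropy.Tree()
    gene_tree.seed_node = root

    if forced_terminal_dup is not None:
        target = None
        for leaf in gene_tree.leaf_node_iter():
            if leaf.label.split(COPY_SEP)[0] == forced_terminal_dup:
                target = leaf
                break
        if target is None:
            raise ValueError(f"no copy of species {forced_terminal_dup!r}")
        truth.log(forced_terminal_dup, "duplication", "terminal")
        a = dendropy.Node()
        a.label = target.label
        b = dendropy.Node()
        b.label = copy_name(forced_terminal_dup)
        target.label = sup_label
        target.add_child(a)
        target.add_child(b)

    # Promote leaf labels to taxa so dendropy treats them as tips.
    taxa = dendropy.TaxonNamespace()
    gene_tree.taxon_namespace = taxa
    species_map: dict[str, str] = {}
    for leaf in gene_tree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.label)
        species_map[leaf.label] = leaf.label.split(COPY_SEP)[0]
        leaf.label = None
    family = GeneFamily(tree=gene_tree, species_map=species_map)
    return family, truth


def simulate_locus_evolution(
    tree: dendropy.Tree, params: SimParams
) -> tuple[list[GenomeLocus], GroundTruth]:
    """Evolve a gene locus down the tree from ``params.ancestral_order``.

    On each branch, independently: with ``split_prob`` the locus gains a
    split at a uniformly chosen junction (a large ORF gap is inserted);
    with ``dup_rate`` a uniformly chosen gene acquires an adjacent in-locus
    duplicate; with ``gene_loss_prob`` a uniformly chosen gene is lost
    (never the last one).  Leaves emit :class:`GenomeLocus` tables with
    re-serialized ORF indices.
    """
    rng = params.rng()
    truth = GroundTruth()
    truth.true_ancestral = list(params.ancestral_order)
    # A locus state is a list of blocks; each block a list of labels.
    root_state: list[list[str]] = [list(params.ancestral_order)]

    def evolve(state: list[list[str]], branch: str) -> list[list[str]]:
        state = [list(b) for b in state]
        if rng.random() < params.split_prob:
            sizes = [len(b) for b in state]
            junctions = sum(max(s - 1, 0) for s in sizes)
            if junctions:
                j = int(rng.integers(junctions))
                for bi, s in enumerate(sizes):
                    if j < s - 1:
                        blk = state[bi]
                        state[bi:bi + 1] = [blk[: j + 1], blk[j + 1:]]
                        truth.log(branch, "split", (blk[j], blk[j + 1]))
                        break
                    j -= max(s - 1, 0)
        if rng.random() < params.dup_rate:
            total = sum(len(b) for b in state)
            g = int(rng.integers(total))
            for blk in state:
                if g < len(blk):
                    blk.insert(g + 1, blk[g])
                    truth.log(branch, "duplication", blk[g])
                    break
                g -= len(blk)
        if rng.random() < params.gene_loss_prob:
            total = sum(len(b) for b in state)
            if total > 1:
                g = int(rng.integers(total))
                for bi, blk in enumerate(state):
                    if g < len(blk):
                        truth.log(branch, "loss", blk[g])
                        del blk[g]
                        if not blk:
                            del state[bi]
                        break
                    g -= len(blk)
        return state

    states: dict[dendropy.Node, list[list[str]]] = {tree.seed_node: root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        states[node] = evolve(states[node.parent_node], _node_name(node))

    loci: list[GenomeLocus] = []
    for leaf in tree.leaf_node_iter():
        genes: list[Gene] = []
        idx = 0
        for bi, blk in enumerate(states[leaf]):
            if bi:
                idx += 50  # comfortably beyond any max_intervening in use
            for label in blk:
                genes.append(Gene(label=label, replicon="chr", orf_index=idx))
                idx += 1
        loci.append(GenomeLocus(species=leaf.taxon.label, genes=genes))
    return loci, truth
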