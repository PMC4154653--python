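"""Rule-based classification of extra gene copies against a species backbone.

Given a gene tree whose leaves are ``<species>__c<k>`` copies, each extra
copy is classified by where it attaches:

* **SSD** — species-specific duplication: the copy's sister group (at a
  supported node) consists only of copies from the same species.
* **LSD** — lineage-specific duplication: the smallest supported clade
  containing the copy holds extra copies of two or more species that form
  a clade in the species tree, i.e. the duplication predates their split.
* **paralog_clade** — the copy belongs to a deep, robustly supported clade
  made entirely of extra copies spanning several lineages (the pattern of
  an anciently transferred paralogous locus such as the N-ATPase).
* **HGT_candidate** — the copy nests, with robust support, inside a clade
  whose other members all belong to a foreign lineage (reported as donor).
* **unresolved** otherwise.

Classification is rule-based, mirroring how such calls are read off
published trees; it is not a reconciliation optimization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy

from patchmap.phylo import Support, node_support, tree_from_string

__all__ = [
    "GeneFamily",
    "SupportThresholds",
    "DuplicationCall",
    "extra_copies",
    "classify_copy",
    "detect_paralog_clade",
    "root_at_paralog_clade",
    "flag_overhangs",
]

COPY_SEP = "__c"


@dataclass
class GeneFamily:
    """A gene tree plus leaf→species and species→lineage maps."""

    tree: dendropy.Tree
    species_map: dict[str, str]
    lineage_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_newick(
        cls, newick: str, lineage_map: dict[str, str] | None = None
    ) -> "GeneFamily":
        """Parse a newick gene tree using the ``<species>__c<k>`` leaf
        convention; a leaf without the copy suffix is its species' sole copy."""
        tree = tree_from_string(newick)
        species_map: dict[str, str] = {}
        seen: set[str] = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if label in seen:
                raise ValueError(f"duplicate leaf label {label!r}")
            seen.add(label)
            species_map[label] = label.split(COPY_SEP)[0]
        return cls(tree=tree, species_map=species_map, lineage_map=lineage_map or {})

    def species_of(self, leaf_label: str) -> str:
        return self.species_map[leaf_label]

    def lineage_of(self, leaf_label: str) -> str:
        sp = self.species_of(leaf_label)
        return self.lineage_map.get(sp, sp)

    def find_leaf(self, label: str) -> dendropy.Node:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"no leaf named {label!r}")


@dataclass(frozen=True)
class SupportThresholds:
    """Two support levels: *robust* and the weaker *shown*.

    Each level is a (posterior, bootstrap) pair.  When a node carries both
    annotations both must pass; when it carries only one, that one decides.
    A node with no annotation fails every level.
    """

    robust: tuple[float, float] = (0.95, 80.0)
    shown: tuple[float, float] = (0.80, 50.0)

    def __post_init__(self) -> None:
        if self.robust[0] < self.shown[0] or self.robust[1] < self.shown[1]:
            raise ValueError("robust thresholds must dominate shown thresholds")

    def meets(self, support: Support, level: str) -> bool:
        post_min, boot_min = getattr(self, level)
        checks = []
        if support.posterior is not None:
            checks.append(support.posterior >= post_min)
        if support.bootstrap is not None:
            checks.append(support.bootstrap >= boot_min)
        return bool(checks) and all(checks)

    def node_meets(self, node: dendropy.Node, level: str) -> bool:
        return self.meets(node_support(node), level)


@dataclass
class DuplicationCall:
    species: str
    subunit: str | None
    call: str  # SSD | LSD | HGT_candidate | paralog_clade | unresolved
    evidence: tuple[str | None, Support] | None = None
    donor_lineage: str | None = None

    def __post_init__(self) -> None:
        if (self.donor_lineage is not None) != (self.call == "HGT_candidate"):
            raise ValueError("donor_lineage set iff call is HGT_candidate")


def extra_copies(family: GeneFamily) -> dict[str, int]:
    """Species with two or more leaves in the family, with their counts."""
    counts = Counter(family.species_map.values())
    return {sp: n for sp, n in counts.items() if n >= 2}


def _leaves_under(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def _species_form_clade(
    species: set[str], species_tree: dendropy.Tree, lineage_map: dict[str, str]
) -> bool:
    """Do these species form a clade in the (possibly lineage-level) backbone?

    Each species is mapped to its own leaf if present, else to its lineage's
    leaf (lineages as polytomies).  A single mapped leaf is trivially a clade.
    """
    tree_leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    mapped: set[str] = set()
    for sp in species:
        if sp in tree_leaves:
            mapped.add(sp)
        elif lineage_map.get(sp) in tree_leaves:
            mapped.add(lineage_map[sp])
        else:
            return False
    if len(mapped) == 1:
        return True
    mrca = species_tree.mrca(taxon_labels=sorted(mapped))
    if mrca is None:
        return False
    return set(_leaves_under(mrca)) == mapped


def detect_paralog_clade(
    family: GeneFamily,
    min_lineages: int = 2,
    thresholds: SupportThresholds = SupportThresholds(),
) -> dendropy.Node | None:
    """Largest robustly supported clade made entirely of extra copies
    spanning at least ``min_lineages`` lineages; ``None`` if absent.

    Such a clade is the signature of an ancient paralogous locus carried in
    addition to the canonical one; the family tree may then be rooted at it.
    """
    if min_lineages < 2:
        raise ValueError("min_lineages must be >= 2")
    dup_species = set(extra_copies(family))
    best: dendropy.Node | None = None
    best_size = 0
    for node in family.tree.preorder_internal_node_iter():
        if node is family.tree.seed_node:
            continue
        if not thresholds.node_meets(node, "robust"):
            continue
        leaves = _leaves_under(node)
        if not all(family.species_of(l) in dup_species for l in leaves):
            continue
        lineages = {family.lineage_of(l) for l in leaves}
        if len(lineages) < min_lineages:
            continue
        if len(leaves) > best_size:
            best, best_size = node, len(leaves)
    return best


def root_at_paralog_clade(family: GeneFamily, clade: dendropy.Node) -> None:
    """Re-root the family tree on the branch subtending the paralog clade
    (in place).  Copy counts are unaffected by rooting."""
    family.tree.reroot_at_edge(clade.edge, update_bipartitions=False)


def classify_copy(
    family: GeneFamily,
    species_tree: dendropy.Tree,
    leaf: str | dendropy.Node,
    thresholds: SupportThresholds = SupportThresholds(),
    min_lineages: int = 2,
    subunit: str | None = None,
) -> DuplicationCall:
    """Classify one extra copy.  The copy must belong to a duplicated species.

    Rules are applied in order SSD → LSD → paralog_clade → HGT_candidate →
    unresolved; membership in a detected paralog clade takes precedence over
    the foreign-lineage nesting test, since an ancient paralog clade always
    nests among foreign lineages by construction.
    """
    node = family.find_leaf(leaf) if isinstance(leaf, str) else leaf
    label = node.taxon.label
    species = family.species_of(label)
    lineage = family.lineage_of(label)
    dup_species = set(extra_copies(family))
    if species not in dup_species:
        raise ValueError(f"leaf {label!r} belongs to a non-duplicated species")

    # SSD: sister group at a supported parent is all same-species copies.
    parent = node.parent_node
    if parent is not None and thresholds.node_meets(parent, "shown"):
        sisters = [l for l in _leaves_under(parent) if l != label]
        if sisters and all(family.species_of(l) == species for l in sisters):
            return DuplicationCall(
                species=species,
                subunit=subunit,
                call="SSD",
                evidence=(parent.label, node_support(parent)),
            )

    # Smallest supported clade containing the copy.
    smallest_shown = None
    anc = node.parent_node
    while anc is not None:
        if thresholds.node_meets(anc, "shown"):
            smallest_shown = anc
            break
        anc = anc.parent_node

    # LSD: that clade holds extra copies of >=2 species forming a species clade.
    if smallest_shown is not None:
        clade_dup_species = {
            family.species_of(l)
            for l in _leaves_under(smallest_shown)
            if family.species_of(l) in dup_species
        }
        if len(clade_dup_species) >= 2 and _species_form_clade(
            clade_dup_species, species_tree, family.lineage_map
        ):
            return DuplicationCall(
                species=species,
                subunit=subunit,
                call="LSD",
                evidence=(smallest_shown.label, node_support(smallest_shown)),
            )

    # Ancient paralog clade membership.
    paralog = detect_paralog_clade(family, min_lineages=min_lineages, thresholds=thresholds)
    if paralog is not None and label in _leaves_under(paralog):
        return DuplicationCall(
            species=species,
            subunit=subunit,
            call="paralog_clade",
            evidence=(paralog.label, node_support(paralog)),
        )

    # HGT candidate: nested among a foreign lineage with robust support.
    smallest_robust = None
    anc = node.parent_node
    while anc is not None:
        if thresholds.node_meets(anc, "robust"):
            smallest_robust = anc
            break
        anc = anc.parent_node
    if smallest_robust is not None:
        others = [
            l
            for l in _leaves_under(smallest_robust)
            if family.species_of(l) != species
        ]
        other_lineages = [family.lineage_of(l) for l in others]
        if others and lineage not in other_lineages:
            tally = Counter(other_lineages).most_common()
            if len(tally) == 1 or tally[0][1] > tally[1][1]:
                return DuplicationCall(
                    species=species,
                    subunit=subunit,
                    call="HGT_candidate",
                    evidence=(smallest_robust.label, node_support(smallest_robust)),
                    donor_lineage=tally[0][0],
                )

    return DuplicationCall(species=species, subunit=subunit, call="unresolved")


def flag_overhangs(
    copy_lengths: dict[str, tuple[float, float]],
    threshold_aa: int = 100,
) -> dict[str, set[str]]:
    """Flag copies whose terminal overhangs against the orthogroup alignment
    reach ``threshold_aa`` amino acids.

    ``copy_lengths`` maps copy id → (leading overhang, trailing overhang) in
    aa.  Returns copy → subset of {"N_extension", "C_extension"}; copies with
    no flag are omitted.
    """
    flags: dict[str, set[str]] = {}
    for copy, (lead, trail) in copy_lengths.items():
        if lead < 0 or trail < 0:
            raise ValueError(f"negative overhang for copy {copy!r}")
        hits: set[str] = set()
        if lead >= threshold_aa:
            hits.add("N_extension")
        if trail >= threshold_aa:
            hits.add("C_extension")
        if hits:
            flags[copy] = hits
    return flags
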