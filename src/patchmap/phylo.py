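"""Shared tree plumbing: rooted newick I/O and node-support annotations.

Trees are dendropy ``Tree`` objects throughout.  Node support is an
optional pair (posterior probability in [0, 1], bootstrap percentage in
[0, 100]); in newick it is carried on internal-node labels either as a
single number or as ``posterior/bootstrap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = ["Support", "parse_support_label", "read_tree", "tree_from_string",
           "node_support", "leaf_labels"]


@dataclass(frozen=True)
class Support:
    """Node support: either component may be missing."""

    posterior: float | None = None
    bootstrap: float | None = None

    def __post_init__(self) -> None:
        if self.posterior is not None and not (0.0 <= self.posterior <= 1.0):
            raise ValueError(f"posterior out of [0,1]: {self.posterior}")
        if self.bootstrap is not None and not (0.0 <= self.bootstrap <= 100.0):
            raise ValueError(f"bootstrap out of [0,100]: {self.bootstrap}")


def parse_support_label(label: str | None) -> Support:
    """Parse a node label into a :class:`Support`.

    ``"0.97/85"`` gives both components; a lone number is read as a
    posterior if ≤ 1, else as a bootstrap percentage.  Non-numeric labels
    give an empty Support.
    """
    if not label:
        return Support()
    parts = label.strip().split("/")
    try:
        values = [float(p) for p in parts]
    except ValueError:
        return Support()
    if len(values) == 2:
        return Support(posterior=values[0], bootstrap=values[1])
    if len(values) == 1:
        v = values[0]
        return Support(posterior=v) if v <= 1.0 else Support(bootstrap=v)
    return Support()


def tree_from_string(newick: str, rooted: bool = True) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Internal-node labels are preserved (not misread as taxa) so support
    annotations survive.
    """
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted" if rooted else "default-unrooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def read_tree(path: str, rooted: bool = True) -> dendropy.Tree:
    """Read a newick file into a rooted dendropy tree."""
    with open(path) as fh:
        return tree_from_string(fh.read(), rooted=rooted)


def node_support(node: dendropy.Node) -> Support:
    """Support pair of an internal node, parsed from its label."""
    return parse_support_label(node.label)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf taxon labels in the tree's leaf-iteration order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]
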