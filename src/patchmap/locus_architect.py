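"""ATP-synthase locus maps: blocks, splits, duplicates, signatures, ancestry.

A genome's ATP-synthase locus is an ordered list of subunit-labeled genes
(serial ORF indices along a replicon, with strand).  This module segments
the list into syntenic blocks, names split junctions against a reference
gene order, distinguishes in-locus from ectopic duplicates, recognizes the
N-ATPase signature (atpR present, delta subunit absent, characteristic
order), renders the per-genome pattern notation, and infers an ancestral
gene order by adjacency parsimony: every ordered neighbour pair observed
within a block is a binary character, ancestral presence is inferred by
Fitch parsimony over a backbone, and the ancestral order is the
maximum-weight Hamiltonian path through the resulting adjacency graph.

Coordinates are 0-based ORF serial indices (the field counts "intervening
ORFs", not base pairs); ``X`` marks hypothetical intervening genes and
``?`` marks ATPI-family genes whose orthology is unclear — both ride along
in blocks and pattern strings but contribute no adjacency characters.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import dendropy

__all__ = [
    "VALID_LABELS",
    "CORE_LABELS",
    "CANONICAL_ORDER",
    "N_ATPASE_ORDER",
    "Gene",
    "GenomeLocus",
    "LocusBlocks",
    "read_locus_table",
    "write_locus_table",
    "segment_blocks",
    "split_junctions",
    "name_b_prime",
    "classify_placement",
    "detect_n_atpase",
    "pattern_string",
    "parse_pattern",
    "locus_from_pattern",
    "ancestral_order",
]

#: All recognized subunit labels.  0B' is the upstream copy of a duplicated
#: 0B; X is a hypothetical intervening ORF; ? an unassignable ATPI-family gene.
VALID_LABELS = frozenset(
    {"I", "sI", "R", "0A", "0C", "0B", "0B'", "ID", "IA", "IG", "IB", "IE", "X", "?"}
)
CORE_LABELS = frozenset(VALID_LABELS - {"X", "?"})

#: Inferred ancestral order of the canonical F0F1 locus.
CANONICAL_ORDER = ["I", "sI", "0A", "0C", "0B", "ID", "IA", "IG", "IB", "IE"]
#: Characteristic order of the N-ATPase locus (no ID, atpR present).
N_ATPASE_ORDER = ["IB", "IE", "I", "R", "0A", "0C", "0B", "IA", "IG"]

#: KEGG orthology ids of the canonical subunits.
KO_IDS = {
    "0A": "K02108", "0B": "K02109", "0C": "K02110", "IA": "K02111",
    "IB": "K02112", "ID": "K02113", "IE": "K02114", "IG": "K02115",
    "I": "K02116", "sI": "K02116",
}


def normalize_label(label: str) -> str:
    """Map the unicode prime variant to the ASCII form and validate."""
    label = label.strip().replace("′", "'")
    if label not in VALID_LABELS:
        raise ValueError(f"unknown subunit label {label!r}")
    return label


@dataclass(frozen=True)
class Gene:
    """One gene: subunit label, replicon, 0-based serial ORF index, strand."""

    label: str
    replicon: str
    orf_index: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", normalize_label(self.label))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.orf_index < 0:
            raise ValueError("orf_index must be >= 0")


@dataclass
class GenomeLocus:
    """All ATP-synthase genes of one genome, in replicon/index order."""

    species: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"locus for {self.species!r} has no genes")
        last: dict[str, int] = {}
        for g in self.genes:
            if g.replicon in last and g.orf_index <= last[g.replicon]:
                raise ValueError(
                    f"{self.species}: orf_index not strictly increasing on "
                    f"replicon {g.replicon!r}"
                )
            last[g.replicon] = g.orf_index


@dataclass
class LocusBlocks:
    """Syntenic blocks of a locus and the inter-block gaps.

    ``gaps[i]`` is the intervening-ORF count between blocks i and i+1 when
    both sit on the same replicon, else ``None`` (replicon change).
    """

    blocks: list[list[Gene]]
    gaps: list[int | None] = field(default_factory=list)

    def oriented_labels(self, i: int) -> list[str]:
        """Labels of block ``i`` in transcription order (majority strand)."""
        return oriented_labels(self.blocks[i])

    def all_genes(self) -> list[Gene]:
        return [g for b in self.blocks for g in b]


def oriented_labels(block: Sequence[Gene]) -> list[str]:
    """Block labels read upstream→downstream: flipped when the majority
    strand is '-'."""
    strands = Counter(g.strand for g in block)
    genes = list(block)
    if strands["-"] > strands["+"]:
        genes = genes[::-1]
    return [g.label for g in genes]


def read_locus_table(stream: TextIO | str) -> list[GenomeLocus]:
    """Parse a tab-separated locus table.

    Columns: ``species, replicon, orf_index, strand, subunit_label``; header
    row required, ``#`` comments ignored.  Rows are grouped by species in
    order of first appearance.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("locus table is empty")
    header = [c.strip() for c in lines[0].split("\t")]
    expected = ["species", "replicon", "orf_index", "strand", "subunit_label"]
    if header != expected:
        raise ValueError(f"bad header {header!r}; expected {expected!r}")
    by_species: dict[str, list[Gene]] = {}
    for line in lines[1:]:
        sp, rep, idx, strand, label = [c.strip() for c in line.split("\t")]
        by_species.setdefault(sp, []).append(
            Gene(label=label, replicon=rep, orf_index=int(idx), strand=strand)
        )
    return [GenomeLocus(species=sp, genes=genes) for sp, genes in by_species.items()]


def write_locus_table(loci: Iterable[GenomeLocus], stream: TextIO) -> None:
    stream.write("species\treplicon\torf_index\tstrand\tsubunit_label\n")
    for locus in loci:
        for g in locus.genes:
            stream.write(
                f"{locus.species}\t{g.replicon}\t{g.orf_index}\t{g.strand}\t{g.label}\n"
            )


def segment_blocks(locus: GenomeLocus, max_intervening: int = 3) -> LocusBlocks:
    """Cut a locus into blocks wherever the ORF gap exceeds the threshold.

    A new block starts when the gap between consecutive ATP genes exceeds
    ``max_intervening`` intervening ORFs, or when the replicon changes.
    ``X`` (hypothetical) genes never anchor a block edge: they are kept only
    when flanked within a block, and count toward gaps otherwise.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    anchors = [g for g in locus.genes if g.label != "X"]
    x_genes = [g for g in locus.genes if g.label == "X"]
    blocks: list[list[Gene]] = []
    gaps: list[int | None] = []
    for g in anchors:
        if not blocks:
            blocks.append([g])
            continue
        prev = blocks[-1][-1]
        if g.replicon != prev.replicon:
            blocks.append([g])
            gaps.append(None)
            continue
        gap = g.orf_index - prev.orf_index - 1
        if gap > max_intervening:
            blocks.append([g])
            gaps.append(gap)
        else:
            blocks[-1].append(g)
    # Re-attach X genes that fall strictly inside a block's span.
    for x in x_genes:
        for block in blocks:
            if (
                x.replicon == block[0].replicon
                and block[0].orf_index < x.orf_index < block[-1].orf_index
            ):
                block.append(x)
                block.sort(key=lambda g: g.orf_index)
                break
    return LocusBlocks(blocks=blocks, gaps=gaps)


def split_junctions(
    blocks: LocusBlocks, reference_order: Sequence[str] = CANONICAL_ORDER
) -> set[str]:
    """Junctions of the reference order broken across blocks.

    For each pair of reference-adjacent labels found in different blocks the
    junction ``"upstream|downstream"`` is reported.  Within split loci the
    genes are interpreted against the order they take when the locus is
    intact, so within-block position does not matter — only co-membership.
    A core locus label absent from the reference order is an error.
    """
    reference = [normalize_label(l) for l in reference_order]
    if len(set(reference)) != len(reference):
        raise ValueError("reference_order must list each label once")
    membership: dict[str, set[int]] = {}
    for i, block in enumerate(blocks.blocks):
        for g in block:
            label = "0B" if g.label == "0B'" else g.label
            if label in ("X", "?"):
                continue
            if label not in reference:
                raise ValueError(
                    f"locus label {label!r} absent from the reference order"
                )
            membership.setdefault(label, set()).add(i)
    junctions: set[str] = set()
    for a, b in itertools.pairwise(reference):
        if a in membership and b in membership and not (membership[a] & membership[b]):
            junctions.add(f"{a}|{b}")
    return junctions


def name_b_prime(locus: GenomeLocus, max_intervening: int = 3) -> GenomeLocus:
    """Rename the upstream copy of an in-block 0B pair to 0B'.

    When exactly two 0B copies share a block, the upstream one (in
    transcription order, i.e. the copy between 0C and the downstream 0B)
    becomes 0B'.  Copies in different blocks are ectopic, not 0B'.  Three or
    more in-block copies are left unchanged with a warning flagging all but
    the most downstream for manual review.
    """
    blocks = segment_blocks(locus, max_intervening=max_intervening)
    rename: set[Gene] = set()
    for block in blocks.blocks:
        copies = [g for g in block if g.label == "0B"]
        if len(copies) < 2:
            continue
        strands = Counter(g.strand for g in block)
        reverse = strands["-"] > strands["+"]
        ordered = sorted(copies, key=lambda g: g.orf_index, reverse=reverse)
        if len(copies) == 2:
            rename.add(ordered[0])  # upstream copy
        else:
            flagged = [f"{g.replicon}:{g.orf_index}" for g in ordered[:-1]]
            warnings.warn(
                f"{locus.species}: {len(copies)} in-block 0B copies; "
                f"{flagged} flagged for manual review",
                stacklevel=2,
            )
    new_genes = [
        replace(g, label="0B'") if g in rename else g for g in locus.genes
    ]
    return GenomeLocus(species=locus.species, genes=new_genes)


def classify_placement(
    locus: GenomeLocus, blocks: LocusBlocks
) -> dict[Gene, str]:
    """Classify duplicate gene copies as ``in_locus`` or ``ectopic``.

    The *main* locus is the block carrying the most distinct core labels
    (a tie is an error prompting a ``max_intervening`` review).  A copy
    sharing its block with another copy of the same label is an in-locus
    duplicate; a copy sitting in a non-main block is ectopic.  The single
    canonical copy residing in the main block is not reported.
    """
    def distinct_core(block: list[Gene]) -> int:
        return len({g.label for g in block if g.label in CORE_LABELS})

    sizes = [distinct_core(b) for b in blocks.blocks]
    best = max(sizes)
    if sizes.count(best) > 1:
        raise ValueError(
            f"{locus.species}: tie for the main block ({best} core labels in "
            f"{sizes.count(best)} blocks); review max_intervening"
        )
    main = sizes.index(best)
    label_counts = Counter(
        g.label for g in blocks.all_genes() if g.label in CORE_LABELS
    )
    duplicated = {l for l, n in label_counts.items() if n >= 2}
    calls: dict[Gene, str] = {}
    for i, block in enumerate(blocks.blocks):
        in_block = Counter(g.label for g in block)
        for g in block:
            if g.label not in duplicated:
                continue
            if in_block[g.label] >= 2:
                calls[g] = "in_locus"
            elif i != main:
                calls[g] = "ectopic"
    return calls


def detect_n_atpase(
    block: Sequence[Gene] | Sequence[str], require_R: bool = True
) -> bool:
    """Does this gene run carry the N-ATPase signature?

    True iff the run contains atpR (unless ``require_R`` is off), lacks the
    delta subunit (ID), and its label sequence is consistent with the
    N-ATPase order IB-IE-I-R-0A-0C-0B-IA-IG — i.e. a subsequence of it, so
    absences from splits or partial loci are tolerated.  The switch exists
    because degenerate N-ATPase loci missing atpR are known.
    """
    if block and isinstance(block[0], Gene):
        labels = oriented_labels(block)  # type: ignore[arg-type]
    else:
        labels = [normalize_label(l) for l in block]  # type: ignore[arg-type]
    seq = []
    for l in labels:
        l = "0B" if l == "0B'" else l
        if l in ("X", "?"):
            continue
        if not seq or seq[-1] != l:
            seq.append(l)
    if "ID" in seq:
        return False
    if require_R and "R" not in seq:
        return False
    # subsequence test against the N order, tried in both reading directions
    def is_subseq(sub: list[str], ref: list[str]) -> bool:
        it = iter(ref)
        return all(s in it for s in sub)

    return is_subseq(seq, N_ATPASE_ORDER) or is_subseq(seq[::-1], N_ATPASE_ORDER)


def pattern_string(locus: GenomeLocus, blocks: LocusBlocks | None = None,
                   max_intervening: int = 3) -> str:
    """Render the per-genome pattern notation: labels hyphen-joined within
    blocks, blocks semicolon-joined, X and ? preserved."""
    if blocks is None:
        blocks = segment_blocks(locus, max_intervening=max_intervening)
    return ";".join(
        "-".join(blocks.oriented_labels(i)) for i in range(len(blocks.blocks))
    )


def parse_pattern(text: str) -> list[list[str]]:
    """Parse pattern notation into blocks of labels."""
    blocks = []
    for chunk in text.strip().split(";"):
        labels = [normalize_label(l) for l in chunk.split("-") if l]
        if not labels:
            raise ValueError(f"empty block in pattern {text!r}")
        blocks.append(labels)
    return blocks


def locus_from_pattern(
    species: str, text: str, replicon: str = "chr", block_gap: int = 999
) -> GenomeLocus:
    """Materialize a pattern string as a locus with synthetic ORF indices
    (consecutive within blocks, ``block_gap`` intervening ORFs between)."""
    genes: list[Gene] = []
    idx = 0
    for bi, labels in enumerate(parse_pattern(text)):
        if bi:
            idx += block_gap
        for label in labels:
            genes.append(Gene(label=label, replicon=replicon, orf_index=idx))
            idx += 1
    return GenomeLocus(species=species, genes=genes)


# --- ancestral gene order by adjacency parsimony -------------------------

def _adjacencies(locus: GenomeLocus, max_intervening: int) -> set[tuple[str, str]]:
    """Directed core-label adjacencies within blocks, transcription order.

    X and ? are skipped; 0B' folds into 0B (it is a duplicate, not a
    distinct locus position); self-adjacencies are dropped.
    """
    adj: set[tuple[str, str]] = set()
    blocks = segment_blocks(locus, max_intervening=max_intervening)
    for i in range(len(blocks.blocks)):
        labels = []
        for l in blocks.oriented_labels(i):
            l = "0B" if l == "0B'" else l
            if l in ("X", "?"):
                continue
            if not labels or labels[-1] != l:
                labels.append(l)
        adj.update((a, b) for a, b in itertools.pairwise(labels) if a != b)
    return adj


def _fitch_root_weight(
    tree: dendropy.Tree, leaf_present: dict[str, bool]
) -> float:
    """Fitch parsimony root score for one binary character.

    Returns 1.0 when the root set is {present}, 0.0 for {absent}, 0.5 when
    ambiguous.  Polytomies use the k-ary Fitch rule (intersection of child
    sets if non-empty, else union); leaves missing from the map count as
    absent.
    """
    sets: dict[dendropy.Node, frozenset[bool]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            sets[node] = frozenset({leaf_present.get(label, False)})
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            sets[node] = inter if inter else frozenset.union(*child_sets)
    root = sets[tree.seed_node]
    if root == frozenset({True}):
        return 1.0
    if root == frozenset({False}):
        return 0.0
    return 0.5


def _best_path(
    labels: list[str], weight: dict[tuple[str, str], float]
) -> tuple[list[str], float]:
    """Maximum-weight path over ``labels`` using only edges in ``weight``.

    Bitmask DP; returns the best path (longest, then heaviest) and its
    weight.  Deterministic: labels are iterated in sorted order.
    """
    n = len(labels)
    # best[(mask, last)] = (weight, path-tuple); masks visited in order, so
    # every predecessor state is final before it is extended.
    best: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {
        (1 << i, i): (0.0, (i,)) for i in range(n)
    }
    overall = (1, 0.0, (0,))  # (path length, weight, path)
    for mask in range(1, 1 << n):
        for last in range(n):
            state = best.get((mask, last))
            if state is None:
                continue
            w, path = state
            if (len(path), w) > overall[:2]:
                overall = (len(path), w, path)
            for b in range(n):
                if mask & (1 << b):
                    continue
                edge = (labels[last], labels[b])
                if edge not in weight:
                    continue
                key = (mask | (1 << b), b)
                cand = (w + weight[edge], path + (b,))
                if key not in best or cand[0] > best[key][0]:
                    best[key] = cand
    return [labels[i] for i in overall[2]], overall[1]


def ancestral_order(
    loci: Sequence[GenomeLocus],
    backbone: dendropy.Tree | None = None,
    max_intervening: int = 3,
) -> list[str]:
    """Infer the ancestral gene order of a locus from extant loci.

    Every directed within-block adjacency is a binary character; its
    ancestral presence is inferred by Fitch parsimony over ``backbone``
    (loci matched to leaves by species label; a star tree when no backbone
    is given).  Edge weight is 2×(inferred ancestral presence: 1, 0.5 if
    ambiguous, 0) plus the observed adjacency frequency; the ancestral
    order is the maximum-weight Hamiltonian path over all observed core
    labels.  A label absent from some genomes is not vetoed — parsimony and
    frequency decide its place.  If no path covers every label, the best
    partial chains are concatenated with a warning.
    """
    if not loci:
        raise ValueError("need at least one locus")
    per_locus = {l.species: _adjacencies(l, max_intervening) for l in loci}
    labels = sorted({lab for adj in per_locus.values() for pair in adj for lab in pair})
    if len(labels) > 16:
        raise ValueError(f"too many distinct labels for exact search: {labels}")
    all_edges = sorted(set().union(*per_locus.values()))

    if backbone is None:
        taxa = dendropy.TaxonNamespace(sorted(per_locus))
        tree = dendropy.Tree(taxon_namespace=taxa)
        for name in sorted(per_locus):
            child = dendropy.Node(taxon=taxa.get_taxon(name))
            tree.seed_node.add_child(child)
    else:
        tree = backbone

    n = len(per_locus)
    weight: dict[tuple[str, str], float] = {}
    for edge in all_edges:
        present = {sp: (edge in adj) for sp, adj in per_locus.items()}
        anc = _fitch_root_weight(tree, present)
        freq = sum(present.values()) / n
        weight[edge] = 2.0 * anc + freq

    path, _ = _best_path(labels, weight)
    if len(path) == len(labels):
        return path

    warnings.warn(
        "adjacency graph admits no single path through all labels; "
        "returning concatenated best partial chains",
        stacklevel=2,
    )
    chains: list[list[str]] = []
    remaining = list(labels)
    while remaining:
        sub_weight = {
            e: w for e, w in weight.items()
            if e[0] in remaining and e[1] in remaining
        }
        chain, _ = _best_path(remaining, sub_weight)
        chains.append(chain)
        remaining = [l for l in remaining if l not in chain]
    return [l for c in chains for l in c]
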