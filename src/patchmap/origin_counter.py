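"""Minimal origin counts, HGT-event counts, and a Sankoff parsimony engine.

Two counting paths are provided.  The *unit-count* path treats the deep
prokaryotic backbone as unresolved (a star over origin units): a mode with
k origin units needs k independent origins or, alternatively, k − 1
horizontal transfers (the first occurrence is vertical).  The *Sankoff*
path is a general small-parsimony dynamic program over a resolved rooted
tree with configurable gain/loss costs, for synthetic studies or future
resolved backbones; on a star tree with losses forbidden the two paths
agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from patchmap.grouping_model import GroupingAssumptions, OriginUnits, collapse_units
from patchmap.trait_tables import MODE_CODES, TraitMatrix

__all__ = [
    "CostScheme",
    "EventSummary",
    "SankoffResult",
    "min_origins",
    "hgt_events",
    "sankoff",
    "summarize",
]

ABSENT, PRESENT = 0, 1
_STATES = (ABSENT, PRESENT)


def min_origins(units: OriginUnits) -> int:
    """Minimal number of independent origins for a mode.

    One per origin unit; a mode flagged ancient contributes a single origin
    however widely it is spread; a mode with no incidence contributes none.
    """
    if not units.units:
        return 0
    if units.ancient:
        return 1
    return len(units.units)


def hgt_events(origins: int) -> int:
    """Transfers that alternatively explain ``origins`` independent gains.

    The first occurrence is vertical descent, so k origins trade against
    k − 1 transfers; never negative.
    """
    if origins < 0:
        raise ValueError("origins must be >= 0")
    return max(origins - 1, 0)


@dataclass
class EventSummary:
    """Per-mode and total origin/HGT counts."""

    per_mode: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def total_origins(self) -> int:
        return sum(o for o, _ in self.per_mode.values())

    @property
    def total_hgt(self) -> int:
        return sum(h for _, h in self.per_mode.values())

    def origins(self, mode: str) -> int:
        return self.per_mode[mode][0]

    def hgt(self, mode: str) -> int:
        return self.per_mode[mode][1]

    def to_frame(self) -> pd.DataFrame:
        """One row per mode plus a TOTAL row (origins, hgt_events)."""
        rows = [
            {"mode": m, "origins": o, "hgt_events": h}
            for m, (o, h) in self.per_mode.items()
        ]
        rows.append(
            {
                "mode": "TOTAL",
                "origins": self.total_origins,
                "hgt_events": self.total_hgt,
            }
        )
        return pd.DataFrame(rows)


def summarize(matrix: TraitMatrix, assumptions: GroupingAssumptions) -> EventSummary:
    """Collapse, count origins, and count transfers for all nine modes."""
    summary = EventSummary()
    for mode in MODE_CODES:
        units = collapse_units(matrix, assumptions, mode)
        o = min_origins(units)
        summary.per_mode[mode] = (o, hgt_events(o))
    return summary


@dataclass(frozen=True)
class CostScheme:
    """Edge-transition costs for binary-state parsimony.

    ``math.inf`` forbids a transition (e.g. ``loss_cost=inf`` for a Dollo
    -style "no reversals" model).  ``root_state_prior`` constrains the root
    to absent/present or leaves it free.
    """

    gain_cost: float = 1.0
    loss_cost: float = 1.0
    root_state_prior: str = "free"  # absent | present | free

    def __post_init__(self) -> None:
        if self.gain_cost < 0 or self.loss_cost < 0:
            raise ValueError("costs must be non-negative")
        if math.isinf(self.gain_cost) and math.isinf(self.loss_cost):
            raise ValueError("gain and loss costs cannot both be infinite")
        if self.root_state_prior not in ("absent", "present", "free"):
            raise ValueError(f"bad root prior {self.root_state_prior!r}")

    def edge_cost(self, parent: int, child: int) -> float:
        if parent == child:
            return 0.0
        return self.gain_cost if child == PRESENT else self.loss_cost


@dataclass
class SankoffResult:
    min_cost: float
    labeling: dict[dendropy.Node, int]
    gains: int
    losses: int


def sankoff(
    tree: dendropy.Tree,
    leaf_states: dict[str, int],
    costs: CostScheme,
) -> SankoffResult:
    """Binary-state Sankoff small parsimony on a rooted tree.

    ``leaf_states`` maps every leaf label to 0 (absent) or 1 (present).
    Returns the minimum total edge cost, one optimal full labeling, and the
    gain (0→1) / loss (1→0) edge counts of that labeling.  Ties are broken
    deterministically in favour of ``absent``, so repeated runs agree.
    Multifurcations are handled natively; infinite costs propagate through
    the min-plus recursion as ``math.inf``.
    """
    # Bottom-up: S[node][s] = min cost of the subtree given node has state s.
    score: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in leaf_states:
                raise ValueError(f"leaf {label!r} has no state assigned")
            s = leaf_states[label]
            if s not in _STATES:
                raise ValueError(f"leaf {label!r}: state must be 0 or 1")
            score[node] = [0.0 if s == t else math.inf for t in _STATES]
        else:
            totals = [0.0, 0.0]
            for child in node.child_nodes():
                for s in _STATES:
                    totals[s] += min(
                        costs.edge_cost(s, t) + score[child][t] for t in _STATES
                    )
            score[node] = totals

    root = tree.seed_node
    root_scores = list(score[root])
    if costs.root_state_prior == "absent":
        root_scores[PRESENT] = math.inf
    elif costs.root_state_prior == "present":
        root_scores[ABSENT] = math.inf
    min_cost = min(root_scores)
    if math.isinf(min_cost):
        raise ValueError("no labeling satisfies the cost scheme and root prior")

    # Top-down backtrace, preferring ABSENT at ties.
    labeling: dict[dendropy.Node, int] = {}
    labeling[root] = ABSENT if root_scores[ABSENT] <= root_scores[PRESENT] else PRESENT
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = labeling[node.parent_node]
        best_t, best_v = ABSENT, math.inf
        for t in _STATES:  # ABSENT first: ties keep absent
            v = costs.edge_cost(p, t) + score[node][t]
            if v < best_v:
                best_t, best_v = t, v
        labeling[node] = best_t

    gains = losses = 0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p, c = labeling[node.parent_node], labeling[node]
        if p == ABSENT and c == PRESENT:
            gains += 1
        elif p == PRESENT and c == ABSENT:
            losses += 1
    return SankoffResult(min_cost=min_cost, labeling=labeling, gains=gains, losses=losses)
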