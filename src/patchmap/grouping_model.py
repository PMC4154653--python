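"""Monophyly / ancient-origin assumptions and origin-unit collapsing.

Because the deep branching order of prokaryotic lineages is unresolved, the
origin count for a trait depends on which lineages one is willing to treat
as a single potential point of origin.  This module represents those
assumptions declaratively — merge rules (e.g. "all proteobacterial
subgroups share one origin") and "ancient" modes (one origin regardless of
spread) — and collapses a trait matrix into per-mode *origin units*.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import TextIO

import yaml

from patchmap.trait_tables import (
    MODE_CODES,
    TraitMatrix,
    ValidationError,
    normalize_lineage,
)

__all__ = [
    "MergeRule",
    "GroupingAssumptions",
    "OriginUnits",
    "load_assumptions",
    "default_assumptions",
    "collapse_units",
]


@dataclass(frozen=True)
class MergeRule:
    """Treat a set of lineages as one origin unit.

    ``modes`` is ``None`` for an all-mode rule, otherwise the subset of mode
    codes the rule applies to.
    """

    label: str
    lineages: frozenset[str]
    modes: frozenset[str] | None = None

    def applies_to(self, mode: str) -> bool:
        return self.modes is None or mode in self.modes


@dataclass
class GroupingAssumptions:
    """A validated bundle of merge rules and ancient modes."""

    merges: list[MergeRule] = field(default_factory=list)
    ancient_modes: frozenset[str] = frozenset()
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.ancient_modes:
            if m not in MODE_CODES:
                raise ValidationError(f"unknown mode code in ancient list: {m!r}")
        for rule in self.merges:
            if not rule.lineages:
                raise ValidationError(f"merge rule {rule.label!r} has no lineages")
            if rule.modes is not None:
                for m in rule.modes:
                    if m not in MODE_CODES:
                        raise ValidationError(
                            f"merge rule {rule.label!r}: unknown mode {m!r}"
                        )
        # A lineage may sit in two rules only if their mode scopes are disjoint.
        for i, a in enumerate(self.merges):
            for b in self.merges[i + 1:]:
                shared = a.lineages & b.lineages
                if not shared:
                    continue
                if a.modes is None or b.modes is None or (a.modes & b.modes):
                    raise ValidationError(
                        f"merge rules {a.label!r} and {b.label!r} overlap on "
                        f"{sorted(shared)} with overlapping mode scope"
                    )

    def validate_against(self, matrix: TraitMatrix) -> None:
        """Raise if any merged lineage is absent from the matrix."""
        known = set(matrix.lineages)
        for rule in self.merges:
            missing = rule.lineages - known
            if missing:
                raise ValidationError(
                    f"merge rule {rule.label!r} names lineages absent from the "
                    f"matrix: {sorted(missing)}"
                )


@dataclass(frozen=True)
class OriginUnits:
    """Per-mode incidence after collapsing: the set of origin-unit labels."""

    mode: str
    units: frozenset[str]
    ancient: bool = False


def load_assumptions(stream: TextIO | str) -> GroupingAssumptions:
    """Load assumptions from a YAML/JSON key-value document.

    Schema::

        ancient: [He, Me]
        merges:
          - label: proteobacteria
            lineages: [proteobacteria_alpha, ...]
            modes: all            # or a list of mode codes
            note: optional free text
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    doc = yaml.safe_load(stream)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError("grouping config must be a mapping")
    ancient = frozenset(doc.get("ancient") or [])
    merges: list[MergeRule] = []
    notes: dict[str, str] = {}
    for entry in doc.get("merges") or []:
        label = entry["label"]
        lineages = frozenset(normalize_lineage(l) for l in entry["lineages"])
        modes_raw = entry.get("modes", "all")
        modes = None if modes_raw in (None, "all") else frozenset(modes_raw)
        merges.append(MergeRule(label=label, lineages=lineages, modes=modes))
        if entry.get("note"):
            notes[label] = str(entry["note"])
    if doc.get("notes"):
        notes.update({str(k): str(v) for k, v in doc["notes"].items()})
    return GroupingAssumptions(merges=merges, ancient_modes=ancient, notes=notes)


def default_assumptions() -> GroupingAssumptions:
    """The packaged default grouping config.

    Encodes: respiration and methanogenesis ancient (single origin each);
    the proteobacterial subgroups merged for all modes; and a single shared
    origin for iron oxidation in the archaeoglobi, the thermoplasmata and
    the unclassified euryarchaeon.
    """
    ref = resources.files("patchmap.data") / "groupings_table1.yaml"
    return load_assumptions(ref.read_text())


def collapse_units(
    matrix: TraitMatrix,
    assumptions: GroupingAssumptions,
    mode: str,
) -> OriginUnits:
    """Collapse the non-zero lineages of a mode into origin units.

    Each merged set whose rule covers this mode is replaced by its single
    label; remaining lineages stand as their own units.  The ``ancient``
    flag is copied from the assumptions; an ancient mode with any incidence
    contributes exactly one origin downstream.
    """
    if mode not in MODE_CODES:
        raise ValidationError(f"unknown mode code {mode!r}")
    assumptions.validate_against(matrix)
    units: set[str] = set()
    for lineage in matrix.nonzero_lineages(mode):
        label = lineage
        for rule in assumptions.merges:
            if rule.applies_to(mode) and lineage in rule.lineages:
                label = rule.label
                break
        units.add(label)
    return OriginUnits(
        mode=mode,
        units=frozenset(units),
        ancient=mode in assumptions.ancient_modes,
    )
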