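"""Species/trait tables and the lineage-by-mode incidence matrix.

A *bioenergetic mode* is one of nine energy-conservation strategies, encoded
by a 2–3 letter code (``He`` heterotrophy/respiration … ``FO`` iron
oxidation).  Each species carries exactly one mode, a lineage key and a
domain group; the lineage-by-mode count matrix is the substrate for the
origin/HGT counting downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import pandas as pd

__all__ = [
    "MODE_CODES",
    "DOMAIN_GROUPS",
    "SpeciesRecord",
    "TraitMatrix",
    "Census",
    "ValidationError",
    "abbreviation_ok",
    "parse_species_table",
    "write_species_table",
    "make_abbreviation",
    "build_trait_matrix",
    "matrix_census",
]

#: The nine bioenergetic mode codes and their long names.
MODE_CODES: dict[str, str] = {
    "He": "heterotrophy/respiration",
    "OP": "oxygenic photosynthesis",
    "AP": "anoxygenic photosynthesis",
    "Me": "methanogenesis",
    "SR": "sulfate/arsenate reduction",
    "SfR": "sulfur reduction",
    "SO": "sulfur oxidation",
    "FR": "iron reduction",
    "FO": "iron oxidation",
}

DOMAIN_GROUPS = ("bacteria", "crenarchaea", "euryarchaea", "korarchaea")

_COLUMNS = ["species_name", "abbreviation", "lineage", "domain_group", "mode"]


def abbreviation_ok(abbrev: str, mode: str) -> bool:
    """Loose well-formedness check for an abbreviation token.

    Canonical tokens are ``Xx_yyy`` + mode code (8 characters with a
    2-letter code, 9 with ``SfR``), but short epithets and condensed
    variants yield 6–7; the token must start with a capital letter and end
    with the record's mode code.
    """
    return (
        6 <= len(abbrev) <= 9
        and abbrev[0].isupper()
        and abbrev.endswith(mode)
    )


class ValidationError(ValueError):
    """Raised when an input table or record violates the format contract."""


@dataclass
class SpeciesRecord:
    """One species: name, 8-character abbreviation, lineage, domain, mode."""

    full_name: str
    abbreviation: str
    lineage: str
    domain_group: str
    mode: str
    abbrev_ok: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODE_CODES:
            raise ValidationError(
                f"unknown mode code {self.mode!r} for species {self.full_name!r}"
            )
        if self.domain_group not in DOMAIN_GROUPS:
            raise ValidationError(
                f"unknown domain group {self.domain_group!r} for {self.full_name!r}"
            )
        self.lineage = normalize_lineage(self.lineage)


def normalize_lineage(key: str) -> str:
    """Lower-case and whitespace-normalize a lineage key."""
    return " ".join(key.strip().lower().split())


def make_abbreviation(
    full_name: str,
    mode: str,
    existing: Iterable[str] | None = None,
) -> str:
    """Build the 8-character species abbreviation.

    The token keeps the first two letters of the genus and the first three
    of the species epithet, joined by an underscore, followed by the mode
    code: ``("Fibrobacter succinogenes", "He") -> "Fi_sucHe"``.  The first
    letter is capitalized.

    Parameters
    ----------
    full_name:
        Binomial (or longer) species name; at least two words.
    mode:
        One of the nine mode codes.
    existing:
        Optional collection of already-assigned abbreviations; a collision
        raises ``ValidationError`` naming both parties.
    """
    if mode not in MODE_CODES:
        raise ValidationError(f"unknown mode code {mode!r}")
    words = full_name.split()
    if len(words) < 2:
        raise ValidationError(
            f"cannot abbreviate single-word species name {full_name!r}"
        )
    token = words[0][:2].capitalize() + "_" + words[1][:3] + mode
    if existing is not None and token in set(existing):
        raise ValidationError(
            f"abbreviation collision: {token!r} already assigned "
            f"(while abbreviating {full_name!r})"
        )
    return token


def parse_species_table(stream: TextIO | str) -> list[SpeciesRecord]:
    """Parse a tab-separated species table into records.

    Expected columns: ``species_name, abbreviation, lineage, domain_group,
    mode``; a header row is required and ``#`` comment lines are ignored.
    An empty abbreviation cell is filled from :func:`make_abbreviation`.
    A malformed abbreviation is kept but flagged (``abbrev_ok=False``) with
    a warning; an unknown mode or a duplicate species name is an error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError("species table is empty (no header row)")
    header = [c.strip() for c in lines[0].split("\t")]
    if header != _COLUMNS:
        raise ValidationError(
            f"bad header {header!r}; expected columns {_COLUMNS!r}"
        )
    records: list[SpeciesRecord] = []
    seen_names: set[str] = set()
    for i, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != len(_COLUMNS):
            raise ValidationError(f"row {i}: expected {len(_COLUMNS)} columns")
        name, abbrev, lineage, domain, mode = cells
        if mode not in MODE_CODES:
            raise ValidationError(f"row {i} ({name!r}): unknown mode code {mode!r}")
        if name in seen_names:
            raise ValidationError(f"row {i}: duplicate species name {name!r}")
        seen_names.add(name)
        if not abbrev:
            abbrev = make_abbreviation(name, mode)
        ok = abbreviation_ok(abbrev, mode)
        if not ok:
            warnings.warn(
                f"row {i} ({name!r}): abbreviation {abbrev!r} does not match "
                "the Xx_yyyMM scheme; record kept",
                stacklevel=2,
            )
        records.append(
            SpeciesRecord(
                full_name=name,
                abbreviation=abbrev,
                lineage=lineage,
                domain_group=domain,
                mode=mode,
                abbrev_ok=ok,
            )
        )
    return records


def write_species_table(records: Iterable[SpeciesRecord], stream: TextIO) -> None:
    """Serialize records back to the tab-separated format (round-trippable)."""
    stream.write("\t".join(_COLUMNS) + "\n")
    for r in records:
        stream.write(
            "\t".join(
                [r.full_name, r.abbreviation, r.lineage, r.domain_group, r.mode]
            )
            + "\n"
        )


@dataclass
class TraitMatrix:
    """Lineage-by-mode species count matrix.

    ``counts`` is a pandas DataFrame: one row per lineage (input order
    preserved), one column per mode code, integer cells.  ``row_domain``
    maps each lineage to its domain group.
    """

    counts: pd.DataFrame
    row_domain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(MODE_CODES):
            raise ValidationError("matrix columns must be the nine mode codes")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("matrix cells must be non-negative")

    @property
    def lineages(self) -> list[str]:
        return list(self.counts.index)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def nonzero_lineages(self, mode: str) -> list[str]:
        """Lineages with at least one species in the given mode."""
        col = self.counts[mode]
        return list(col.index[col > 0])


def build_trait_matrix(records: Iterable[SpeciesRecord]) -> TraitMatrix:
    """Tally records into a :class:`TraitMatrix` (lineage order of first
    appearance)."""
    records = list(records)
    lineages: list[str] = []
    row_domain: dict[str, str] = {}
    for r in records:
        if r.lineage not in row_domain:
            lineages.append(r.lineage)
            row_domain[r.lineage] = r.domain_group
        elif row_domain[r.lineage] != r.domain_group:
            raise ValidationError(
                f"lineage {r.lineage!r} assigned to two domain groups"
            )
    counts = pd.DataFrame(0, index=lineages, columns=list(MODE_CODES), dtype=int)
    for r in records:
        counts.loc[r.lineage, r.mode] += 1
    return TraitMatrix(counts=counts, row_domain=row_domain)


@dataclass
class Census:
    """Per-lineage summary plus domain-group and grand totals.

    ``per_lineage`` columns: ``domain_group``, ``species_total`` (row sum)
    and ``mode_count`` (number of distinct modes, i.e. non-zero cells).
    """

    per_lineage: pd.DataFrame
    domain_totals: dict[str, int]
    grand_total: int

    def mode_count(self, lineage: str) -> int:
        return int(self.per_lineage.loc[normalize_lineage(lineage), "mode_count"])


def matrix_census(matrix: TraitMatrix) -> Census:
    """Summarize a validated trait matrix.

    ``mode_count`` is the number of non-zero cells in each row; totals are
    sums over rows, overall and per domain group.
    """
    per = pd.DataFrame(
        {
            "domain_group": [matrix.row_domain.get(l, "") for l in matrix.lineages],
            "species_total": matrix.counts.sum(axis=1),
            "mode_count": (matrix.counts > 0).sum(axis=1),
        },
        index=matrix.counts.index,
    )
    domain_totals = (
        per.groupby("domain_group")["species_total"].sum().astype(int).to_dict()
    )
    return Census(
        per_lineage=per,
        domain_totals=domain_totals,
        grand_total=int(per["species_total"].sum()),
    )
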