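"""Bonferroni-corrected trait screening of signals against a PheWAS table.

Effects are oriented to the asthma risk allele: for disease traits an odds
ratio below 1 on another trait means the risk allele is protective for it.
The screen retains associations with p strictly below alpha / n_traits and
annotates each with a curated trait group (asthma, blood/immune cell,
allergy, other respiratory, inflammatory, auto-immune; unmatched traits are
reported as ungrouped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import Column, ValidationError, read_table, read_yaml

__all__ = [
    "PheWASRecord",
    "TraitGroup",
    "ScreenedAssociation",
    "bonferroni_threshold",
    "display_threshold",
    "truncate_significant",
    "screen_traits",
    "significance_matrix",
    "read_phewas_table",
    "read_trait_groups",
    "UNGROUPED",
]

UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class PheWASRecord:
    """One rsid x trait association, effect oriented to the risk allele."""

    rsid: str
    trait: str
    effect: float
    p_value: float
    odds_ratio: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(
                f"{self.rsid}/{self.trait}: p_value {self.p_value} outside (0, 1]"
            )
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValidationError(
                f"{self.rsid}/{self.trait}: odds ratio must be positive"
            )


@dataclass(frozen=True)
class TraitGroup:
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class ScreenedAssociation:
    """A retained association with its group and orientation annotations."""

    record: PheWASRecord
    group: str
    protective: bool | None
    neg_log10_p: float


def bonferroni_threshold(alpha: float, n_traits: int) -> float:
    """Per-trait significance level alpha / n_traits."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if n_traits < 1:
        raise ValidationError("n_traits must be >= 1")
    return alpha / n_traits


def truncate_significant(x: float, digits: int = 3) -> float:
    """Truncate (not round) ``x`` to ``digits`` significant digits.

    Truncation matches how the corrected threshold is conventionally
    printed: 0.05/778 = 6.4267e-5 is displayed as 6.42e-5.
    """
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exponent - digits + 1)
    return math.floor(x / scale) * scale


def display_threshold(alpha: float, n_traits: int, digits: int = 3) -> float:
    """Display form of the Bonferroni threshold (truncated significand).

    Comparisons should use :func:`bonferroni_threshold` at full precision;
    this companion exists only for reporting.
    """
    return truncate_significant(bonferroni_threshold(alpha, n_traits), digits)


def _trait_lookup(groups: Sequence[TraitGroup]) -> Mapping[str, str]:
    lookup: dict[str, str] = {}
    for group in groups:
        for trait in group.members:
            if trait in lookup:
                raise ValidationError(
                    f"trait {trait!r} appears in groups {lookup[trait]!r} and {group.name!r}"
                )
            lookup[trait] = group.name
    return lookup


def screen_traits(
    records: Iterable[PheWASRecord],
    threshold: float,
    groups: Sequence[TraitGroup] = (),
) -> list[ScreenedAssociation]:
    """Retain associations with p < ``threshold`` (strict) and annotate them.

    The protective flag is only ever set for records carrying an odds
    ratio and is True iff OR < 1 (an OR of exactly 1 is not protective).
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold {threshold} outside (0, 1)")
    lookup = _trait_lookup(groups)
    out = []
    for rec in records:
        if rec.p_value >= threshold:
            continue
        protective = None if rec.odds_ratio is None else rec.odds_ratio < 1.0
        out.append(
            ScreenedAssociation(
                record=rec,
                group=lookup.get(rec.trait, UNGROUPED),
                protective=protective,
                neg_log10_p=-math.log10(rec.p_value),
            )
        )
    return out


def significance_matrix(screened: Sequence[ScreenedAssociation]) -> pd.DataFrame:
    """rsid x trait matrix of -log10(p) for the retained associations.

    Cells with no retained association are NaN.  Row/column order follows
    first appearance.
    """
    rsids: list[str] = []
    traits: list[str] = []
    for s in screened:
        if s.record.rsid not in rsids:
            rsids.append(s.record.rsid)
        if s.record.trait not in traits:
            traits.append(s.record.trait)
    frame = pd.DataFrame(index=rsids, columns=traits, dtype=float)
    for s in screened:
        frame.loc[s.record.rsid, s.record.trait] = s.neg_log10_p
    frame.index.name = "rsid"
    return frame


def read_phewas_table(path: str | Path) -> list[PheWASRecord]:
    schema = [
        Column("rsid"),
        Column("trait"),
        Column("effect", "float"),
        Column("p_value", "float"),
        Column("odds_ratio", "float", optional=True),
    ]
    return [PheWASRecord(**row) for row in read_table(path, schema)]


def read_trait_groups(path: str | Path) -> list[TraitGroup]:
    """Load a trait-group YAML mapping of group name -> list of traits."""
    raw = read_yaml(path)
    if not isinstance(raw, dict):
        raise ValidationError("trait-group file must map group name -> trait list")
    groups = [
        TraitGroup(name=str(name), members=frozenset(map(str, traits or ())))
        for name, traits in raw.items()
    ]
    _trait_lookup(groups)  # enforce disjointness
    return groups
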