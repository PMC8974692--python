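"""Tissue/cell expression classification and colocalization summaries.

Expression: a gene is called enriched/enhanced in a tissue or cell type
when its expression there is at least four times that of every other
class (the Human-Protein-Atlas-style rule); single-cell pTPM matrices are
log10(x + 1) transformed for heatmap display.

Colocalization: per gene and tissue class (lung vs blood/immune cells) the
median posterior H4 over the available studies is compared to a strict 0.8
cutoff; genes with no records are reported as having no data rather than
as unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "ExpressionProfile",
    "ColocSummary",
    "enrichment_flag",
    "log_matrix",
    "coloc_summarize",
    "classify_coloc_pattern",
    "LUNG",
    "BLOOD_IMMUNE",
    "PATTERNS",
]

LUNG = "lung"
BLOOD_IMMUNE = "blood_immune"
PATTERNS = ("lung_only", "blood_only", "both", "neither", "no_data")


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-class expression of one gene (NX for tissues, pTPM for cells)."""

    gene: str
    per_class: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {c: v for c, v in self.per_class.items() if v < 0}
        if bad:
            raise ValidationError(f"{self.gene}: negative expression {bad}")


def enrichment_flag(profile: ExpressionProfile, fold: float = 4.0) -> set[str]:
    """Classes where the gene's expression is >= ``fold`` x every other class.

    The comparison is inclusive ("at least four times").  For ``fold`` > 1
    at most one class can qualify.  A single-class profile admits no
    comparison and raises.
    """
    if fold <= 0:
        raise ValidationError("fold must be positive")
    classes = list(profile.per_class)
    if len(classes) < 2:
        raise ValidationError(f"{profile.gene}: need >= 2 classes to compare")
    enriched = set()
    for cls in classes:
        others = max(v for c, v in profile.per_class.items() if c != cls)
        if profile.per_class[cls] >= fold * others and profile.per_class[cls] > 0:
            enriched.add(cls)
    return enriched


def log_matrix(values, pseudocount: float = 1.0):
    """Elementwise log10(x + pseudocount); preserves input container type.

    The unit pseudocount maps zero expression to zero, the standard choice
    for TPM-scale heatmaps.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("expression values must be non-negative")
    out = np.log10(arr + pseudocount)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


@dataclass(frozen=True)
class ColocSummary:
    """Median colocalization posterior of one gene in one tissue class."""

    gene: str
    tissue_class: str
    h4_values: tuple[float, ...]
    median_h4: float
    linked: bool


def coloc_summarize(
    records: Iterable[tuple[str, str, float]],
    h4_cutoff: float = 0.8,
) -> list[ColocSummary]:
    """Summarize (gene, tissue_class, h4) records per gene and tissue class.

    ``linked`` uses a strict comparison (median H4 > cutoff; a median of
    exactly 0.8 is not linked).  Output order follows first appearance.
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for gene, tissue_class, h4 in records:
        if not 0.0 <= h4 <= 1.0:
            raise ValidationError(f"{gene}/{tissue_class}: h4 {h4} outside [0, 1]")
        key = (gene, tissue_class)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(h4)
    out = []
    for gene, tissue_class in order:
        values = grouped[(gene, tissue_class)]
        med = float(median(values))
        out.append(
            ColocSummary(
                gene=gene,
                tissue_class=tissue_class,
                h4_values=tuple(values),
                median_h4=med,
                linked=med > h4_cutoff,
            )
        )
    return out


def classify_coloc_pattern(summaries: Sequence[ColocSummary]) -> str:
    """Classify one gene's lung/blood linkage pattern.

    ``no_data`` when no summaries exist; otherwise the combination of the
    lung and blood/immune linked flags (a missing tissue class counts as
    not linked).
    """
    if not summaries:
        return "no_data"
    genes = {s.gene for s in summaries}
    if len(genes) > 1:
        raise ValidationError(f"summaries mix genes: {sorted(genes)}")
    classes = {s.tissue_class for s in summaries}
    extra = classes - {LUNG, BLOOD_IMMUNE}
    if extra:
        raise ValidationError(f"unknown tissue class(es) {sorted(extra)}")
    lung = any(s.linked for s in summaries if s.tissue_class == LUNG)
    blood = any(s.linked for s in summaries if s.tissue_class == BLOOD_IMMUNE)
    if lung and blood:
        return "both"
    if lung:
        return "lung_only"
    if blood:
        return "blood_only"
    return "neither"
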