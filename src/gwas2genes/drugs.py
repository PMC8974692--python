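"""Drug-gene interaction triage.

Interaction records from a scored interaction database are retained when
their interaction score exceeds 1.0 (strictly); records known only from
clinical-trial registries carry no score and travel through a separate
channel so they are never counted as scored interactions.  The per-gene
summary covers the full queried universe, including genes with nothing
known against them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ValidationError

__all__ = [
    "DrugInteraction",
    "FilteredInteractions",
    "GeneDruggability",
    "filter_interactions",
    "summarize_druggability",
    "SOURCE_SCORED",
    "SOURCE_TRIAL",
]

SOURCE_SCORED = "scored_db"
SOURCE_TRIAL = "clinical_trial"

_NCT = re.compile(r"^NCT\d+$")


@dataclass(frozen=True)
class DrugInteraction:
    """One drug-gene interaction or clinical-trial record.

    ``source`` is derived from the presence of an interaction score:
    scored-database records carry one, trial-only records do not.
    """

    gene: str
    drug: str
    interaction_score: float | None = None
    interaction_type: str | None = None
    trial_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene or not self.drug:
            raise ValidationError("gene and drug must be non-empty")
        if self.interaction_score is not None and self.interaction_score <= 0:
            raise ValidationError(
                f"{self.gene}/{self.drug}: interaction score must be positive"
            )
        bad = [t for t in self.trial_ids if not _NCT.match(t)]
        if bad:
            raise ValidationError(
                f"{self.gene}/{self.drug}: malformed trial id(s) {bad}"
            )

    @property
    def source(self) -> str:
        return SOURCE_SCORED if self.interaction_score is not None else SOURCE_TRIAL


@dataclass
class FilteredInteractions:
    """Scored records passing the cutoff, plus the untouched trial channel."""

    scored: list[DrugInteraction]
    trials: list[DrugInteraction]


def filter_interactions(
    records: Iterable[DrugInteraction], min_score: float = 1.0
) -> FilteredInteractions:
    """Retain scored records with interaction score strictly above ``min_score``.

    Trial-only records pass through to the trial channel untouched; a score
    of exactly ``min_score`` is excluded.
    """
    if min_score < 0:
        raise ValidationError("min_score must be >= 0")
    scored, trials = [], []
    for rec in records:
        if rec.source == SOURCE_TRIAL:
            trials.append(rec)
        elif rec.interaction_score > min_score:
            scored.append(rec)
    return FilteredInteractions(scored=scored, trials=trials)


@dataclass(frozen=True)
class GeneDruggability:
    gene: str
    n_scored: int
    max_score: float | None
    has_trial: bool
    trial_ids: tuple[str, ...] = ()


def summarize_druggability(
    records: Iterable[DrugInteraction],
    genes: Sequence[str] | None = None,
    min_score: float = 1.0,
) -> list[GeneDruggability]:
    """Per-gene summary over the queried universe.

    ``genes`` fixes the universe (genes with no records get zero rows);
    when omitted it is the distinct genes of ``records`` in order of
    appearance.  Counts come only from the scored channel after the
    ``min_score`` filter; trial presence is reported separately.
    """
    records = list(records)
    if genes is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.gene)
        genes = list(seen)
    filtered = filter_interactions(records, min_score=min_score)
    out = []
    for gene in genes:
        scored = [r for r in filtered.scored if r.gene == gene]
        trial_ids: list[str] = []
        for r in records:
            if r.gene == gene:
                trial_ids.extend(r.trial_ids)
        has_trial = any(
            r.gene == gene and (r.source == SOURCE_TRIAL or r.trial_ids)
            for r in records
        )
        out.append(
            GeneDruggability(
                gene=gene,
                n_scored=len(scored),
                max_score=max((r.interaction_score for r in scored), default=None),
                has_trial=has_trial,
                trial_ids=tuple(dict.fromkeys(trial_ids)),
            )
        )
    return out
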