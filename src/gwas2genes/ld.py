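"""LD proxy selection.

When a sentinel SNP is absent from a target database, the stand-in is the
linked variant with the highest squared allelic correlation r² to the
sentinel, subject to a floor (r² >= 0.2 by default).  Ties at equal r² are
broken by the lexicographically smallest rsid so the choice is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import Column, ValidationError, read_table

__all__ = ["LDPair", "ProxyChoice", "NoProxyError", "select_proxy", "read_ld_table", "read_rsid_set"]


@dataclass(frozen=True)
class LDPair:
    """Squared allelic correlation between two variants."""

    rsid_a: str
    rsid_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValidationError(f"r2 {self.r2} outside [0, 1]")
        if self.rsid_a == self.rsid_b and self.r2 != 1.0:
            raise ValidationError(f"r2({self.rsid_a}, itself) must be 1, got {self.r2}")


@dataclass(frozen=True)
class ProxyChoice:
    sentinel: str
    chosen: str
    r2: float
    is_self: bool

    def __post_init__(self) -> None:
        if self.is_self != (self.chosen == self.sentinel):
            raise ValidationError("is_self flag inconsistent with chosen rsid")
        if self.is_self and self.r2 != 1.0:
            raise ValidationError("self-proxy must have r2 = 1")


class NoProxyError(LookupError):
    """No linked variant meets the r² floor in the interrogated dataset.

    Carries the best sub-threshold r² found (``best_r2``, None when no
    neighbor was available at all) so callers can report how close the
    signal came to being interrogable.
    """

    def __init__(self, sentinel: str, best_r2: float | None):
        self.sentinel = sentinel
        self.best_r2 = best_r2
        detail = "no neighbor available" if best_r2 is None else f"best r2 = {best_r2}"
        super().__init__(f"{sentinel}: no proxy at or above the r2 floor ({detail})")


def select_proxy(
    sentinel: str,
    neighbors: Iterable[LDPair],
    available: Iterable[str],
    r2_min: float = 0.2,
) -> ProxyChoice:
    """Pick the proxy for ``sentinel`` among ``available`` variants.

    If the sentinel itself is available it is its own proxy (r² = 1).
    Otherwise the available neighbor with the highest r² >= ``r2_min`` is
    chosen, smallest rsid first on ties.  Raises :class:`NoProxyError` when
    nothing qualifies.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValidationError(f"r2_min {r2_min} outside (0, 1]")
    available = set(available)
    if sentinel in available:
        return ProxyChoice(sentinel, sentinel, 1.0, True)

    best: tuple[float, str] | None = None  # (-r2 handled via comparisons)
    best_sub: float | None = None
    for pair in neighbors:
        if sentinel not in (pair.rsid_a, pair.rsid_b):
            raise ValidationError(
                f"LD pair ({pair.rsid_a}, {pair.rsid_b}) does not reference sentinel {sentinel}"
            )
        other = pair.rsid_b if pair.rsid_a == sentinel else pair.rsid_a
        if other == sentinel or other not in available:
            continue
        if pair.r2 >= r2_min:
            cand = (pair.r2, other)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        elif best_sub is None or pair.r2 > best_sub:
            best_sub = pair.r2
    if best is None:
        raise NoProxyError(sentinel, best_sub)
    r2, chosen = best
    return ProxyChoice(sentinel, chosen, r2, False)


def read_ld_table(path: str | Path) -> list[LDPair]:
    """Read a long-format LD TSV (rsid_a, rsid_b, r2).

    Symmetric duplicates (a,b)/(b,a) are collapsed, keeping the first
    occurrence; conflicting r² for the same unordered pair is an error.
    """
    schema = [Column("rsid_a"), Column("rsid_b"), Column("r2", "fraction")]
    seen: dict[frozenset[str], float] = {}
    pairs: list[LDPair] = []
    for row in read_table(path, schema):
        key = frozenset((row["rsid_a"], row["rsid_b"]))
        if key in seen:
            if seen[key] != row["r2"]:
                raise ValidationError(
                    f"conflicting r2 for pair {sorted(key)}: {seen[key]} vs {row['r2']}"
                )
            continue
        seen[key] = row["r2"]
        pairs.append(LDPair(row["rsid_a"], row["rsid_b"], row["r2"]))
    return pairs


def read_rsid_set(path: str | Path) -> set[str]:
    """Read a newline-delimited rsid availability file."""
    with Path(path).open(encoding="utf-8") as handle:
        return {line.strip() for line in handle if line.strip()}
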