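"""Domain types, validated TSV/GMT/JSON readers and the packaged reference tables.

The packaged tables transcribe the published moderate-to-severe asthma GWAS
translational analysis: the 25 association signals with risk alleles, the
LD-proxy table used when a sentinel is absent from a database, the per
signal:gene evidence-score table, the disease-term enrichment table and the
drug-interaction table.  They are the worked inputs for the scoring, triage
and reporting stages and the regression anchors for the test suite.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, fields
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

logger = logging.getLogger("gwas2genes")

__all__ = [
    "SchemaError",
    "ParseError",
    "ValidationError",
    "DataError",
    "EvidenceCategory",
    "UB_CATEGORIES",
    "PRESENCE_ONLY_CATEGORIES",
    "Signal",
    "EvidenceRecord",
    "GeneSetCollection",
    "EvidenceScoreRow",
    "ProxyTableRow",
    "EnrichmentTableRow",
    "Column",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
    "read_yaml",
    "load_fixture",
    "split_gene_label",
    "FIXTURE_NAMES",
]


class ValidationError(ValueError):
    """Input fails a declared invariant or schema contract."""


class DataError(RuntimeError):
    """Input is syntactically valid but semantically unusable."""


class SchemaError(ValidationError):
    """Header does not provide a mandatory column."""


class ParseError(ValidationError):
    """A cell cannot be coerced to its declared type."""


class EvidenceCategory(str, Enum):
    """The fourteen signal-to-gene evidence categories.

    Ten single-weight database categories, three double-weight U-BIOPRED
    eQTL compartments (bronchial brush, bronchial biopsy, nasal brush) and a
    literature-association category.
    """

    GTEX_RESP_EQTL = "gtex_resp_eqtl"
    GTEX_BLOOD_EQTL = "gtex_blood_eqtl"
    GTEX_RESP_SQTL = "gtex_resp_sqtl"
    GTEX_BLOOD_SQTL = "gtex_blood_sqtl"
    OTG_EQTL_RESP = "otg_eqtl_resp"
    OTG_EQTL_BLOOD = "otg_eqtl_blood"
    OTG_V2G = "otg_v2g"
    OTG_COLOC = "otg_coloc"
    HAPLOREG_EQTL = "haploreg_eqtl"
    FUNCTIONAL_VARIANT_LD = "functional_variant_ld"
    UB_BRUSH_EQTL = "ub_brush_eqtl"
    UB_BIOPSY_EQTL = "ub_biopsy_eqtl"
    UB_NASAL_EQTL = "ub_nasal_eqtl"
    LITERATURE = "literature"


#: U-BIOPRED eQTL compartments (double weight in the default scheme).
UB_CATEGORIES = frozenset(
    {
        EvidenceCategory.UB_BRUSH_EQTL,
        EvidenceCategory.UB_BIOPSY_EQTL,
        EvidenceCategory.UB_NASAL_EQTL,
    }
)

#: Categories scored by presence alone (no per-record p-value).
PRESENCE_ONLY_CATEGORIES = frozenset(
    {
        EvidenceCategory.OTG_V2G,
        EvidenceCategory.FUNCTIONAL_VARIANT_LD,
        EvidenceCategory.LITERATURE,
    }
)


@dataclass(frozen=True)
class Signal:
    """One GWAS association signal (sentinel SNP) with its risk allele."""

    rsid: str
    closest_gene: str
    risk_allele: str
    non_risk_allele: str
    raf_eur: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("signal rsid must be non-empty")
        if self.risk_allele == self.non_risk_allele:
            raise ValidationError(
                f"{self.rsid}: risk and non-risk alleles are identical"
            )
        if not 0.0 <= self.raf_eur <= 1.0:
            raise ValidationError(
                f"{self.rsid}: risk-allele frequency {self.raf_eur} outside [0, 1]"
            )


@dataclass(frozen=True)
class EvidenceRecord:
    """One source-specific piece of signal-to-gene support.

    ``p_value`` is absent for presence-only categories (variant-to-gene
    scores, tagged functional variants, literature); ``h4`` is the
    colocalization posterior and only meaningful for the coloc category;
    ``effect_b`` is the expression change per risk allele (B-value).
    """

    signal_rsid: str
    gene: str
    category: EvidenceCategory
    tissue: str = ""
    p_value: float | None = None
    effect_b: float | None = None
    h4: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.category, EvidenceCategory):
            try:
                object.__setattr__(
                    self, "category", EvidenceCategory(self.category)
                )
            except ValueError:
                raise ValidationError(
                    f"unknown evidence category {self.category!r}"
                ) from None
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValidationError(
                f"{self.signal_rsid}:{self.gene}: p_value {self.p_value} outside (0, 1]"
            )
        if self.h4 is not None and not 0.0 <= self.h4 <= 1.0:
            raise ValidationError(
                f"{self.signal_rsid}:{self.gene}: h4 {self.h4} outside [0, 1]"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (terms) over a background universe of gene symbols."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if not self.background:
            self.background = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        self.background = frozenset(self.background)
        for term, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"term {term!r} is empty")
            extra = genes - self.background
            if extra:
                raise ValidationError(
                    f"term {term!r} has genes outside the background: {sorted(extra)}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.terms == other.terms and self.background == other.background


@dataclass(frozen=True)
class EvidenceScoreRow:
    """One row of the packaged evidence-score table (verbatim transcription).

    ``ub_column`` is the printed U-BIOPRED column; for most rows it counts
    eQTL compartments (each worth two points) but a subset of rows is printed
    with point totals instead, so ``published_total`` is stored verbatim and
    :attr:`weight2_consistent` marks rows where ``base + 2*ub == total``.
    """

    signal_rsid: str
    gene: str
    base_score: int
    ub_column: int
    published_total: int

    @property
    def weight2_consistent(self) -> bool:
        return self.base_score + 2 * self.ub_column == self.published_total


@dataclass(frozen=True)
class ProxyTableRow:
    """LD-block summary and per-dataset proxy choices for one sentinel."""

    rsid: str
    ld_block_bp: int
    n_snps_ld: int
    proxy_other: str | None = None
    r2_other: float | None = None
    proxy_biopsy: str | None = None
    r2_biopsy: float | None = None
    proxy_brush: str | None = None
    r2_brush: float | None = None
    proxy_nasal: str | None = None
    r2_nasal: float | None = None


@dataclass(frozen=True)
class EnrichmentTableRow:
    """One disease-term row of the packaged enrichment table."""

    term: str
    genes: tuple[str, ...]
    count: int
    percent: float
    fold_enrichment: float
    p_value: float
    fdr: float


# ---------------------------------------------------------------------------
# Validated tabular IO
# ---------------------------------------------------------------------------

def _parse_float(cell: str) -> float:
    return float(cell)


def _parse_fraction(cell: str) -> float:
    value = float(cell)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class Column:
    """Declared column of a TSV schema.

    ``kind`` is one of ``str``, ``int``, ``float``, ``fraction``.  Optional
    columns coerce the empty string to ``None`` (a missing measurement is
    distinct from zero).
    """

    name: str
    kind: str = "str"
    optional: bool = False

    def parse(self, cell: str) -> Any:
        parsers: dict[str, Callable[[str], Any]] = {
            "str": str,
            "int": int,
            "float": _parse_float,
            "fraction": _parse_fraction,
        }
        if cell == "":
            if self.optional:
                return None
            if self.kind == "str":
                return ""
            raise ValueError("mandatory cell is empty")
        return parsers[self.kind](cell)


def read_table(path: str | Path, schema: Sequence[Column]) -> list[dict[str, Any]]:
    """Read a header-carrying TSV against a declared column schema.

    Header order is irrelevant; unknown columns are ignored with a logged
    warning.  A missing mandatory column raises :class:`SchemaError`; an
    uncoercible cell raises :class:`ParseError` naming the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: file has no header row")
        known = {col.name for col in schema}
        missing = known - set(header)
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory column(s) {sorted(missing)}"
            )
        unknown = [name for name in header if name not in known]
        if unknown:
            logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
        rows: list[dict[str, Any]] = []
        for lineno, raw in enumerate(reader, start=2):
            row: dict[str, Any] = {}
            for col in schema:
                cell = raw.get(col.name)
                if cell is None:
                    cell = ""
                try:
                    row[col.name] = col.parse(cell.strip())
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: column {col.name!r}: "
                        f"cannot parse {cell!r} ({exc})"
                    ) from None
            rows.append(row)
    return rows


def write_table(
    rows: Iterable[Mapping[str, Any]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write mappings as a TSV; ``None`` becomes the empty cell."""
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValidationError("cannot infer columns from an empty table")
        columns = list(rows[0].keys())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(
                ["" if row.get(c) is None else row.get(c) for c in columns]
            )


def dataclass_rows(records: Iterable[Any]) -> list[dict[str, Any]]:
    """Flatten dataclass instances to plain dict rows for :func:`write_table`."""
    out = []
    for rec in records:
        row = {}
        for f in fields(rec):
            value = getattr(rec, f.name)
            if isinstance(value, Enum):
                value = value.value
            elif isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            row[f.name] = value
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated member genes).

    Duplicate genes within a term are deduplicated; term order is preserved
    (insertion-ordered dict).  A line with fewer than three fields raises
    :class:`ParseError` with its line number.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(parts)} field(s), need >= 3"
                )
            term = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} lists no genes")
            terms[term] = genes
    bg = frozenset(background) if background is not None else frozenset()
    return GeneSetCollection(terms=terms, background=bg)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (description column left empty)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for term, genes in collection.terms.items():
            handle.write("\t".join([term, ""] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# JSON / YAML
# ---------------------------------------------------------------------------

def read_json(path: str | Path) -> Any:
    with Path(path).open(encoding="utf-8") as handle:
        return json.load(handle)


def write_json(obj: Any, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_yaml(path: str | Path) -> Any:
    import yaml

    with Path(path).open(encoding="utf-8") as handle:
        return yaml.safe_load(handle)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "signals",
    "proxies",
    "evidence_scores",
    "drug_table",
    "enrichment_table",
)

def split_gene_label(label: str) -> list[str]:
    """Split slash-cluster labels like ``HLA-DQA1/A2`` into atomic symbols.

    Abbreviated parts after a slash replace the same-length suffix of the
    first full symbol (``HLA-DQA1/A2/B1`` -> HLA-DQA1, HLA-DQA2, HLA-DQB1);
    a part as long as the full symbol stands alone.  Plain labels pass
    through.  Downstream set operations need atomic symbols.
    """
    parts = label.split("/")
    if len(parts) == 1:
        return [label]
    first = parts[0]
    out = [first]
    for part in parts[1:]:
        if len(part) >= len(first):
            out.append(part)
        else:
            out.append(first[: len(first) - len(part)] + part)
    return out


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("gwas2genes.data").joinpath(filename)))


def _load_signals() -> list[Signal]:
    schema = [
        Column("rsid"),
        Column("closest_gene"),
        Column("risk_allele"),
        Column("non_risk_allele"),
        Column("raf_eur", "fraction"),
    ]
    return [Signal(**row) for row in read_table(_fixture_path("signals.tsv"), schema)]


def _load_proxies() -> list[ProxyTableRow]:
    schema = [Column("rsid"), Column("ld_block_bp", "int"), Column("n_snps_ld", "int")]
    for ds in ("other", "biopsy", "brush", "nasal"):
        schema += [
            Column(f"proxy_{ds}", "str", optional=True),
            Column(f"r2_{ds}", "fraction", optional=True),
        ]
    rows = read_table(_fixture_path("proxies.tsv"), schema)
    return [
        ProxyTableRow(**{k: (v if v != "" else None) for k, v in row.items()})
        for row in rows
    ]


def _load_evidence_scores() -> list[EvidenceScoreRow]:
    schema = [
        Column("signal_rsid"),
        Column("gene"),
        Column("base_score", "int"),
        Column("ub_column", "int"),
        Column("published_total", "int"),
    ]
    return [
        EvidenceScoreRow(**row)
        for row in read_table(_fixture_path("evidence_scores.tsv"), schema)
    ]


def _load_drug_table() -> list["Any"]:
    # DrugInteraction lives with the triage logic; import lazily to avoid a cycle.
    from .drugs import DrugInteraction

    schema = [
        Column("gene"),
        Column("drug"),
        Column("interaction_type"),
        Column("pmids"),
        Column("interaction_score", "float", optional=True),
        Column("trial_ids"),
    ]
    records = []
    for row in read_table(_fixture_path("drug_table.tsv"), schema):
        if not row["drug"]:
            # placeholder row: queried gene with no known interaction
            continue
        trial_ids = tuple(t for t in row["trial_ids"].split(",") if t)
        records.append(
            DrugInteraction(
                gene=row["gene"],
                drug=row["drug"],
                interaction_score=row["interaction_score"],
                interaction_type=row["interaction_type"] or None,
                trial_ids=trial_ids,
            )
        )
    return records


def drug_query_universe() -> list[str]:
    """The queried gene universe of the packaged drug table (42 genes:
    37 candidate causal genes plus 5 interaction-predicted genes), in table
    order including genes with no known interaction."""
    seen: dict[str, None] = {}
    with _fixture_path("drug_table.tsv").open(encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            seen.setdefault(row["gene"])
    return list(seen)


def _load_enrichment_table() -> list[EnrichmentTableRow]:
    schema = [
        Column("term"),
        Column("genes"),
        Column("count", "int"),
        Column("percent", "float"),
        Column("fold_enrichment", "float"),
        Column("p_value", "float"),
        Column("fdr", "float"),
    ]
    rows = read_table(_fixture_path("enrichment_table.tsv"), schema)
    return [
        EnrichmentTableRow(
            term=row["term"],
            genes=tuple(row["genes"].split(",")),
            count=row["count"],
            percent=row["percent"],
            fold_enrichment=row["fold_enrichment"],
            p_value=row["p_value"],
            fdr=row["fdr"],
        )
        for row in rows
    ]


_LOADERS: dict[str, Callable[[], list[Any]]] = {
    "signals": _load_signals,
    "proxies": _load_proxies,
    "evidence_scores": _load_evidence_scores,
    "drug_table": _load_drug_table,
    "enrichment_table": _load_enrichment_table,
}


def load_fixture(name: str) -> list[Any]:
    """Return one packaged reference table as a list of typed records."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        ) from None
    return loader()
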