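"""End-to-end orchestration: configured stage execution and a run report.

A run executes, in order, any enabled subset of: proxy selection, evidence
scoring + candidate selection, PheWAS screening, differential expression,
term enrichment, expression/colocalization profiling and drug triage.
Stages read TSV/GMT/YAML inputs (real, packaged or synthetic), write their
outputs under the configured directory and contribute row counts to a
machine-readable report.  Re-running with an identical configuration and
inputs is byte-identical in every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .io import (
    Column,
    DataError,
    EvidenceRecord,
    ValidationError,
    dataclass_rows,
    load_fixture,
    read_gmt,
    read_table,
    read_yaml,
    write_json,
    write_table,
)
from . import de as de_mod
from . import drugs as drugs_mod
from . import enrich as enrich_mod
from . import ld as ld_mod
from . import phewas as phewas_mod
from . import profiles as profiles_mod
from . import scoring
from . import simulate

logger = logging.getLogger("gwas2genes")

__all__ = ["RunReport", "run_pipeline", "fixture_config", "synthetic_config", "STAGES"]

STAGES = ("proxy", "score", "phewas", "de", "enrich", "profile", "drugs")


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    version: str
    config_hash: str
    seed: int | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    candidates: dict[str, Any] | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunReport":
        return cls(**raw)

    def write(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def read(cls, path: str | Path) -> "RunReport":
        with Path(path).open(encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def _config_hash(config: Mapping[str, Any]) -> str:
    # outdir is where results land, not what they are: exclude it so the
    # same analysis in two directories hashes (and re-runs) identically
    hashable = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()
    ).hexdigest()


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    """Read raw evidence records (signal_rsid, gene, category, ...)."""
    schema = [
        Column("signal_rsid"),
        Column("gene"),
        Column("category"),
        Column("tissue"),
        Column("p_value", "float", optional=True),
        Column("effect_b", "float", optional=True),
        Column("h4", "fraction", optional=True),
    ]
    return [EvidenceRecord(**row) for row in read_table(path, schema)]


def fixture_config(outdir: str | Path) -> dict[str, Any]:
    """Configuration replaying the packaged published tables."""
    return {
        "outdir": str(outdir),
        "stages": {"score": True, "drugs": True},
        "inputs": {"evidence": "published", "drugs": "fixture"},
        "params": {"overrides": {"rs61816761": "FLG"}},
    }


def synthetic_config(outdir: str | Path, seed: int = 0) -> dict[str, Any]:
    """Configuration exercising score and de stages on generated data."""
    return {
        "outdir": str(outdir),
        "seed": seed,
        "stages": {"score": True, "de": True},
        "inputs": {"evidence": "synthetic", "expression": "synthetic"},
        "params": {},
    }


def _stage_proxy(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    pairs = ld_mod.read_ld_table(inputs["ld_table"])
    available = ld_mod.read_rsid_set(inputs["available"])
    sentinels = sorted({p.rsid_a for p in pairs})
    if "sentinels" in inputs:
        sentinels = sorted(ld_mod.read_rsid_set(inputs["sentinels"]))
    r2_min = params.get("r2_min", 0.2)
    rows = []
    for sentinel in sentinels:
        neighbors = [p for p in pairs if sentinel in (p.rsid_a, p.rsid_b)]
        try:
            choice = ld_mod.select_proxy(sentinel, neighbors, available, r2_min=r2_min)
            rows.append(
                {
                    "sentinel": choice.sentinel,
                    "chosen": choice.chosen,
                    "r2": choice.r2,
                    "is_self": choice.is_self,
                    "status": "ok",
                }
            )
        except ld_mod.NoProxyError as exc:
            rows.append(
                {
                    "sentinel": sentinel,
                    "chosen": None,
                    "r2": exc.best_r2,
                    "is_self": False,
                    "status": "no_proxy",
                }
            )
    write_table(rows, outdir / "proxies.tsv", ["sentinel", "chosen", "r2", "is_self", "status"])
    report.stages["proxy"] = {
        "rows_in": len(pairs),
        "rows_out": len(rows),
        "n_no_proxy": sum(1 for r in rows if r["status"] == "no_proxy"),
    }
    report.thresholds["r2_min"] = r2_min


def _stage_score(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    source = inputs.get("evidence", "published")
    scheme = scoring.WeightScheme(threshold=params.get("score_threshold", 3))
    if source == "published":
        cards = scoring.cards_from_published()
        rows_in = len(cards)
    elif source == "synthetic":
        sim = simulate.SimulationConfig(seed=int(config.get("seed", 0)))
        records, _truth = simulate.gen_evidence(sim)
        records = scoring.filter_significant(records)
        cards = scoring.score_evidence(records, scheme)
        rows_in = len(records)
    else:
        records = read_evidence_table(source)
        records = scoring.filter_significant(records)
        cards = scoring.score_evidence(records, scheme)
        rows_in = len(records)
    overrides = params.get("overrides", {})
    # overrides only apply where the referenced gene was scored
    overrides = {
        s: g
        for s, g in overrides.items()
        if any(c.signal_rsid == s and c.gene == g for c in cards)
    }
    candidates = scoring.select_candidates(cards, scheme, overrides)
    write_table(
        [
            {
                "signal_rsid": c.signal_rsid,
                "gene": c.gene,
                "base_score": c.base_score,
                "ub_count": c.ub_count,
                "total": c.total,
            }
            for c in cards
        ],
        outdir / "scorecards.tsv",
        ["signal_rsid", "gene", "base_score", "ub_count", "total"],
    )
    write_json(
        {
            "per_signal": {s: [list(p) for p in picks] for s, picks in candidates.per_signal.items()},
            "unique_genes": candidates.unique_genes,
            "annotations": candidates.annotations,
        },
        outdir / "candidates.json",
    )
    report.stages["score"] = {
        "rows_in": rows_in,
        "rows_out": len(cards),
        "n_signals": len(candidates.per_signal),
        "n_threshold_signals": candidates.n_threshold_signals,
        "n_fallback_signals": candidates.n_fallback_signals,
        "n_candidate_genes": len(candidates.unique_genes),
    }
    report.thresholds["score_threshold"] = scheme.threshold
    report.thresholds["max_possible_score"] = scoring.max_possible_score(scheme)
    report.candidates = {
        "unique_genes": candidates.unique_genes,
        "per_signal": {s: [list(p) for p in picks] for s, picks in candidates.per_signal.items()},
    }
    report.annotations.update(candidates.annotations)


def _stage_phewas(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    records = phewas_mod.read_phewas_table(inputs["phewas"])
    groups = (
        phewas_mod.read_trait_groups(inputs["trait_groups"])
        if "trait_groups" in inputs
        else []
    )
    alpha = params.get("alpha", 0.05)
    n_traits = params.get("n_traits", len({r.trait for r in records}))
    threshold = phewas_mod.bonferroni_threshold(alpha, n_traits)
    screened = phewas_mod.screen_traits(records, threshold, groups)
    rows = [
        {
            "rsid": s.record.rsid,
            "trait": s.record.trait,
            "effect": s.record.effect,
            "p_value": s.record.p_value,
            "odds_ratio": s.record.odds_ratio,
            "group": s.group,
            "protective": s.protective,
            "neg_log10_p": s.neg_log10_p,
        }
        for s in screened
    ]
    columns = ["rsid", "trait", "effect", "p_value", "odds_ratio", "group", "protective", "neg_log10_p"]
    write_table(rows, outdir / "phewas_significant.tsv", columns)
    matrix = phewas_mod.significance_matrix(screened)
    matrix.to_csv(outdir / "phewas_matrix.tsv", sep="\t")
    report.stages["phewas"] = {
        "rows_in": len(records),
        "rows_out": len(screened),
        "n_traits": n_traits,
    }
    report.thresholds["phewas_threshold"] = threshold
    report.thresholds["phewas_threshold_display"] = phewas_mod.display_threshold(alpha, n_traits)


def _stage_de(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    if inputs.get("expression") == "synthetic":
        sim = simulate.SimulationConfig(seed=int(config.get("seed", 0)))
        dataset, _planted = simulate.gen_expression(sim)
    else:
        dataset = de_mod.ExpressionDataset.from_tsv(
            inputs["expression_matrix"], inputs["sample_sheet"]
        )
    q = params.get("q", 0.05)
    results = de_mod.run_de(
        dataset,
        q=q,
        force_kruskal=params.get("force_kruskal", False),
        posthoc_adjust=params.get("posthoc_adjust", "per_gene"),
    )
    frame = de_mod.results_frame(results)
    frame.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    report.stages["de"] = {
        "rows_in": len(dataset.genes),
        "rows_out": len(results),
        "n_significant": int(sum(r.significant for r in results)),
    }
    report.thresholds["de_q"] = q


def _stage_enrich(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    collection = read_gmt(inputs["gmt"])
    query_source = inputs.get("query", "candidates")
    if query_source == "candidates":
        if report.candidates is None:
            raise DataError("enrich stage asked for candidates but score stage did not run")
        query = report.candidates["unique_genes"]
    else:
        with Path(query_source).open(encoding="utf-8") as handle:
            query = [line.strip() for line in handle if line.strip()]
    results = enrich_mod.term_enrichment(
        query, collection, mode=params.get("enrich_mode", "ease")
    )
    write_table(
        dataclass_rows(results),
        outdir / "enrichment.tsv",
        ["term", "k", "n", "K", "N", "fold_enrichment", "p_value", "fdr_q", "percent"],
    )
    report.stages["enrich"] = {
        "rows_in": len(collection.terms),
        "rows_out": len(results),
        "n_significant": sum(1 for r in results if r.fdr_q < 0.05),
    }


def _stage_profile(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    out: dict[str, Any] = {}
    rows_in = 0
    if "profiles" in inputs:
        schema = [Column("gene"), Column("class"), Column("value", "float")]
        rows = read_table(inputs["profiles"], schema)
        rows_in += len(rows)
        per_gene: dict[str, dict[str, float]] = {}
        for row in rows:
            per_gene.setdefault(row["gene"], {})[row["class"]] = row["value"]
        fold = params.get("enrichment_fold", 4.0)
        out["enriched"] = {
            gene: sorted(
                profiles_mod.enrichment_flag(
                    profiles_mod.ExpressionProfile(gene, classes), fold=fold
                )
            )
            for gene, classes in per_gene.items()
        }
    if "coloc" in inputs:
        schema = [Column("gene"), Column("tissue_class"), Column("h4", "fraction")]
        rows = read_table(inputs["coloc"], schema)
        rows_in += len(rows)
        summaries = profiles_mod.coloc_summarize(
            (r["gene"], r["tissue_class"], r["h4"]) for r in rows
        )
        by_gene: dict[str, list] = {}
        for s in summaries:
            by_gene.setdefault(s.gene, []).append(s)
        out["coloc"] = {
            gene: {
                "pattern": profiles_mod.classify_coloc_pattern(ss),
                "median_h4": {s.tissue_class: s.median_h4 for s in ss},
            }
            for gene, ss in by_gene.items()
        }
    write_json(out, outdir / "profiles.json")
    report.stages["profile"] = {"rows_in": rows_in, "rows_out": len(out)}


def _stage_drugs(config, params, outdir, report) -> None:
    inputs = config.get("inputs", {})
    source = inputs.get("drugs", "fixture")
    if source == "fixture":
        from .io import drug_query_universe

        records = load_fixture("drug_table")
        genes = drug_query_universe()
    else:
        records = _read_drug_table(source)
        genes = None
    min_score = params.get("min_score", 1.0)
    summary = drugs_mod.summarize_druggability(records, genes=genes, min_score=min_score)
    write_table(
        [
            {
                "gene": s.gene,
                "n_scored": s.n_scored,
                "max_score": s.max_score,
                "has_trial": s.has_trial,
                "trial_ids": ",".join(s.trial_ids),
            }
            for s in summary
        ],
        outdir / "drug_summary.tsv",
        ["gene", "n_scored", "max_score", "has_trial", "trial_ids"],
    )
    report.stages["drugs"] = {
        "rows_in": len(records),
        "rows_out": len(summary),
        "n_genes_with_scored_interaction": sum(1 for s in summary if s.n_scored > 0),
    }
    report.thresholds["drug_min_score"] = min_score


def _read_drug_table(path: str | Path) -> list[drugs_mod.DrugInteraction]:
    schema = [
        Column("gene"),
        Column("drug"),
        Column("interaction_type"),
        Column("pmids"),
        Column("interaction_score", "float", optional=True),
        Column("trial_ids"),
    ]
    records = []
    for row in read_table(path, schema):
        if not row["drug"]:
            continue
        records.append(
            drugs_mod.DrugInteraction(
                gene=row["gene"],
                drug=row["drug"],
                interaction_score=row["interaction_score"],
                interaction_type=row["interaction_type"] or None,
                trial_ids=tuple(t for t in row["trial_ids"].split(",") if t),
            )
        )
    return records


_STAGE_FUNCS = {
    "proxy": _stage_proxy,
    "score": _stage_score,
    "phewas": _stage_phewas,
    "de": _stage_de,
    "enrich": _stage_enrich,
    "profile": _stage_profile,
    "drugs": _stage_drugs,
}


def run_pipeline(config: Mapping[str, Any] | str | Path) -> RunReport:
    """Execute the enabled stages of ``config`` and write a run report.

    ``config`` is a mapping or the path of a YAML file.  A stage failure
    aborts the run with the stage name attached; outputs of stages that
    already completed are left in place.
    """
    if isinstance(config, (str, Path)):
        config = read_yaml(config)
    if not isinstance(config, Mapping):
        raise ValidationError("pipeline config must be a mapping")
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.get("params", {}) or {}
    enabled = config.get("stages", {}) or {}
    unknown = set(enabled) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) {sorted(unknown)}")

    report = RunReport(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.get("seed"),
    )
    for stage in STAGES:
        if not enabled.get(stage, False):
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, params, outdir, report)
        except (ValidationError, DataError):
            raise
        except Exception as exc:  # pragma: no cover - defensive context wrap
            raise DataError(f"stage {stage!r} failed: {exc}") from exc
    report.write(outdir / "report.json")
    return report
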