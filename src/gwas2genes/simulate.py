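"""Seeded generators for pipeline-shaped synthetic inputs.

Each generator is a pure function of its configuration: a single global
seed is fanned out to fixed per-generator streams (a counter-based spawn of
numpy SeedSequence), so adding a generator never perturbs the draws of an
existing one and identical configurations always reproduce identical data.

Defaults mirror the study designs the pipeline was built around: 25
association signals; three subject groups of 20 controls, 50 mild-moderate
and 38 severe asthma subjects (the bronchial-epithelium design; the blood
design 87/77/246 can be requested); 80% true nulls with Beta(0.1, 1)
alternative p-values for FDR calibration; and per-category evidence
occurrence probabilities of 0.8 for the designated causal gene versus 0.05
for decoy genes.  Expression baselines are log-normal — microarray
intensities are right-skewed, which also exercises the normality gate both
ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .de import GROUPS, ExpressionDataset
from .io import EvidenceCategory, EvidenceRecord, UB_CATEGORIES, ValidationError

__all__ = [
    "SimulationConfig",
    "gen_ld_block",
    "gen_evidence",
    "gen_expression",
    "gen_pvalues",
    "EPITHELIUM_GROUP_SIZES",
    "BLOOD_GROUP_SIZES",
]

#: Bronchial-epithelium design: control / mild-moderate / severe.
EPITHELIUM_GROUP_SIZES = (20, 50, 38)
#: Whole-blood design.
BLOOD_GROUP_SIZES = (87, 77, 246)

# fixed stream ids: appending new generators must not shift existing streams
_STREAMS = {"ld": 0, "evidence": 1, "expression": 2, "pvalues": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters shared by the generators (a pure function of these)."""

    seed: int = 0
    # evidence generator
    n_signals: int = 25
    n_genes_per_signal: int = 5
    category_prob_true: float | Mapping[EvidenceCategory, float] = 0.8
    category_prob_decoy: float | Mapping[EvidenceCategory, float] = 0.05
    # LD generator
    ld_decay: float = 0.9
    # expression generator
    n_genes: int = 100
    n_planted: int = 10
    group_sizes: tuple[int, int, int] = EPITHELIUM_GROUP_SIZES
    effect_sd_units: float = 2.0
    # p-value ensemble generator
    m_pvalues: int = 1000
    pi0: float = 0.8
    alt_beta_params: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValidationError(f"pi0 {self.pi0} outside [0, 1]")
        if not 0.0 < self.ld_decay < 1.0:
            raise ValidationError(f"ld_decay {self.ld_decay} outside (0, 1)")
        if min(self.group_sizes) < 3:
            raise ValidationError("group sizes must be >= 3")
        if self.effect_sd_units < 0:
            raise ValidationError("effect_sd_units must be non-negative")
        for p in self._prob_map(self.category_prob_true).values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("category probabilities must lie in [0, 1]")
        for p in self._prob_map(self.category_prob_decoy).values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("category probabilities must lie in [0, 1]")

    @staticmethod
    def _prob_map(
        probs: float | Mapping[EvidenceCategory, float],
    ) -> dict[EvidenceCategory, float]:
        if isinstance(probs, Mapping):
            return {cat: float(probs.get(cat, 0.0)) for cat in EvidenceCategory}
        return {cat: float(probs) for cat in EvidenceCategory}


def gen_ld_block(n_snps: int, ld_decay: float, seed: int = 0) -> np.ndarray:
    """Symmetric r² matrix with geometric distance decay.

    r²(i, j) = ld_decay^(2|i-j|): per-position allelic correlation decay
    ``ld_decay`` squared into r² units.  Deterministic given its arguments
    (the seed is accepted for interface symmetry with the other
    generators).
    """
    if n_snps < 2:
        raise ValidationError("need >= 2 SNPs")
    if not 0.0 < ld_decay < 1.0:
        raise ValidationError(f"ld_decay {ld_decay} outside (0, 1)")
    idx = np.arange(n_snps)
    dist = np.abs(idx[:, None] - idx[None, :])
    return ld_decay ** (2.0 * dist)


def gen_evidence(
    config: SimulationConfig,
) -> tuple[list[EvidenceRecord], dict[str, str]]:
    """Evidence records with one planted causal gene per signal.

    The designated gene of each signal receives each evidence category
    independently with the elevated probability; decoy genes with the
    background probability.  Generated p-values sit below the 0.05
    significance rule and coloc H4 above 0.8, so the records survive
    upstream significance filtering by construction.  Returns the records
    and the signal -> designated-gene truth map.
    """
    rng = _rng(config.seed, "evidence")
    p_true = SimulationConfig._prob_map(config.category_prob_true)
    p_decoy = SimulationConfig._prob_map(config.category_prob_decoy)
    records: list[EvidenceRecord] = []
    truth: dict[str, str] = {}
    for s in range(config.n_signals):
        signal = f"rs_sim{s:03d}"
        genes = [f"GENE{s:03d}_{g}" for g in range(config.n_genes_per_signal)]
        truth[signal] = genes[0]
        for gi, gene in enumerate(genes):
            probs = p_true if gi == 0 else p_decoy
            for cat in EvidenceCategory:
                if rng.random() >= probs[cat]:
                    continue
                p_value = None
                h4 = None
                effect = None
                if cat is EvidenceCategory.OTG_COLOC:
                    h4 = float(rng.uniform(0.81, 0.99))
                elif cat not in (
                    EvidenceCategory.OTG_V2G,
                    EvidenceCategory.FUNCTIONAL_VARIANT_LD,
                    EvidenceCategory.LITERATURE,
                ):
                    p_value = float(rng.uniform(1e-6, 0.049))
                    effect = float(rng.normal(0.0, 0.3))
                tissue = "respiratory" if cat in UB_CATEGORIES else "mixed"
                records.append(
                    EvidenceRecord(
                        signal_rsid=signal,
                        gene=gene,
                        category=cat,
                        tissue=tissue,
                        p_value=p_value,
                        effect_b=effect,
                        h4=h4,
                    )
                )
    return records, truth


def gen_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, list[str]]:
    """Three-group expression matrix with planted differential genes.

    Baseline intensities are log-normal per gene; each planted gene's
    asthma groups (mild-moderate and severe) are shifted upward by
    ``effect_sd_units`` times that gene's theoretical baseline standard
    deviation.  Returns the dataset and the planted gene names.
    """
    rng = _rng(config.seed, "expression")
    n_control, n_mild, n_severe = config.group_sizes
    sizes = {"control": n_control, "mild_moderate": n_mild, "severe": n_severe}
    samples: list[str] = []
    group: dict[str, str] = {}
    for level in GROUPS:
        for i in range(sizes[level]):
            name = f"{level}_{i:03d}"
            samples.append(name)
            group[name] = level
    n_samples = len(samples)

    genes = [f"g{g:04d}" for g in range(config.n_genes)]
    planted = genes[: config.n_planted]
    mu = rng.uniform(4.0, 7.0, size=config.n_genes)
    sigma = rng.uniform(0.2, 0.5, size=config.n_genes)
    values = np.exp(rng.normal(mu[:, None], sigma[:, None], size=(config.n_genes, n_samples)))
    # theoretical SD of the log-normal baseline
    sd = np.sqrt(np.exp(sigma**2) - 1.0) * np.exp(mu + sigma**2 / 2.0)
    asthma_cols = np.array([i for i, s in enumerate(samples) if group[s] != "control"])
    for gi in range(config.n_planted):
        values[gi, asthma_cols] += config.effect_sd_units * sd[gi]
    dataset = ExpressionDataset(genes=genes, samples=samples, values=values, group=group)
    return dataset, planted


def gen_pvalues(
    m: int,
    pi0: float,
    alt_beta_params: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """p-value ensemble with floor(pi0 * m) uniform nulls.

    Alternatives draw from Beta(a, b) (the default Beta(0.1, 1) piles mass
    near zero).  Returns (p_values, is_null) with nulls first.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0.0 <= pi0 <= 1.0:
        raise ValidationError(f"pi0 {pi0} outside [0, 1]")
    a, b = alt_beta_params
    if a <= 0 or b <= 0:
        raise ValidationError("Beta parameters must be positive")
    rng = _rng(seed, "pvalues")
    n_null = int(np.floor(pi0 * m))
    nulls = rng.uniform(0.0, 1.0, size=n_null)
    alts = rng.beta(a, b, size=m - n_null)
    p = np.concatenate([nulls, alts])
    is_null = np.zeros(m, dtype=bool)
    is_null[:n_null] = True
    return p, is_null
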