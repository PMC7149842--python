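"""Case-control cohort simulator with known per-gene carrier rates.

For gene ``g`` with control carrier probability ``p_g`` and enrichment
odds ratio ``theta_g``, case carrier probability is obtained by odds
scaling::

    p'_g = theta_g * p_g / (1 - p_g + theta_g * p_g)

so ``theta_g`` is exactly the (conditional) odds ratio the Fisher test
estimates. Each carrier event produces one heterozygous variant at a
unique synthetic site with a qualifying external AF; distractor variants
are injected that each fail exactly one named filter criterion.

Randomness is confined to a single seeded generator; experiment replicate
``r`` uses the derived seed sequence ``(seed, r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .burden_stats import gene_burden_scan
from .cohort_model_io.models import (
    CohortDataset,
    Consequence,
    GenePanel,
    Group,
    IndividualRecord,
    VariantRecord,
)
from .qualifying_filter import FilterConfig, select_qualifying

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "SimulationTruth",
    "case_carrier_probability",
    "simulate_cohort",
    "type_i_error_experiment",
    "power_and_recovery_experiment",
]

_CONSEQUENCE_CHOICES = (
    Consequence.MISSENSE,
    Consequence.SPLICE_REGION,
    Consequence.SYNONYMOUS,
    Consequence.INFRAME_INSERTION,
)
_CONSEQUENCE_WEIGHTS = (0.7, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters for one gene."""

    carrier_probability: float  # control carrier probability p_g
    odds_ratio: float = 1.0  # theta_g; 1 = null

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_probability < 1.0):
            raise ValueError(f"carrier_probability must be in [0,1), got {self.carrier_probability}")
        if self.odds_ratio < 0.0:
            raise ValueError(f"odds_ratio must be >= 0, got {self.odds_ratio}")


@dataclass(frozen=True)
class SimulationConfig:
    genes: Mapping[str, GeneSpec]
    seed: int
    n_cases: int = 37
    n_controls: int = 534
    n_common_distractors: int = 0  # fail the external-AF criterion
    n_offpanel_distractors: int = 0  # fail the panel criterion
    qualifying_af_range: Tuple[float, float] = (0.0, 5e-5)
    common_af: float = 0.01
    variants_per_carrier_lambda: Optional[float] = None  # Poisson allelic series if set

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not self.genes:
            raise ValueError("at least one gene must be specified")
        lo, hi = self.qualifying_af_range
        if not (0.0 <= lo <= hi < 0.001):
            raise ValueError("qualifying_af_range must lie inside [0, 0.001)")

    def panel(self) -> GenePanel:
        return GenePanel("simulated", self.genes.keys())


@dataclass(frozen=True)
class SimulationTruth:
    gene_specs: Dict[str, GeneSpec]
    case_probabilities: Dict[str, float]
    carriers_by_gene: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]]  # (case ids, control ids)

    def carrier_counts(self, gene: str) -> Tuple[int, int]:
        cases, controls = self.carriers_by_gene[gene]
        return len(cases), len(controls)


def case_carrier_probability(p: float, theta: float) -> float:
    """Odds-scaled case carrier probability p' = theta*p / (1 - p + theta*p)."""
    return theta * p / (1.0 - p + theta * p)


def simulate_cohort(config: SimulationConfig) -> Tuple[CohortDataset, SimulationTruth]:
    """Draw one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    case_ids = [f"SIM_CASE{i:05d}" for i in range(config.n_cases)]
    control_ids = [f"SIM_CTRL{i:05d}" for i in range(config.n_controls)]
    individuals = [IndividualRecord(i, Group.CASE) for i in case_ids] + [
        IndividualRecord(i, Group.CONTROL) for i in control_ids
    ]
    n_total = len(individuals)

    variants: List[VariantRecord] = []
    columns: List[np.ndarray] = []
    carriers_by_gene: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {}
    case_probs: Dict[str, float] = {}
    position = 1_000_000

    def add_variant(gene: str, carrier_rows: List[int], consequence: Consequence,
                    af: float) -> None:
        nonlocal position
        position += 1
        variants.append(
            VariantRecord(
                chrom="1", pos=position, ref="C", alt="T", gene_symbol=gene,
                consequence=consequence,
                external_afs={"ExAC": af} if af > 0 else {},
            )
        )
        column = np.zeros(n_total, dtype=np.int8)
        column[carrier_rows] = 1
        columns.append(column)

    def qualifying_af() -> float:
        lo, hi = config.qualifying_af_range
        return float(rng.uniform(lo, hi))

    def draw_consequence() -> Consequence:
        return _CONSEQUENCE_CHOICES[rng.choice(len(_CONSEQUENCE_CHOICES), p=_CONSEQUENCE_WEIGHTS)]

    for gene in sorted(config.genes):
        spec = config.genes[gene]
        p_case = case_carrier_probability(spec.carrier_probability, spec.odds_ratio)
        case_probs[gene] = p_case
        is_carrier = np.concatenate(
            [
                rng.random(config.n_cases) < p_case,
                rng.random(config.n_controls) < spec.carrier_probability,
            ]
        )
        carrier_rows = np.flatnonzero(is_carrier)
        for row in carrier_rows:
            n_sites = (
                1
                if config.variants_per_carrier_lambda is None
                else 1 + int(rng.poisson(config.variants_per_carrier_lambda))
            )
            for _ in range(n_sites):
                add_variant(gene, [int(row)], draw_consequence(), qualifying_af())
        carriers_by_gene[gene] = (
            tuple(case_ids[r] for r in carrier_rows if r < config.n_cases),
            tuple(control_ids[r - config.n_cases] for r in carrier_rows if r >= config.n_cases),
        )

    gene_names = sorted(config.genes)
    for _ in range(config.n_common_distractors):
        gene = gene_names[int(rng.integers(len(gene_names)))]
        row = int(rng.integers(n_total))
        add_variant(gene, [row], Consequence.MISSENSE, config.common_af)
    for i in range(config.n_offpanel_distractors):
        row = int(rng.integers(n_total))
        add_variant(f"SIM_OFFPANEL{i}", [row], Consequence.MISSENSE, qualifying_af())

    dosages = (
        np.stack(columns, axis=1) if columns else np.zeros((n_total, 0), dtype=np.int8)
    )
    cohort = CohortDataset(individuals, variants, dosages)
    truth = SimulationTruth(
        gene_specs=dict(config.genes),
        case_probabilities=case_probs,
        carriers_by_gene=carriers_by_gene,
    )
    return cohort, truth


def _replicate_config(config: SimulationConfig, replicate: int) -> SimulationConfig:
    # derive a per-replicate seed from (seed, r): reproducible and independent
    derived = int(np.random.SeedSequence([config.seed, replicate]).generate_state(1)[0])
    return SimulationConfig(
        genes=config.genes, seed=derived, n_cases=config.n_cases,
        n_controls=config.n_controls,
        n_common_distractors=config.n_common_distractors,
        n_offpanel_distractors=config.n_offpanel_distractors,
        qualifying_af_range=config.qualifying_af_range, common_af=config.common_af,
        variants_per_carrier_lambda=config.variants_per_carrier_lambda,
    )


def _run_pipeline(config: SimulationConfig, replicate: int):
    cohort, truth = simulate_cohort(_replicate_config(config, replicate))
    panel = config.panel()
    qualifying = select_qualifying(cohort, FilterConfig(), panel)
    return gene_burden_scan(cohort, panel, qualifying), truth


@dataclass(frozen=True)
class TypeIErrorResult:
    alpha: float
    n_reps: int
    n_null_tests: int
    rejection_rate_chi2: float
    rejection_rate_fisher_one_sided: float
    mc_standard_error_chi2: float
    mc_standard_error_fisher: float


def type_i_error_experiment(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
) -> TypeIErrorResult:
    """Full-pipeline null calibration: fraction of null genes with p < alpha."""
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a meaningful rate")
    null_genes = {g for g, spec in config.genes.items() if spec.odds_ratio == 1.0}
    n_tests = 0
    rejected_chi2 = 0
    rejected_fisher = 0
    for rep in range(n_reps):
        results, _ = _run_pipeline(config, rep)
        for res in results:
            if res.gene_symbol not in null_genes:
                continue
            n_tests += 1
            rejected_chi2 += res.p_chi2 < alpha
            rejected_fisher += res.p_fisher_one_sided < alpha
    rate_chi2 = rejected_chi2 / n_tests
    rate_fisher = rejected_fisher / n_tests

    def mc_se(rate: float) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / n_tests))

    return TypeIErrorResult(
        alpha=alpha, n_reps=n_reps, n_null_tests=n_tests,
        rejection_rate_chi2=rate_chi2,
        rejection_rate_fisher_one_sided=rate_fisher,
        mc_standard_error_chi2=mc_se(rate_chi2),
        mc_standard_error_fisher=mc_se(rate_fisher),
    )


@dataclass(frozen=True)
class RecoveryResult:
    gene: str
    true_odds_ratio: float
    n_reps: int
    detection_rate_top_k: float
    top_k: int
    pooled_odds_ratio: float
    pooled_log_or_ci: Tuple[float, float]  # ~95% Wald interval on the pooled estimate
    rank_one_rate: float


def power_and_recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    top_k: int = 5,
) -> Dict[str, RecoveryResult]:
    """Detection rate and pooled odds-ratio recovery for the planted genes.

    The pooled estimate aggregates carrier counts over all replicates with a
    Haldane-Anscombe 0.5 correction before forming the odds ratio.
    """
    planted = sorted(g for g, spec in config.genes.items() if spec.odds_ratio != 1.0)
    if not planted:
        raise ValueError("no gene with odds_ratio != 1 to recover")
    pooled = {g: np.zeros(4, dtype=np.int64) for g in planted}
    detected = {g: 0 for g in planted}
    rank_one = {g: 0 for g in planted}
    for rep in range(n_reps):
        results, _ = _run_pipeline(config, rep)
        ranks = {res.gene_symbol: rank for rank, res in enumerate(results, start=1)}
        by_gene = {res.gene_symbol: res for res in results}
        for g in planted:
            table = by_gene[g].table
            pooled[g] += (table.a, table.b, table.c, table.d)
            detected[g] += ranks[g] <= top_k
            rank_one[g] += ranks[g] == 1

    out = {}
    for g in planted:
        a, b, c, d = (float(v) + 0.5 for v in pooled[g])
        log_or = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        out[g] = RecoveryResult(
            gene=g,
            true_odds_ratio=config.genes[g].odds_ratio,
            n_reps=n_reps,
            detection_rate_top_k=detected[g] / n_reps,
            top_k=top_k,
            pooled_odds_ratio=float(np.exp(log_or)),
            pooled_log_or_ci=(float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))),
            rank_one_rate=rank_one[g] / n_reps,
        )
    return out
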