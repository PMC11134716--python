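"""Synthetic tumor cohorts with planted, fully known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial RNA-seq counts with sample-specific library
sizes, a tumor vs adjacent-normal contrast with planted fold-changes, and
right-censored survival times whose hazard depends on the *dichotomized*
(above/below tumor-median) expression of planted prognosis genes.

Dichotomizing inside the generative model makes the planted hazard ratio
the estimand of the downstream median-split Cox fit, so parameter recovery
is a sharp test.  Survival times are exponential (constant baseline
hazard), hence exactly proportional-hazards; censoring is independent
uniform, calibrated to a target censoring fraction.

Gene-level truth (which genes are planted, their baseline means and fold
changes) is drawn from ``config.seed``; sample-level noise from
``cohort_seed``.  Two calls with the same config but different cohort
seeds therefore yield independent cohorts from the *same* generative
truth — the train/validate design the score-transfer experiments need.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CATEGORIES,
    STAGES,
    UP_CATEGORIES,
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
)

logger = logging.getLogger("sahr")

#: config order of the planted-gene tuple
PLANTED_ORDER = (
    "oncogene_like",
    "up_regulated_saver",
    "down_regulated_saver",
    "suppressor_like",
)

#: marginal stage frequencies, roughly early-heavy as in resected cohorts
STAGE_PROBS = (0.35, 0.30, 0.25, 0.10)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults are the reference study conditions used throughout the test
    suite: 400 tumors vs 50 normals, 500 genes with 10 planted per
    prognosis category, 4-fold planted expression changes, per-gene
    dichotomized hazard ratio 2.5 and 30% censoring.
    """

    n_genes: int = 500
    n_tumor: int = 400
    n_normal: int = 50
    baseline_mean_log_range: tuple[float, float] = (1.5, 8.0)  # ln of mean count
    nb_dispersion: float = 0.2
    size_factor_log_sd: float = 0.3
    n_planted_per_category: tuple[int, int, int, int] = (10, 10, 10, 10)
    de_log2fc: float = 2.0
    planted_hr: float = 2.5
    baseline_hazard: float = 1e-3
    censoring_rate_target: float = 0.3
    zero_inflation_fraction: float = 0.0
    zero_inflation_dropout: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tumor < 1 or self.n_normal < 1:
            raise ValidationError("n_genes, n_tumor, n_normal must be positive")
        if len(self.n_planted_per_category) != 4 or any(
            k < 0 for k in self.n_planted_per_category
        ):
            raise ValidationError("n_planted_per_category must be 4 non-negative ints")
        if sum(self.n_planted_per_category) > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")
        if self.planted_hr < 1.0:
            raise ValidationError("planted_hr must be >= 1 (1 = no survival effect)")
        if not (0.0 <= self.censoring_rate_target < 1.0):
            raise ValidationError("censoring_rate_target must lie in [0, 1)")
        if not (0.0 <= self.zero_inflation_fraction < 1.0):
            raise ValidationError("zero_inflation_fraction must lie in [0, 1)")
        if not (0.0 <= self.zero_inflation_dropout < 1.0):
            raise ValidationError("zero_inflation_dropout must lie in [0, 1)")
        if self.nb_dispersion < 0 or self.size_factor_log_sd < 0:
            raise ValidationError("dispersion and size-factor sd must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        lo, hi = self.baseline_mean_log_range
        if not lo <= hi:
            raise ValidationError("baseline_mean_log_range must be ordered")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort.

    ``genes`` has one row per planted gene (category, direction, planted
    log2 fold change and hazard ratio, zero-inflation flag);
    ``linear_predictor`` is each tumor sample's true log-hazard offset.
    """

    genes: pd.DataFrame
    linear_predictor: pd.Series
    config: SimulationConfig = field(repr=False)


def calibrate_censoring(times: Sequence[float], target_rate: float) -> float:
    """Upper bound b of a Uniform(0, b) censoring law hitting a target rate.

    For C ~ U(0, b) the expected censoring fraction over the given event
    times is mean(min(t/b, 1)), monotone decreasing in b; the bound solving
    it for ``target_rate`` is found by bracketing + Brent search.  A target
    of 0 returns ``inf`` (no censoring).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValidationError("calibrate_censoring: empty times")
    if not (0.0 <= target_rate < 1.0):
        raise ValidationError("target censoring rate must lie in [0, 1)")
    if target_rate == 0.0:
        return float("inf")
    pos_frac = float(np.mean(t > 0))
    if target_rate >= pos_frac:  # unreachable: zero times are never censored
        raise ValidationError(
            f"target {target_rate} unreachable: only {pos_frac:.3f} of times are positive"
        )

    def realized(b: float) -> float:
        return float(np.mean(np.minimum(t / b, 1.0)))

    lo = max(float(t[t > 0].min()) * 1e-9, 1e-300)
    hi = max(float(t.max()), lo * 10)
    while realized(hi) > target_rate:
        hi *= 10.0
        if hi > 1e300:
            break
    return float(brentq(lambda b: realized(b) - target_rate, lo, hi, xtol=1e-12, rtol=1e-12))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(
    config: SimulationConfig, cohort_seed: int | None = None
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate one cohort: counts, clinical table and planted truth.

    Deterministic given ``(config, cohort_seed)``; ``cohort_seed`` defaults
    to ``config.seed``.
    """
    cohort_seed = config.seed if cohort_seed is None else cohort_seed
    truth_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    rng = np.random.default_rng(np.random.SeedSequence([int(cohort_seed), 1]))

    n_genes, n_tumor, n_normal = config.n_genes, config.n_tumor, config.n_normal
    gene_ids = np.array([f"G{i:05d}" for i in range(1, n_genes + 1)])
    tumor_ids = [f"T{i:04d}" for i in range(1, n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, n_normal + 1)]

    # ---- gene-level truth -------------------------------------------------
    lo, hi = config.baseline_mean_log_range
    base_mean = np.exp(truth_rng.uniform(lo, hi, size=n_genes))
    total_planted = sum(config.n_planted_per_category)
    planted_idx = truth_rng.choice(n_genes, size=total_planted, replace=False)
    category = np.full(n_genes, "", dtype=object)
    start = 0
    for cat, k in zip(PLANTED_ORDER, config.n_planted_per_category):
        category[planted_idx[start : start + k]] = cat
        start += k
    lfc = np.zeros(n_genes)
    for cat in PLANTED_ORDER:
        sign = 1.0 if cat in UP_CATEGORIES else -1.0
        lfc[category == cat] = sign * config.de_log2fc
    n_zi = int(round(config.zero_inflation_fraction * total_planted))
    zi_genes = (
        truth_rng.choice(planted_idx, size=n_zi, replace=False) if n_zi else np.array([], int)
    )
    zero_inflated = np.zeros(n_genes, dtype=bool)
    zero_inflated[zi_genes] = True

    # ---- counts -----------------------------------------------------------
    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_tumor + n_normal))
    tumor_mean = base_mean[:, None] * (2.0 ** lfc)[:, None] * size_factors[None, :n_tumor]
    normal_mean = base_mean[:, None] * size_factors[None, n_tumor:]
    counts = np.empty((n_genes, n_tumor + n_normal), dtype=np.int64)
    counts[:, :n_tumor] = _nb_draw(rng, tumor_mean, config.nb_dispersion)
    counts[:, n_tumor:] = _nb_draw(rng, normal_mean, config.nb_dispersion)
    if n_zi:
        dropout = rng.random((n_zi, n_tumor)) < config.zero_inflation_dropout
        counts[zi_genes[:, None].repeat(n_tumor, 1), np.arange(n_tumor)[None, :]] *= ~dropout

    # ---- survival ---------------------------------------------------------
    # risk indicator: true normalized expression above the tumor median
    true_norm_tumor = counts[:, :n_tumor] / size_factors[None, :n_tumor]
    lp = np.zeros(n_tumor)
    log_hr = np.log(config.planted_hr)
    for g in planted_idx:
        z = true_norm_tumor[g] > np.median(true_norm_tumor[g])
        sign = 1.0 if category[g] in ("oncogene_like", "down_regulated_saver") else -1.0
        lp += sign * log_hr * z
    hazard = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate_target > 0:
        bound = calibrate_censoring(event_time, config.censoring_rate_target)
        cens_time = rng.uniform(0.0, bound, n_tumor)
        os_time = np.minimum(event_time, cens_time)
        os_event = (event_time <= cens_time).astype(int)
    else:
        os_time = event_time
        os_event = np.ones(n_tumor, dtype=int)

    stage = rng.choice(STAGES, size=n_tumor, p=STAGE_PROBS)
    split = _stratified_split(os_event, rng)

    # ---- assemble ---------------------------------------------------------
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=tumor_ids + normal_ids
    )
    expr = ExpressionMatrix(counts=counts_df)
    clinical = pd.DataFrame(
        {
            "condition": ["tumor"] * n_tumor + ["normal"] * n_normal,
            "os_time": np.concatenate([os_time, np.full(n_normal, np.nan)]),
            "os_event": np.concatenate([os_event.astype(float), np.full(n_normal, np.nan)]),
            "stage": list(stage) + ["unknown"] * n_normal,
            "split": list(split) + ["unassigned"] * n_normal,
        },
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    order = np.argsort(planted_idx, kind="stable")
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids[planted_idx[order]],
            "category": category[planted_idx[order]],
            "direction": [
                "up" if category[g] in UP_CATEGORIES else "down" for g in planted_idx[order]
            ],
            "log2_fold_change": lfc[planted_idx[order]],
            "hr": config.planted_hr,
            "zero_inflated": zero_inflated[planted_idx[order]],
        }
    ).reset_index(drop=True)
    truth = SyntheticTruth(
        genes=truth_genes,
        linear_predictor=pd.Series(lp, index=tumor_ids, name="linear_predictor"),
        config=config,
    )
    logger.info(
        "simulate_cohort: %d genes x (%d tumor + %d normal), %d planted, %.1f%% censored",
        n_genes, n_tumor, n_normal, total_planted, 100 * (1 - os_event.mean()),
    )
    return expr, ClinicalTable(clinical), truth


def _stratified_split(events: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """50/50 train/test split stratified by the event indicator."""
    split = np.full(len(events), "test", dtype=object)
    for value in (0, 1):
        idx = np.flatnonzero(events == value)
        idx = rng.permutation(idx)
        split[idx[: (len(idx) + 1) // 2]] = "train"
    return split


def assign_split(
    clinical: ClinicalTable, seed: int, force: bool = False
) -> ClinicalTable:
    """Assign a seeded, event-stratified 50/50 train/test split to tumors.

    Existing assignments are kept unless ``force``; normals stay unassigned.
    """
    df = clinical.data.copy()
    tumors = df.index[df["condition"] == "tumor"]
    if not force and (df.loc[tumors, "split"] != "unassigned").all():
        return clinical
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    events = df.loc[tumors, "os_event"].fillna(0).to_numpy()
    df.loc[tumors, "split"] = _stratified_split(events, rng)
    return ClinicalTable(df)


def write_truth(truth: SyntheticTruth, genes_path, lp_path) -> None:
    """Persist a truth table: planted genes TSV + per-sample linear predictor TSV."""
    truth.genes.to_csv(genes_path, sep="\t", index=False)
    truth.linear_predictor.rename_axis("sample_id").to_csv(lp_path, sep="\t")
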