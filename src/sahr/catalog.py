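"""Median-split survival screening and four-way prognosis categorization.

Every differentially expressed gene is dichotomized at its training-tumor
median expression and the two patient groups compared by univariable Cox
regression.  Combining the DE direction with the hazard ratio of the
lower- vs higher-expression group (HR_lh) yields four behavioral classes:

====================  =========  ==============================
DE direction          HR_lh      category
====================  =========  ==============================
up                    < 1        oncogene_like
up                    >= 1       up_regulated_saver
down                  < 1        down_regulated_saver
down                  >= 1       suppressor_like
====================  =========  ==============================

Genes whose Cox p-value is >= 0.05 stay uncategorized (``none``).  The
stored hazard ratio is re-oriented worse-vs-better group, hence always
>= 1.  Genes unexpressed in more than 30% of tumors are split at zero
instead of the median (zero samples -> lower-expression group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, ValidationError
from .stats import MonotoneLikelihoodWarning, cox_binary

logger = logging.getLogger("sahr")

DEFAULT_ALPHA = 0.05
DEFAULT_ZERO_FRACTION = 0.30
MIN_SPLIT_SAMPLES = 4


@dataclass(frozen=True)
class PrognosisGeneRecord:
    gene_id: str
    direction: str            # up / down
    cutoff: float
    hr: float                 # worse-vs-better oriented, >= 1
    cox_p: float
    category: str             # one of the four, or "none"
    zero_rule_applied: bool
    unsplittable: bool = False
    flagged: bool = False     # monotone-likelihood Cox fit


@dataclass(frozen=True)
class MedianSplit:
    cutoff: float
    higher: np.ndarray        # boolean per sample
    zero_rule_applied: bool
    unsplittable: bool


def median_split(
    values, zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION
) -> MedianSplit:
    """Dichotomize expression values at the median (or at zero).

    Samples strictly above the cutoff form the higher-expression group;
    ties with the cutoff go to lower.  When more than
    ``zero_fraction_threshold`` of the values are exactly zero the cutoff
    is zero instead: unexpressed samples are lower, all others higher.
    A split leaving one group empty is marked unsplittable.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < MIN_SPLIT_SAMPLES:
        raise ValidationError(f"median_split needs >= {MIN_SPLIT_SAMPLES} samples")
    zero_frac = float(np.mean(v == 0.0))
    if zero_frac > zero_fraction_threshold:
        cutoff, zero_rule = 0.0, True
    else:
        cutoff, zero_rule = float(np.median(v)), False
    higher = v > cutoff
    unsplittable = bool(higher.all() or (~higher).all())
    return MedianSplit(cutoff, higher, zero_rule, unsplittable)


def categorize(direction: str, hr_lower_vs_higher: float, cox_p: float,
               alpha: float = DEFAULT_ALPHA) -> str:
    """Pure mapping (direction, HR_lh, p) -> category."""
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be up or down, got {direction!r}")
    if cox_p >= alpha:
        return "none"
    if direction == "up":
        return "oncogene_like" if hr_lower_vs_higher < 1.0 else "up_regulated_saver"
    return "down_regulated_saver" if hr_lower_vs_higher < 1.0 else "suppressor_like"


def screen_gene(
    values,
    times,
    events,
    direction: str,
    gene_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION,
) -> PrognosisGeneRecord:
    """Median-split + Cox screen of one DE gene on training tumors.

    ``values`` are normalized expression values aligned with ``times`` /
    ``events``.  The Cox covariate is membership of the *lower*-expression
    group, so exp(beta) is HR_lh directly; the stored ``hr`` is
    re-oriented to the worse-vs-better group (max(HR_lh, 1/HR_lh)).
    """
    split = median_split(values, zero_fraction_threshold)
    if split.unsplittable:
        return PrognosisGeneRecord(
            gene_id=gene_id, direction=direction, cutoff=split.cutoff,
            hr=float("nan"), cox_p=float("nan"), category="none",
            zero_rule_applied=split.zero_rule_applied, unsplittable=True,
        )
    lower = (~split.higher).astype(int)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", MonotoneLikelihoodWarning)
        fit = cox_binary(times, events, lower)
    flagged = fit.flagged
    if flagged:
        logger.warning("screen_gene %s: monotone likelihood, HR capped", gene_id)
    hr_lh = fit.hr
    category = categorize(direction, hr_lh, fit.wald_p, alpha)
    oriented = max(hr_lh, 1.0 / hr_lh)
    return PrognosisGeneRecord(
        gene_id=gene_id, direction=direction, cutoff=split.cutoff,
        hr=float(oriented), cox_p=float(fit.wald_p), category=category,
        zero_rule_applied=split.zero_rule_applied, flagged=flagged,
    )


def catalog_cohort(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    deg_table: pd.DataFrame,
    use_split: str = "train",
    alpha: float = DEFAULT_ALPHA,
    zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every DEG on the chosen tumor subset.

    ``use_split`` selects the tumors screened: ``"train"`` (default,
    avoids test-set leakage) or ``"all"`` (whole-cohort screening, the
    descriptive-catalog variant).  Returns the per-gene catalog frame and
    a per-category frequency summary.
    """
    if use_split not in ("train", "all"):
        raise ValidationError("use_split must be 'train' or 'all'")
    if matrix.normalized is None:
        raise ValidationError("catalog_cohort requires a normalized matrix")
    tumors = clinical.tumors()
    if use_split == "train":
        tumors = tumors[tumors["split"] == "train"]
    tumors = tumors[tumors["os_time"].notna() & tumors["os_event"].notna()]
    if len(tumors) < MIN_SPLIT_SAMPLES:
        raise ValidationError("not enough training tumors with survival data")
    surv = clinical.survival_frame(tumors.index)
    times = surv["time"].to_numpy()
    events = surv["event"].to_numpy()

    degs = deg_table[deg_table["direction"].isin(["up", "down"])]
    records: list[PrognosisGeneRecord] = []
    if len(degs) == 0:
        logger.warning("catalog_cohort: no DEGs to screen; empty catalog")
    for gene_id, direction in zip(degs["gene_id"], degs["direction"]):
        if gene_id not in matrix.gene_ids:
            raise ValidationError(f"DEG {gene_id!r} absent from expression matrix")
        values = matrix.normalized.loc[gene_id, tumors.index].to_numpy(dtype=float)
        records.append(
            screen_gene(
                values, times, events, direction, gene_id=gene_id,
                alpha=alpha, zero_fraction_threshold=zero_fraction_threshold,
            )
        )
    catalog = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=[
            "gene_id", "direction", "cutoff", "hr", "cox_p", "category",
            "zero_rule_applied", "unsplittable", "flagged",
        ],
    )
    cats = ["oncogene_like", "suppressor_like", "up_regulated_saver",
            "down_regulated_saver", "none"]
    summary = (
        catalog["category"].value_counts().reindex(cats, fill_value=0).rename("n_genes")
        .rename_axis("category").reset_index()
        if len(catalog)
        else pd.DataFrame({"category": cats, "n_genes": 0})
    )
    logger.info(
        "catalog_cohort: screened %d DEGs on %d tumors (%s); categorized %d",
        len(catalog), len(tumors), use_split,
        int((catalog["category"] != "none").sum()) if len(catalog) else 0,
    )
    return catalog, summary
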