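"""Tumor vs adjacent-normal differential expression.

A gene is called differentially expressed when its Benjamini-Hochberg
adjusted p-value is below 0.01 and it changes at least 2-fold between
tumors and adjacent normals.  The two-group test is Welch's t on
log2(normalized + pseudocount); downstream stages consume only the call
(direction + significance), for which this is an adequate, dependency-free
test.  Ribosomal RNA genes are removed before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("sahr")

DEFAULT_ADJ_P = 0.01
DEFAULT_FOLD_CHANGE = 2.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adj_p_value: float
    direction: str  # up / down / none


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; ties in the
    input map to identical outputs and the input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def remove_rrna(matrix: ExpressionMatrix, rrna_gene_list: Iterable[str]) -> ExpressionMatrix:
    """Drop ribosomal RNA genes; unknown ids are ignored with a warning."""
    wanted = list(rrna_gene_list)
    present = [g for g in wanted if g in matrix.gene_ids]
    unknown = set(wanted) - set(present)
    if unknown:
        logger.warning("remove_rrna: %d listed ids not in matrix (ignored)", len(unknown))
    out = matrix.drop_genes(present)
    logger.info("remove_rrna: removed %d genes, %d remain", len(present), out.n_genes)
    return out


def test_differential(
    matrix: ExpressionMatrix,
    conditions: pd.Series | Sequence[str],
    adj_p_threshold: float = DEFAULT_ADJ_P,
    fold_change_threshold: float = DEFAULT_FOLD_CHANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Welch-test every gene for a tumor vs normal expression difference.

    ``matrix`` must be normalized.  ``conditions`` maps each sample to
    ``tumor`` or ``normal`` (aligned with the sample order, or a Series
    indexed by sample id).  Returns a gene-ordered frame with columns
    ``gene_id``, ``log2_fold_change``, ``p_value``, ``adj_p_value``,
    ``direction``; direction is ``up``/``down`` only when the adjusted p
    is below the threshold *and* |log2FC| clears the fold-change bar.
    """
    if matrix.normalized is None:
        raise ValidationError("test_differential requires a normalized matrix")
    if isinstance(conditions, pd.Series):
        cond = conditions.reindex(matrix.sample_ids)
        if cond.isna().any():
            sid = cond.index[cond.isna()][0]
            raise ValidationError(f"no condition for sample {sid!r}")
        cond = cond.to_numpy()
    else:
        cond = np.asarray(list(conditions))
        if cond.shape[0] != matrix.n_samples:
            raise ValidationError("conditions must align with samples")
    is_tumor = cond == "tumor"
    is_normal = cond == "normal"
    if is_tumor.sum() < 2 or is_normal.sum() < 2:
        raise ValidationError("need >= 2 tumor and >= 2 normal samples")

    norm = matrix.normalized.to_numpy(dtype=float)
    log_norm = np.log2(norm + pseudocount)
    a = log_norm[:, is_tumor]
    b = log_norm[:, is_normal]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    # zero-variance genes: identical means -> no evidence; different -> certain
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & np.isclose(mean_a, mean_b)] = 1.0
    p[degenerate & ~np.isclose(mean_a, mean_b)] = 0.0

    lfc = np.log2(
        (norm[:, is_tumor].mean(axis=1) + pseudocount)
        / (norm[:, is_normal].mean(axis=1) + pseudocount)
    )
    adj = bh_adjust(p)
    lfc_bar = np.log2(fold_change_threshold)
    significant = adj < adj_p_threshold
    direction = np.where(
        significant & (lfc >= lfc_bar), "up",
        np.where(significant & (lfc <= -lfc_bar), "down", "none"),
    )
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "adj_p_value": adj,
            "direction": direction,
        }
    ).reset_index(drop=True)
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    logger.info(
        "test_differential: %d genes tested, %d up, %d down (adj p < %g, fold >= %g)",
        len(out), n_up, n_down, adj_p_threshold, fold_change_threshold,
    )
    return out
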