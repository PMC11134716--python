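"""Training, application and cross-platform transfer of the SAHR score.

SAHR (Score of Aggregated Hazard Ratio) summarizes a tumor's malignancy
as ``score = sum_i delta_i * HR_i`` over a trained gene panel: each panel
gene contributes its (worse-vs-better oriented) hazard ratio, signed by
whether the sample sits on the risky side of the gene's expression cutoff.
The coefficient table:

    oncogene_like:         expression > cutoff -> +1, else -1
    down_regulated_saver:  expression > cutoff -> +1, else -1
    up_regulated_saver:    expression > cutoff -> -1, else +1
    suppressor_like:       expression > cutoff -> -1, else +1

Panels take the 20 / 20 / 10 / 10 smallest-p genes of the oncogene-like,
suppressor-like, up-regulated-saver and down-regulated-saver categories
(hazard ratios above 20 are discarded first, freeing their slots).
Samples with score > 0 form the SAHR-positive (higher-malignancy) group.

Transfer to another expression platform intersects the panel with the
target's genes, re-anchors every cutoff at the target cohort's median and
freezes the training hazard ratios; because medians and threshold
comparisons are rank-based, scores are invariant under any strictly
monotone per-gene transformation of the target data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog import DEFAULT_ALPHA, DEFAULT_ZERO_FRACTION, screen_gene
from .io import (
    CATEGORIES,
    DEFAULT_LIMITS,
    HR_MAX,
    SAHREntry,
    SAHRModel,
    ValidationError,
)

logger = logging.getLogger("sahr")

#: categories whose risky state is expression above the cutoff
_PLUS_WHEN_HIGH = ("oncogene_like", "down_regulated_saver")


@dataclass(frozen=True)
class SAHRScore:
    """One sample's score: sum of per-gene signed hazard ratios."""

    sample_id: str
    score: float
    group: str                  # positive / negative
    deltas: tuple[int, ...]     # +-1 per model entry, in model order


def train_sahr(
    catalog: pd.DataFrame,
    limits: dict | tuple = None,
    hr_cap: float = HR_MAX,
    cancer_type_label: str = "synthetic",
    provenance: dict | None = None,
) -> SAHRModel:
    """Select the per-category top genes of a catalog into a frozen panel.

    Per category: drop flagged or above-cap hazard ratios, sort by Cox p
    ascending (ties broken by larger HR, then gene id), keep up to the
    category limit.  A category with fewer survivors than its limit
    contributes what it has; the panel may hold fewer than 60 genes.
    """
    if limits is None:
        limits = dict(DEFAULT_LIMITS)
    elif not isinstance(limits, dict):
        limits = dict(zip(CATEGORIES, limits))
    if len(catalog) == 0:
        raise ValidationError("train_sahr: empty catalog")
    entries: list[SAHREntry] = []
    for cat in CATEGORIES:
        sub = catalog[
            (catalog["category"] == cat)
            & ~catalog["flagged"].astype(bool)
            & (catalog["hr"] <= hr_cap)
        ].copy()
        sub = sub.sort_values(
            ["cox_p", "hr", "gene_id"], ascending=[True, False, True], kind="stable"
        )
        kept = sub.head(limits[cat])
        if len(kept) < limits[cat]:
            logger.warning(
                "train_sahr: only %d/%d %s genes available", len(kept), limits[cat], cat
            )
        for row in kept.itertuples():
            entries.append(SAHREntry(row.gene_id, cat, float(row.cutoff), float(row.hr)))
    prov = dict(provenance or {})
    prov.setdefault("n_entries", len(entries))
    prov.setdefault("hr_cap", hr_cap)
    return SAHRModel(cancer_type_label=cancer_type_label, entries=entries, provenance=prov)


def assign_delta(value: float, entry: SAHREntry) -> int:
    """The +-1 coefficient of one gene for one sample (cutoff ties -> 'lower')."""
    high = value > entry.cutoff
    if entry.category in _PLUS_WHEN_HIGH:
        return 1 if high else -1
    return -1 if high else 1


def score_sample(values: pd.Series, model: SAHRModel, sample_id: str = "") -> SAHRScore:
    """SAHR score of one sample; every model gene must be present.

    A missing gene is an error directing the caller to
    :func:`transfer_model`, which handles platform gene intersections.
    """
    if len(model) == 0:
        raise ValidationError("cannot score with an empty model")
    missing = [e.gene_id for e in model.entries if e.gene_id not in values.index]
    if missing:
        raise ValidationError(
            f"model genes absent from sample: {missing[:5]}...; "
            "use transfer_model to adapt the panel to this platform"
        )
    deltas = tuple(assign_delta(float(values[e.gene_id]), e) for e in model.entries)
    score = float(sum(d * e.hr for d, e in zip(deltas, model.entries)))
    return SAHRScore(
        sample_id=sample_id, score=score,
        group="positive" if score > 0 else "negative", deltas=deltas,
    )


def score_matrix(normalized: pd.DataFrame, model: SAHRModel) -> pd.DataFrame:
    """Score every sample of a genes x samples normalized matrix.

    Returns a frame indexed by sample id with columns ``score`` and
    ``group`` (positive iff score > 0; exact zeros are negative).
    """
    if len(model) == 0:
        raise ValidationError("cannot score with an empty model")
    missing = [g for g in model.gene_ids if g not in normalized.index]
    if missing:
        raise ValidationError(
            f"model genes absent from matrix: {missing[:5]}...; "
            "use transfer_model to adapt the panel to this platform"
        )
    values = normalized.loc[model.gene_ids].to_numpy(dtype=float)  # entries x samples
    cutoffs = np.array([e.cutoff for e in model.entries])[:, None]
    plus_high = np.array([e.category in _PLUS_WHEN_HIGH for e in model.entries])[:, None]
    high = values > cutoffs
    deltas = np.where(high == plus_high, 1.0, -1.0)
    hrs = np.array([e.hr for e in model.entries])
    scores = deltas.T @ hrs
    return pd.DataFrame(
        {"score": scores, "group": np.where(scores > 0, "positive", "negative")},
        index=normalized.columns.rename("sample_id"),
    )


def transfer_model(model: SAHRModel, target_normalized: pd.DataFrame) -> SAHRModel:
    """Re-anchor a trained panel on a new cohort/platform.

    Keeps the genes shared with the target matrix (genes x tumor samples),
    replaces each cutoff with the target cohort's median expression of the
    gene and freezes the training hazard ratios and categories.  Pass
    tumors only: normals would shift the re-anchored medians.
    """
    shared = [e for e in model.entries if e.gene_id in target_normalized.index]
    if not shared:
        raise ValidationError("no model gene is present in the target matrix")
    if len(shared) < 0.5 * len(model):
        logger.warning(
            "transfer_model: only %d/%d model genes on the target platform",
            len(shared), len(model),
        )
    entries = [
        SAHREntry(
            e.gene_id, e.category,
            float(np.median(target_normalized.loc[e.gene_id].to_numpy(dtype=float))),
            e.hr,
        )
        for e in shared
    ]
    prov = dict(model.provenance)
    prov["transferred_from"] = model.cancer_type_label
    prov["intersection_size"] = len(entries)
    prov["target_n_samples"] = target_normalized.shape[1]
    return SAHRModel(
        cancer_type_label=f"{model.cancer_type_label}:transferred",
        entries=entries, provenance=prov,
    )


def stratify(scores: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Split scored samples into SAHR-positive (> 0) and SAHR-negative groups."""
    if len(scores) == 0:
        raise ValidationError("stratify: no scores")
    positive = scores.index[scores["score"] > 0]
    negative = scores.index[scores["score"] <= 0]
    if len(positive) == 0 or len(negative) == 0:
        logger.warning(
            "stratify: degenerate split (%d positive / %d negative); "
            "survival comparison will be refused", len(positive), len(negative),
        )
    return positive, negative


class SAHRScorer(BaseEstimator):
    """Median-split prognosis screening + SAHR panel, as one estimator.

    ``fit`` takes training-tumor expression (samples x genes, normalized),
    their survival outcomes and the tumor-vs-normal DE direction of each
    candidate gene; it screens every directed gene (median split + Cox),
    categorizes it and freezes the top genes per category into a panel.
    ``decision_function`` returns SAHR scores, ``predict`` the +1/-1
    malignancy group.  ``transfer`` re-anchors the fitted panel on another
    cohort and returns a new fitted estimator.

    Parameters
    ----------
    limits : per-category panel sizes (oncogene_like, suppressor_like,
        up_regulated_saver, down_regulated_saver), default (20, 20, 10, 10).
    hr_cap : discard genes with oriented hazard ratio above this (default 20).
    alpha : Cox significance level for categorization (default 0.05).
    zero_fraction_threshold : zero fraction beyond which a gene is split
        at zero rather than the median (default 0.3).
    """

    def __init__(
        self,
        limits: tuple = (20, 20, 10, 10),
        hr_cap: float = HR_MAX,
        alpha: float = DEFAULT_ALPHA,
        zero_fraction_threshold: float = DEFAULT_ZERO_FRACTION,
        cancer_type_label: str = "synthetic",
    ):
        self.limits = limits
        self.hr_cap = hr_cap
        self.alpha = alpha
        self.zero_fraction_threshold = zero_fraction_threshold
        self.cancer_type_label = cancer_type_label

    def fit(self, X, y, directions=None):
        """Screen and select the panel.

        X : DataFrame (samples x genes), normalized training-tumor expression.
        y : (n, 2) array-like or DataFrame with survival time and event
            indicator (columns ``time`` / ``event`` when a DataFrame).
        directions : mapping or Series gene_id -> 'up'/'down' for candidate
            genes (genes absent from it are not screened).
        """
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a DataFrame with gene-id columns")
        if directions is None:
            raise ValidationError("fit requires tumor-vs-normal DE directions")
        times, events = _parse_survival(y, len(X))
        directions = pd.Series(dict(directions)) if not isinstance(directions, pd.Series) else directions
        records = []
        for gene_id, direction in directions.items():
            if direction not in ("up", "down") or gene_id not in X.columns:
                continue
            records.append(
                screen_gene(
                    X[gene_id].to_numpy(dtype=float), times, events, direction,
                    gene_id=str(gene_id), alpha=self.alpha,
                    zero_fraction_threshold=self.zero_fraction_threshold,
                )
            )
        if not records:
            raise ValidationError("no candidate gene could be screened")
        self.catalog_ = pd.DataFrame([r.__dict__ for r in records])
        self.model_ = train_sahr(
            self.catalog_, limits=self.limits, hr_cap=self.hr_cap,
            cancer_type_label=self.cancer_type_label,
            provenance={"n_training_samples": len(X)},
        )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def decision_function(self, X) -> np.ndarray:
        """SAHR score per sample (samples x genes input)."""
        self._check_fitted()
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a DataFrame with gene-id columns")
        return score_matrix(X.T, self.model_)["score"].to_numpy()

    def predict(self, X) -> np.ndarray:
        """+1 for the SAHR-positive (higher-malignancy) group, else -1."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    def transfer(self, X_target) -> "SAHRScorer":
        """New fitted estimator with cutoffs re-anchored on the target cohort."""
        self._check_fitted()
        if not isinstance(X_target, pd.DataFrame):
            raise ValidationError("X_target must be a DataFrame with gene-id columns")
        new = SAHRScorer(**self.get_params())
        new.model_ = transfer_model(self.model_, X_target.T)
        new.catalog_ = self.catalog_
        new.n_features_in_ = X_target.shape[1]
        new.feature_names_in_ = np.asarray(X_target.columns)
        return new

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise ValidationError("SAHRScorer is not fitted")


def _parse_survival(y, n: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        if not {"time", "event"} <= set(y.columns):
            raise ValidationError("survival frame needs 'time' and 'event' columns")
        times = y["time"].to_numpy(dtype=float)
        events = y["event"].to_numpy(dtype=int)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("y must be (n, 2): time and event")
        times, events = arr[:, 0], arr[:, 1].astype(int)
    if len(times) != n:
        raise ValidationError("survival data must align with X rows")
    return times, events
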