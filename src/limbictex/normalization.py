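"""Healthy-control z-normalization and PCA-based feature selection.

Feature tables are long-format pandas DataFrames with columns
``subject_id, group, timepoint, roi, feature, value`` ("FeatureTable").
Normalization is per (roi, feature) against the healthy-control (HC)
reference so that anatomical differences between ROIs do not leak into the
z-scores; selection pools HC subject × ROI observations into one matrix of
16 feature columns, yielding a single selected feature set that applies to
every ROI.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .glszm import FEATURE_NAMES

__all__ = [
    "HealthyReferenceScaler",
    "PCAFeatureSelector",
    "TABLE_COLUMNS",
    "select_representative_features",
]

logger = logging.getLogger(__name__)

#: Required columns of a long-format feature table.
TABLE_COLUMNS = ("subject_id", "group", "timepoint", "roi", "feature", "value")


def _check_table(table: pd.DataFrame, required=("subject_id", "roi", "feature", "value")):
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")


class HealthyReferenceScaler(TransformerMixin, BaseEstimator):
    """Z-transform feature values against per-(ROI, feature) HC statistics.

    ``fit`` computes the sample mean and sd (ddof=1) of each (roi, feature)
    over the reference rows; ``transform`` maps value ↦ (value − mean)/sd,
    applied identically at every timepoint. Pairs whose reference sd is
    zero carry no information and are dropped with a warning.

    Parameters
    ----------
    min_subjects : int, default 3
        Minimum number of reference subjects required per (roi, feature).

    Attributes
    ----------
    stats_ : DataFrame indexed by (roi, feature) with columns mean, sd, n.
    dropped_ : list of (roi, feature) pairs excluded for zero variance.
    """

    def __init__(self, min_subjects: int = 3):
        self.min_subjects = min_subjects

    def fit(self, table: pd.DataFrame, y=None):
        _check_table(table)
        grouped = table.groupby(["roi", "feature"])["value"]
        stats = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        n_sub = table.groupby(["roi", "feature"])["subject_id"].nunique()
        too_few = n_sub[n_sub < self.min_subjects]
        if len(too_few):
            raise ValueError(
                f"insufficient reference subjects (< {self.min_subjects}) for "
                f"{len(too_few)} (roi, feature) pairs, e.g. {too_few.index[0]}"
            )
        zero_sd = stats.index[stats["sd"] == 0].tolist()
        if zero_sd:
            logger.warning(
                "excluding %d zero-variance (roi, feature) pairs from reference: %s",
                len(zero_sd),
                zero_sd[:5],
            )
        self.dropped_ = zero_sd
        self.stats_ = stats.drop(index=zero_sd)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        _check_table(table)
        keys = pd.MultiIndex.from_frame(table[["roi", "feature"]])
        unknown = keys.difference(self.stats_.index)
        if len(unknown):
            raise KeyError(
                f"{len(unknown)} (roi, feature) pairs absent from the reference, "
                f"e.g. {tuple(unknown[0])}"
            )
        mean = self.stats_["mean"].reindex(keys).to_numpy()
        sd = self.stats_["sd"].reindex(keys).to_numpy()
        out = table.copy()
        out["value"] = (table["value"].to_numpy() - mean) / sd
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        _check_table(table)
        keys = pd.MultiIndex.from_frame(table[["roi", "feature"]])
        mean = self.stats_["mean"].reindex(keys).to_numpy()
        sd = self.stats_["sd"].reindex(keys).to_numpy()
        out = table.copy()
        out["value"] = table["value"].to_numpy() * sd + mean
        return out


def select_representative_features(
    components: np.ndarray, feature_names: list[str], k: int
) -> list[str]:
    """One feature per component: largest |loading|, skipping features
    already taken; exact ties break by position in ``feature_names``."""
    selected: list[str] = []
    for c in range(k):
        absload = np.abs(components[c])
        order = np.lexsort((np.arange(len(feature_names)), -absload))
        for idx in order:
            if feature_names[idx] not in selected:
                selected.append(feature_names[idx])
                break
    return selected


class PCAFeatureSelector(BaseEstimator):
    """Pick one representative feature per retained principal component.

    PCA runs on the observations × features matrix built by pivoting the
    (already z-scored) reference table — one row per subject × ROI in
    pooled mode, or per subject within each ROI in per-ROI mode. The
    smallest k components whose cumulative explained variance reaches
    ``var_threshold`` are retained, and for each retained component the
    feature with the largest absolute loading is selected; a feature
    already taken by an earlier component falls through to the next-largest
    loading, so the selected features are distinct. Sign ambiguity of the
    loadings is irrelevant (absolute values); exact ties break by the
    canonical feature order.

    Attributes
    ----------
    loadings_ : DataFrame (feature × component) of PCA loadings.
    explained_variance_ratio_ : ndarray, descending.
    n_components_ : int, retained component count.
    selected_features_ : list of str, one per retained component.
    """

    def __init__(self, var_threshold: float = 0.90, mode: str = "pooled"):
        self.var_threshold = var_threshold
        self.mode = mode

    def _pivot(self, table: pd.DataFrame) -> pd.DataFrame:
        index = ["subject_id", "roi"] if self.mode == "pooled" else ["subject_id"]
        wide = table.pivot_table(
            index=index, columns="feature", values="value", aggfunc="first"
        )
        if wide.isna().any().any():
            raise ValueError("feature table is incomplete: missing (row, feature) cells")
        canonical = [f for f in FEATURE_NAMES if f in wide.columns]
        extras = [f for f in wide.columns if f not in canonical]
        return wide[canonical + sorted(extras)]

    def fit(self, table: pd.DataFrame, y=None):
        if self.mode not in ("pooled", "per_roi"):
            raise ValueError(f"mode must be 'pooled' or 'per_roi', got {self.mode}")
        _check_table(table)
        if self.mode == "per_roi":
            self.per_roi_ = {
                roi: PCAFeatureSelector(self.var_threshold, mode="pooled").fit(sub)
                for roi, sub in table.groupby("roi")
            }
            # pooled summary still computed below for a global selected set
        wide = self._pivot(table)
        if wide.shape[1] < 2:
            raise ValueError("need at least 2 features for PCA selection")
        if wide.shape[0] < 3:
            raise ValueError("need at least 3 observation rows for PCA selection")
        X = wide.to_numpy()
        if np.allclose(X.std(axis=0), 0):
            raise ValueError("all-constant feature matrix: PCA is undefined")
        pca = PCA(svd_solver="full")
        pca.fit(X)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.var_threshold) + 1)
        k = min(k, len(ratios))
        self.explained_variance_ratio_ = ratios
        self.n_components_ = k
        self.loadings_ = pd.DataFrame(
            pca.components_.T,
            index=wide.columns,
            columns=[f"PC{c + 1}" for c in range(pca.components_.shape[0])],
        )
        self.selected_features_ = select_representative_features(
            pca.components_, list(wide.columns), k
        )
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Filter a long table down to the selected features."""
        _check_table(table)
        return table[table["feature"].isin(self.selected_features_)].copy()

    def report(self) -> pd.DataFrame:
        """Loadings of the retained components plus their variance ratios."""
        cols = [f"PC{c + 1}" for c in range(self.n_components_)]
        rep = self.loadings_[cols].copy()
        rep.loc["explained_variance_ratio"] = self.explained_variance_ratio_[
            : self.n_components_
        ]
        return rep
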