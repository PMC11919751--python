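"""Group×time interaction models, FDR correction, and repeated-measures correlation.

The central test asks whether change from baseline to follow-up differs
between the ECT and medication-only (MED) groups for each (ROI, outcome):
a linear mixed model with a subject random intercept,

    y_ist = β0 + β_g·group + β_t·time + δ·group·time + γ'·covariates + a_s + ε_ist,

with MED and baseline as reference levels, so δ is the ECT-specific change
difference. Inference on δ uses a Wald t with between–within denominator
degrees of freedom (df = n_obs − n_subjects − n_within_terms); with two
timepoints and balanced data this reproduces the two-sample t-test on
change scores exactly, which also serves as the non-convergence fallback.

Repeated-measures correlation (rmcorr) estimates the common within-subject
association between a texture feature and a clinical score via ANCOVA with
subject as a factor; with k = 2 visits its error df is N − 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InteractionResult",
    "RmcorrResult",
    "fit_interaction_model",
    "GroupTimeInteraction",
    "fdr_adjust",
    "rmcorr",
    "run_stats_stage",
]

logger = logging.getLogger(__name__)

PATIENT_GROUPS = ("ECT", "MED")  # MED is the reference level
TIMEPOINTS = ("baseline", "followup")
CLINICAL_VARS = ("panss_total", "panss_pos", "panss_neg", "panss_gen", "cgi_s")


@dataclass
class InteractionResult:
    """Group×time interaction test for one (ROI, outcome)."""

    roi: str
    outcome: str
    beta: float
    se: float
    statistic: float
    df: float
    p: float
    method: str = "mixed"  # "mixed" or "change_score_ols" (fallback)
    n_subjects: int = 0
    p_fdr: float | None = None


@dataclass
class RmcorrResult:
    """Common within-subject correlation between two paired variables."""

    r: float
    df: int
    p: float
    ci: tuple[float, float]
    n_subjects: int
    p_fdr: float | None = None


def _encode_sex(col: pd.Series) -> pd.Series:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        mapping = {"M": 1.0, "F": 0.0, "male": 1.0, "female": 0.0}
        out = col.map(mapping)
        if out.isna().any() and not col.isna().all():
            raise ValueError(f"cannot encode sex values {sorted(col.dropna().unique())}")
        return out
    return col.astype(float)


def _build_design(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.Series, pd.Series, int]:
    """Long table -> (exog DataFrame, endog, subject ids, n dropped rows)."""
    required = {"subject_id", "group", "timepoint", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    d = table.copy()
    bad_groups = set(d["group"]) - set(PATIENT_GROUPS)
    if bad_groups:
        raise ValueError(f"unexpected groups {sorted(bad_groups)}; expected {PATIENT_GROUPS}")
    if set(d["timepoint"]) != set(TIMEPOINTS):
        raise ValueError(f"need both timepoints {TIMEPOINTS}, got {sorted(set(d['timepoint']))}")
    if "sex" in covariates and "sex" in d.columns:
        d["sex"] = _encode_sex(d["sex"])
    cols = ["value"] + list(covariates)
    n0 = len(d)
    d = d.dropna(subset=[c for c in cols if c in d.columns])
    n_dropped = n0 - len(d)
    if n_dropped:
        logger.info("listwise deletion removed %d rows with missing data", n_dropped)

    grp = (d["group"] == "ECT").astype(float)
    tim = (d["timepoint"] == "followup").astype(float)
    exog = pd.DataFrame(
        {
            "intercept": np.ones(len(d)),
            "group": grp.to_numpy(),
            "time": tim.to_numpy(),
            "group_x_time": (grp * tim).to_numpy(),
        },
        index=d.index,
    )
    for c in covariates:
        if c not in d.columns:
            raise ValueError(f"covariate column '{c}' missing from table")
        exog[c] = d[c].astype(float).to_numpy()
    for c in exog.columns[1:]:
        if np.ptp(exog[c].to_numpy()) == 0:
            raise ValueError(f"rank-deficient design: column '{c}' is constant")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("rank-deficient design: collinear columns")
    return exog, d["value"].astype(float), d["subject_id"], n_dropped


def _change_score_ols(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[float, float, float, float, float, int]:
    """OLS of within-subject change on group + covariates (fallback path)."""
    d = table.copy()
    if "sex" in covariates and "sex" in d.columns:
        d["sex"] = _encode_sex(d["sex"])
    wide = d.pivot_table(index="subject_id", columns="timepoint", values="value", aggfunc="first")
    delta = (wide["followup"] - wide["baseline"]).dropna()
    sub = d.drop_duplicates("subject_id").set_index("subject_id").loc[delta.index]
    X = pd.DataFrame({"intercept": 1.0, "group": (sub["group"] == "ECT").astype(float)})
    for c in covariates:
        X[c] = sub[c].astype(float).to_numpy()
    keep = X.notna().all(axis=1) & delta.notna()
    X, delta = X[keep], delta[keep]
    res = sm.OLS(delta.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("group")
    beta, se = res.params[j], res.bse[j]
    t = beta / se
    df = res.df_resid
    p = 2 * sps.t.sf(abs(t), df)
    return float(beta), float(se), float(t), float(df), float(p), len(delta)


def fit_interaction_model(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "oz_dose"),
    roi: str = "",
    outcome: str = "value",
    method: str = "mixed",
) -> InteractionResult:
    """Fit the group×time mixed model for one (ROI, outcome).

    Parameters
    ----------
    table : DataFrame
        Long format with subject_id, group ∈ {ECT, MED}, timepoint ∈
        {baseline, followup}, value, and the covariate columns.
    covariates : tuple of str
        Between-subject covariate columns entered as fixed effects.
    method : {"mixed", "change_score"}
        Primary path is a REML linear mixed model with subject random
        intercept; "change_score" forces the OLS-on-change fallback.

    Returns
    -------
    InteractionResult with the group×time coefficient, Wald t, df and p.
    """
    exog, endog, subjects, _ = _build_design(table, covariates)
    n_sub = subjects.nunique()
    counts = table.groupby("group")["subject_id"].nunique()
    if (counts.reindex(PATIENT_GROUPS).fillna(0) < 4).any():
        raise ValueError(f"need >= 4 subjects per group, got {counts.to_dict()}")

    if method == "change_score":
        beta, se, t, df, p, n = _change_score_ols(table, covariates)
        return InteractionResult(roi, outcome, beta, se, t, df, p, "change_score_ols", n)
    if method != "mixed":
        raise ValueError(f"unknown method {method!r}")

    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog.to_numpy(), exog, groups=subjects.to_numpy())
            # Powell polishes the REML optimum far enough that the balanced
            # 2-timepoint fit matches the change-score t-test to ~1e-8
            res = model.fit(reml=True, method="powell", maxiter=2000)
        if not res.converged or not np.isfinite(res.bse["group_x_time"]):
            fallback = True
    except (np.linalg.LinAlgError, ValueError):
        fallback = True

    if fallback:
        logger.warning("mixed model did not converge; falling back to change-score OLS")
        beta, se, t, df, p, n = _change_score_ols(table, covariates)
        return InteractionResult(roi, outcome, beta, se, t, df, p, "change_score_ols", n)

    beta = float(res.params["group_x_time"])
    se = float(res.bse["group_x_time"])
    t = beta / se
    # between-within df: within-subject terms are time and group×time
    df = len(endog) - n_sub - 2
    p = 2 * sps.t.sf(abs(t), df)
    return InteractionResult(roi, outcome, beta, se, float(t), float(df), float(p), "mixed", n_sub)


class GroupTimeInteraction(BaseEstimator):
    """Estimator running the group×time interaction test per (ROI, outcome).

    Parameters
    ----------
    covariates : tuple of str, default ("age", "sex", "oz_dose")
    method : {"mixed", "change_score"}, default "mixed"
    fdr : bool, default True
        Benjamini–Hochberg adjust the p-values as one family.

    Attributes
    ----------
    results_ : DataFrame, one row per (roi, feature) with beta, se,
        statistic, df, p and p_fdr.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = ("age", "sex", "oz_dose"),
        method: str = "mixed",
        fdr: bool = True,
    ):
        self.covariates = covariates
        self.method = method
        self.fdr = fdr

    def fit(self, table: pd.DataFrame, y=None):
        rows = []
        for (roi_name, feat), sub in table.groupby(["roi", "feature"]):
            r = fit_interaction_model(
                sub, covariates=tuple(self.covariates), roi=roi_name,
                outcome=feat, method=self.method,
            )
            rows.append(r)
        res = pd.DataFrame([vars(r) for r in rows]).drop(columns="p_fdr")
        if self.fdr and len(res):
            res["p_fdr"] = fdr_adjust(res["p"].tolist())
        self.results_ = res
        return self


def fdr_adjust(pvals, family: str = "") -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"p-values outside [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1].tolist()


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation of paired (x, y) across subjects.

    Estimates the common within-subject correlation via ANCOVA of y on x
    with subject as a factor (r takes the sign of the shared within-subject
    slope). Requires ≥ 3 subjects with exactly 2 visits each; df = N − 1.
    The confidence interval uses the Fisher z transform with that df.
    """
    d = pd.DataFrame({"subject": list(subjects), "x": list(x), "y": list(y)}).dropna()
    counts = d.groupby("subject").size()
    if (counts != 2).any():
        raise ValueError("every subject must contribute exactly 2 (x, y) pairs")
    n_sub = len(counts)
    if n_sub < 3:
        raise ValueError(f"need >= 3 subjects, got {n_sub}")
    dx = d.groupby("subject")["x"].agg(lambda v: v.iloc[1] - v.iloc[0])
    if np.allclose(dx, 0):
        raise ValueError("all within-subject x-changes are zero: rmcorr undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.rm_corr(data=d, x="x", y="y", subject="subject")
    r = float(res["r"].iloc[0])
    df = int(res["dof"].iloc[0])
    p = float(res["pval"].iloc[0])
    if abs(r) >= 1.0 or df <= 1:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        zse = 1.0 / np.sqrt(df - 1) if df > 1 else np.inf
        ci = tuple(np.tanh([z - 1.959963984540054 * zse, z + 1.959963984540054 * zse]))
    return RmcorrResult(r=r, df=df, p=p, ci=(float(ci[0]), float(ci[1])), n_subjects=n_sub)


def _paired_values(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Pivot a two-timepoint long table to one row per subject × timepoint pair."""
    return table.pivot_table(
        index="subject_id", columns="timepoint", values=value_col, aggfunc="first"
    )


def run_stats_stage(
    texture: pd.DataFrame,
    volumes: pd.DataFrame,
    clinical: pd.DataFrame,
    selected_features: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "oz_dose"),
    volume_covariates: tuple[str, ...] = ("age", "sex", "oz_dose", "etiv"),
    clinical_vars: tuple[str, ...] = CLINICAL_VARS,
    alpha: float = 0.05,
    method: str = "mixed",
) -> dict[str, pd.DataFrame]:
    """Run the full inferential stage.

    1. Group×time mixed models for ROI volume (one BH family across ROIs)
       and for each selected texture feature × ROI (one joint BH family).
    2. For every texture (ROI, feature) significant after FDR, rmcorr
       against each clinical variable, separately per patient group, with
       BH across the clinical variables within each (ROI, feature, group).

    Parameters
    ----------
    texture : long FeatureTable of HC-normalized texture values (patients).
    volumes : long FeatureTable with feature == "volume" (patients).
    clinical : DataFrame with subject_id, group, timepoint, covariates and
        clinical scores.
    selected_features : texture features to test (default: all present).

    Returns
    -------
    dict with DataFrames "volume", "texture", "rmcorr".
    """
    pats = clinical[clinical["group"].isin(PATIENT_GROUPS)]
    covar_cols = sorted(set(covariates) | set(volume_covariates) - {"etiv"} | {"etiv"})
    covar_cols = [c for c in covar_cols if c in pats.columns]
    subject_info = pats.drop_duplicates("subject_id")[["subject_id", "group"] + covar_cols]

    def _with_covars(tbl: pd.DataFrame) -> pd.DataFrame:
        return tbl.drop(columns=[c for c in ("group",) + tuple(covar_cols) if c in tbl.columns]).merge(
            subject_info, on="subject_id", how="inner"
        )

    vol_cov = tuple(c for c in volume_covariates if c in subject_info.columns)
    if set(volume_covariates) - set(vol_cov):
        logger.warning("volume covariates missing from clinical table: %s",
                       sorted(set(volume_covariates) - set(vol_cov)))
    vol_model = GroupTimeInteraction(covariates=vol_cov, method=method, fdr=True)
    vol_model.fit(_with_covars(volumes[volumes["group"].isin(PATIENT_GROUPS)]))
    vol_res = vol_model.results_

    tex = texture[texture["group"].isin(PATIENT_GROUPS)]
    if selected_features is not None:
        tex = tex[tex["feature"].isin(selected_features)]
    tex_model = GroupTimeInteraction(covariates=tuple(covariates), method=method, fdr=True)
    tex_model.fit(_with_covars(tex))
    tex_res = tex_model.results_

    rm_rows = []
    sig = tex_res[tex_res["p_fdr"] < alpha]
    for _, hit in sig.iterrows():
        pair = tex[(tex["roi"] == hit["roi"]) & (tex["feature"] == hit["outcome"])]
        for grp in PATIENT_GROUPS:
            grp_subjects = subject_info.loc[subject_info["group"] == grp, "subject_id"]
            x_wide = _paired_values(pair[pair["subject_id"].isin(grp_subjects)])
            pvals, partial = [], []
            for cv in clinical_vars:
                if cv not in clinical.columns:
                    continue
                y_wide = _paired_values(pats[pats["subject_id"].isin(grp_subjects)], cv)
                common = x_wide.dropna().index.intersection(y_wide.dropna().index)
                subj = np.repeat(common.to_numpy(), 2)
                xv = x_wide.loc[common, ["baseline", "followup"]].to_numpy().ravel()
                yv = y_wide.loc[common, ["baseline", "followup"]].to_numpy().ravel()
                try:
                    rr = rmcorr(subj, xv, yv)
                except ValueError as exc:
                    logger.warning("rmcorr skipped for %s/%s/%s/%s: %s",
                                   hit["roi"], hit["outcome"], grp, cv, exc)
                    continue
                partial.append({
                    "roi": hit["roi"], "feature": hit["outcome"], "group": grp,
                    "clinical_var": cv, "r": rr.r, "df": rr.df, "p": rr.p,
                    "ci_low": rr.ci[0], "ci_high": rr.ci[1], "n_subjects": rr.n_subjects,
                })
                pvals.append(rr.p)
            if partial:
                for row, padj in zip(partial, fdr_adjust(pvals)):
                    row["p_fdr"] = padj
                    rm_rows.append(row)

    rm_res = pd.DataFrame(
        rm_rows,
        columns=["roi", "feature", "group", "clinical_var", "r", "df", "p",
                 "ci_low", "ci_high", "n_subjects", "p_fdr"],
    )
    return {"volume": vol_res, "texture": tex_res, "rmcorr": rm_res}
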