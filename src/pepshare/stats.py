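"""Differential abundance testing on protein-level summaries.

Each protein's summaries are modeled with a fixed-effects linear model

    Y_gbm = mu + Condition_g + Mixture_m + eps,      (group comparison)
    Y_ctm = mu + ConditionTime_ct + Mixture_m + eps  (condition-time)

where the mixture term is included only for multi-mixture designs. Mixture
is modeled as a fixed additive (blocking) effect rather than a random
intercept; in balanced designs this leaves the contrast estimates unchanged
and avoids variance-component estimation. Contrasts of condition means are
tested with two-sided t-tests on the residual degrees of freedom, and
p-values are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["protein", "contrast", "log2fc", "se", "df", "p_value", "adj_p_value"]


@dataclass
class ProteinModelFit:
    """OLS fit of one protein's summaries against the design."""

    protein: str
    conditions: list[str]
    condition_means: np.ndarray
    cov: np.ndarray  # covariance of the condition-mean estimates
    df: float
    sigma2: float
    n_obs: int


def fit_protein_model(
    summaries: pd.DataFrame, design_kind: str = "group"
) -> ProteinModelFit:
    """Fit the per-protein linear model.

    ``summaries`` holds one protein's rows with columns condition, mixture
    (optional), bio_replicate and summary. For ``design_kind='condition-time'``
    the condition column is expected to already encode the condition x time
    cell (one label per cell); the model is the same cell-means layout.
    """
    df_in = summaries.dropna(subset=["summary"])
    conditions = sorted(df_in["condition"].astype(str).unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions with data for testing")
    y = df_in["summary"].to_numpy(float)
    cond = pd.Categorical(df_in["condition"].astype(str), categories=conditions)
    X = pd.get_dummies(cond).to_numpy(float)  # cell means, no intercept
    G = len(conditions)
    if "mixture" in df_in.columns and df_in["mixture"].astype(str).nunique() > 1:
        mix = pd.get_dummies(df_in["mixture"].astype(str), drop_first=True)
        X = np.column_stack([X, mix.to_numpy(float)])
    fit = sm.OLS(y, X).fit()
    protein = str(df_in["protein"].iloc[0]) if "protein" in df_in.columns else ""
    cov = np.asarray(fit.cov_params())[:G, :G]
    return ProteinModelFit(
        protein=protein,
        conditions=conditions,
        condition_means=np.asarray(fit.params)[:G],
        cov=cov,
        df=float(fit.df_resid),
        sigma2=float(fit.mse_resid) if fit.df_resid > 0 else 0.0,
        n_obs=len(y),
    )


def test_contrast(
    fit: ProteinModelFit, contrast: dict[str, float] | pd.Series, name: str | None = None
) -> dict | None:
    """Two-sided t-test of a sum-to-zero contrast of condition means.

    Returns a result record, or ``None`` when the contrast involves a
    condition with no data (not estimable). A zero standard error is flagged
    as degenerate: p = 0 for a nonzero estimate and p = 1 otherwise.
    """
    contrast = dict(contrast)
    coefs = {c: v for c, v in contrast.items() if v != 0}
    if abs(sum(coefs.values())) > 1e-10:
        raise ValueError("contrast coefficients must sum to zero")
    if any(c not in fit.conditions for c in coefs):
        missing = sorted(set(coefs) - set(fit.conditions))
        logger.info("contrast not estimable for %s: no data in %s", fit.protein, missing)
        return None
    L = np.array([coefs.get(c, 0.0) for c in fit.conditions])
    est = float(L @ fit.condition_means)
    se = float(np.sqrt(L @ fit.cov @ L))
    label = name if name is not None else _contrast_label(coefs)
    if se < 1e-12 or fit.df <= 0:
        logger.warning("degenerate contrast (se=0 or df=0) for %s / %s", fit.protein, label)
        if abs(est) < 1e-12:  # exactly null data up to float noise
            est, p = 0.0, 1.0
        else:
            p = 0.0
    else:
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), fit.df))
    return {
        "protein": fit.protein,
        "contrast": label,
        "log2fc": est,
        "se": se,
        "df": fit.df,
        "p_value": p,
    }


def _contrast_label(coefs: dict[str, float]) -> str:
    pos = sorted(c for c, v in coefs.items() if v > 0)
    neg = sorted(c for c, v in coefs.items() if v < 0)
    return "+".join(pos) + " vs " + "+".join(neg)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all_contrasts(
    summaries: pd.DataFrame,
    contrasts: pd.DataFrame,
    design_kind: str = "group",
) -> pd.DataFrame:
    """Fit every protein and test every contrast; BH-adjust across all rows.

    ``contrasts`` has one row per contrast (index = contrast name) and one
    column per condition, each row summing to zero. Non-estimable contrasts
    are absent from the output rather than reported as NaN.
    """
    rows: list[dict] = []
    for protein, sub in summaries.groupby("protein", sort=True):
        try:
            fit = fit_protein_model(sub.assign(protein=protein), design_kind)
        except ValueError:
            continue
        for cname, row in contrasts.iterrows():
            res = test_contrast(fit, row.to_dict(), name=str(cname))
            if res is not None:
                rows.append(res)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if not out.empty:
        out["adj_p_value"] = adjust_fdr(out["p_value"].to_numpy())
    else:
        out["adj_p_value"] = []
    return out


def compare_summarization_methods(
    features: pd.DataFrame,
    contrasts: pd.DataFrame,
    config=None,
    keep_subset: bool = False,
    design_kind: str = "group",
    methods: tuple[str, ...] = ("weighted", "unique", "all"),
) -> pd.DataFrame:
    """Side-by-side differential results for the three summarization methods.

    All methods share identical downstream modeling; rows are stacked with a
    ``method`` column. Proteins a method cannot summarize (e.g. no unique
    peptides for the unique-only method) are simply absent for that method.
    """
    from .core import summarize_features

    frames = []
    for method in methods:
        summaries, _, _ = summarize_features(
            features, config=config, method=method, keep_subset=keep_subset
        )
        res = test_all_contrasts(summaries, contrasts, design_kind)
        res["method"] = method
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
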