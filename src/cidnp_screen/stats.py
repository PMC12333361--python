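"""Statistical layer: coarse-graining, trend fits, PCA, ANOVA/Tukey.

Features live at three natural hierarchy levels — family (logP), molecule
(IP, N, LUMO-HOMO gap, delta_g) and individual proton (a_iso, f-, Q) — so
trends against SNE are examined at a matching coarse-graining: all sites,
the max-SNE site per molecule, or the max-SNE site per (family, series)
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .records import FEATURE_COLUMNS, FeatureTable

LEVELS = ("site", "molecule", "family")


def coarse_grain(table: FeatureTable, level: str) -> FeatureTable:
    """Reduce the table to one representative (max-SNE) row per group.

    ``site`` is the identity; ``molecule`` keeps each molecule's max-SNE
    site; ``family`` keeps the max-SNE row of each (family, series) group.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    df = table.frame
    if level == "site":
        return table.copy()
    keys = ["molecule_id"] if level == "molecule" else ["family", "series"]
    idx = df.groupby(keys, sort=True)["sne"].idxmax()
    return FeatureTable(df.loc[idx].reset_index(drop=True), dict(table.metadata))


@dataclass
class TrendFit:
    """An OLS trend of SNE on one feature, linear or quadratic."""

    predictor: str
    response: str
    form: str  # "linear" | "quadratic"
    coefficients: dict[str, float]
    p_value: float  # overall F-test of the fitted terms
    r_squared: float
    level: str
    n: int


def trend_fit(
    table: FeatureTable,
    predictor: str,
    response: str = "sne",
    form: str = "linear",
    level: str = "site",
) -> TrendFit:
    """Ordinary least squares of ``response`` on ``predictor`` (plus its
    square for the quadratic form), at the requested coarse-graining.

    The quadratic form is the natural model for electron-transfer-related
    features (IP, N, LUMO-HOMO), whose rate dependence is parabolic in the
    Marcus picture; the p-value is the overall F-test of the fitted terms.
    """
    if form not in ("linear", "quadratic"):
        raise ValueError(f"form must be 'linear' or 'quadratic', got {form!r}")
    sub = coarse_grain(table, level).frame
    x = sub[predictor].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    k = 1 if form == "linear" else 2
    if len(x) < k + 3:
        raise ValueError(f"need at least {k + 3} rows for a {form} fit, have {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")

    cols = {predictor: x}
    if form == "quadratic":
        cols[f"{predictor}^2"] = x**2
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(y, X).fit()
    p = float(fit.f_pvalue)
    return TrendFit(
        predictor=predictor,
        response=response,
        form=form,
        coefficients={name: float(v) for name, v in fit.params.items()},
        p_value=max(p, np.finfo(float).tiny),  # keep within (0, 1]
        r_squared=float(fit.rsquared),
        level=level,
        n=len(x),
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # per-site coordinates, PC1..PCk
    loadings: pd.DataFrame  # feature x PC matrix
    explained_variance_ratio: np.ndarray  # all PCs, sums to 1
    cumulative: np.ndarray
    dropped_features: list[str]


def run_pca(
    table: FeatureTable, n_components: int = 3, standardize: bool = True
) -> PCAResult:
    """PCA of the 8-feature matrix across sites.

    Features are z-scored first by default (they span incomparable units:
    eV, MHz, dimensionless indices), making this a correlation-matrix PCA.
    Zero-variance columns cannot be z-scored and are dropped with a
    warning. ``explained_variance_ratio`` covers *all* principal
    components (so it sums to 1); scores and loadings are truncated to
    ``n_components``.
    """
    X = table.features().to_numpy(dtype=float)
    names = list(FEATURE_COLUMNS)
    if n_components > X.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds {X.shape[1]} features")
    if len(X) < n_components + 1:
        raise ValueError("not enough rows for the requested number of components")

    dropped: list[str] = []
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping zero-variance feature column(s): {dropped}")
            X, names = X[:, keep], [n for n, k in zip(names, keep) if k]
            sd = sd[keep]
        X = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=None, svd_solver="full").fit(X)
    ratio = pca.explained_variance_ratio_
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(pca.transform(X)[:, :n_components], columns=pcs)
    scores.insert(0, "molecule_id", table.frame["molecule_id"].to_numpy())
    scores.insert(1, "site_id", table.frame["site_id"].to_numpy())
    loadings = pd.DataFrame(pca.components_[:n_components].T, index=names, columns=pcs)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio,
        cumulative=np.cumsum(ratio),
        dropped_features=dropped,
    )


def anova_tukey(
    table: FeatureTable, grouping: str, response: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    The default design elsewhere in the pipeline groups sites by SNE class
    (low/medium/high) and asks whether a feature differs between classes.
    Returns ``(anova_table, pairwise_table)``; Tukey p-values are
    family-wise adjusted.
    """
    df = table.frame
    for col in (grouping, response):
        if col not in df.columns:
            raise KeyError(f"unknown column {col!r}")
    groups = {name: grp[response].to_numpy(dtype=float) for name, grp in df.groupby(grouping)}
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups in {grouping!r}, have {len(groups)}")
    singletons = [name for name, vals in groups.items() if len(vals) < 2]
    if singletons:
        raise ValueError(f"group(s) with fewer than 2 rows in {grouping!r}: {singletons}")

    f_stat, p = sps.f_oneway(*groups.values())
    k, n = len(groups), len(df)
    anova_table = pd.DataFrame(
        {
            "source": ["between", "within"],
            "df": [k - 1, n - k],
            "F": [float(f_stat), np.nan],
            "p_value": [float(p), np.nan],
        }
    )
    tukey = pairwise_tukeyhsd(
        df[response].to_numpy(dtype=float), df[grouping].astype(str).to_numpy()
    )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    return anova_table, pairwise
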