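"""Within-molecule site ranking and argmax concordance.

The headline qualitative question: how often does the site with the
largest value of a predictor (typically the nucleophilic Fukui index)
coincide with the site showing the largest absolute SNE within the same
molecule? Absolute SNE is used throughout, so emissive vs absorptive
phase plays no role here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import FeatureTable


@dataclass
class MoleculeDetail:
    molecule_id: str
    predicted_site: str
    true_site: str
    hit: bool
    tie: bool


@dataclass
class HitRateResult:
    """Argmax concordance of one predictor over the library."""

    predictor: str
    hits: int
    n_molecules: int
    rate: float
    binomial_ci95: tuple[float, float]
    per_molecule_detail: list[MoleculeDetail] = field(default_factory=list)

    def detail_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (d.molecule_id, d.predicted_site, d.true_site, d.hit, d.tie)
                for d in self.per_molecule_detail
            ],
            columns=["molecule_id", "predicted_site", "true_site", "hit", "tie"],
        )


def clopper_pearson(hits: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval on hits/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    low = 0.0 if hits == 0 else float(stats.beta.ppf(alpha / 2, hits, n - hits + 1))
    high = 1.0 if hits == n else float(stats.beta.ppf(1 - alpha / 2, hits + 1, n - hits))
    return (low, high)


def rank_sites(
    molecule_rows: pd.DataFrame, feature: str, descending: bool = True
) -> tuple[list[str], bool]:
    """Order a molecule's site_ids by a feature column.

    Stable sort; exact ties are broken by lexicographic site_id and the
    returned flag marks that ties occurred.
    """
    if feature not in molecule_rows.columns:
        raise KeyError(f"unknown feature column {feature!r}")
    if len(molecule_rows) == 0:
        raise ValueError("molecule has no sites")
    sub = molecule_rows[["site_id", feature]].copy()
    tie = bool(sub[feature].duplicated().any())
    sub = sub.sort_values(
        [feature, "site_id"], ascending=[not descending, True], kind="mergesort"
    )
    return list(sub["site_id"]), tie


def argmax_hit_rate(table: FeatureTable, predictor: str = "fukui") -> HitRateResult:
    """Per molecule, does argmax(predictor) hit the max-SNE site?

    A tie in either argmax makes the molecule a flagged non-hit — the
    conservative choice, since a genuinely predictive index should single
    out one site. The rate carries an exact Clopper-Pearson 95% CI.
    """
    df = table.frame
    if len(df) == 0:
        raise ValueError("empty feature table")
    if predictor not in df.columns:
        raise KeyError(f"unknown predictor column {predictor!r}")

    details: list[MoleculeDetail] = []
    hits = 0
    for mol, grp in df.groupby("molecule_id", sort=True):
        pred = grp[predictor].to_numpy(dtype=float)
        sne = grp["sne"].to_numpy(dtype=float)
        if not (np.isfinite(pred).all() and np.isfinite(sne).all()):
            raise ValueError(f"{mol}: non-finite predictor or SNE values")
        sites = grp["site_id"].to_numpy()
        p_max, s_max = pred.max(), sne.max()
        tie = (pred == p_max).sum() > 1 or (sne == s_max).sum() > 1
        predicted_site = str(sites[int(np.argmax(pred))])
        true_site = str(sites[int(np.argmax(sne))])
        hit = (not tie) and predicted_site == true_site
        hits += hit
        details.append(MoleculeDetail(str(mol), predicted_site, true_site, hit, tie))

    n = len(details)
    return HitRateResult(
        predictor=predictor,
        hits=hits,
        n_molecules=n,
        rate=hits / n,
        binomial_ci95=clopper_pearson(hits, n),
        per_molecule_detail=details,
    )


def compare_predictors(
    table: FeatureTable, predictors: list[str]
) -> list[HitRateResult]:
    """Hit rates for several candidate site predictors, best first.

    Typical comparison: the Fukui index against raw hyperfine couplings,
    Hirshfeld charges or spin densities.
    """
    results = [argmax_hit_rate(table, p) for p in predictors]
    results.sort(key=lambda r: r.rate, reverse=True)
    return results


def summary_frame(results: list[HitRateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.predictor, r.hits, r.n_molecules, r.rate, r.binomial_ci95[0], r.binomial_ci95[1])
            for r in results
        ],
        columns=["predictor", "hits", "n_molecules", "rate", "ci95_low", "ci95_high"],
    )
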