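"""Cross-estimator analytics for a panel of inbreeding coefficients.

A panel holds one column per inbreeding coefficient (pedigree-based,
GRM-based, uniting-gametes, excess-homozygosity, the three ROH variants
and the HBD-based one) plus the birth year.  The module provides the
summary statistics, pairwise correlations, the regression of a genomic
coefficient on the pedigree coefficient, a PCA of the standardized
coefficient matrix and per-birth-year trend tables.

Animals with any missing coefficient are dropped (listwise) before
pairwise statistics, which keeps the correlation matrix positive
semidefinite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .depression_lmm import DepressionFit, LMMSpec, gibbs_lmm, TEST_MCMC
from .pedigree_kinship import mean_f_by_cohort

#: panel column order (birth_year excluded)
COEFFICIENTS = [
    "F_PED", "F_GRM", "F_UNI", "F_HOM", "F_ROH", "F_ROH_30", "F_ROH_15", "F_HBD",
]


def build_panel(columns: dict[str, pd.Series], birth_years: pd.Series | None = None) -> pd.DataFrame:
    """Assemble a coefficient panel from per-animal Series (outer-joined on id)."""
    df = pd.DataFrame(columns)
    if birth_years is not None:
        df["birth_year"] = birth_years.reindex(df.index)
    return df


def _coef_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in panel.columns if c != "birth_year"]


def summarize(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-coefficient min, max, mean, median and sample SD (n-1)."""
    cols = _coef_columns(panel)
    if len(panel) < 2:
        raise ValueError("need at least 2 animals")
    rows = []
    for c in cols:
        v = panel[c].dropna()
        rows.append((c, v.min(), v.max(), v.mean(), v.median(), v.std(ddof=1)))
    return pd.DataFrame(rows, columns=["coefficient", "min", "max", "mean", "median", "sd"])


def pairwise_correlations(
    panel: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix and two-sided p-values (t transform) on complete rows.

    Constant columns yield NaN entries (flagged undefined) rather than an
    arbitrary value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    cols = _coef_columns(panel)
    data = panel[cols].dropna()
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 complete animals")
    vals = data.to_numpy(dtype=float)
    if method == "spearman":
        vals = stats.rankdata(vals, axis=0)
    const = np.ptp(vals, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(vals.T)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(~const, 1.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def regress_on_fped(
    panel: pd.DataFrame,
    coefficient: str,
    mcmc: tuple[int, int, int] = TEST_MCMC,
    seed: int = 0,
) -> DepressionFit:
    """Bayesian regression of a genomic coefficient on F_PED (no random
    effect): returns slope/intercept posterior means and PSDs.

    The slope is reported under the covariate name, the intercept among the
    fixed effects.
    """
    data = panel[["F_PED", coefficient]].dropna()
    if data["F_PED"].std() == 0:
        raise ValueError("F_PED is constant; regression undefined")
    spec = LMMSpec(
        y=data[coefficient].to_numpy(),
        X=np.ones((len(data), 1)),
        F=data[["F_PED"]].to_numpy(),
        animal_ids=[str(i) for i in data.index],
        fixed_names=["intercept"],
        f_names=["F_PED"],
        trait=coefficient,
    )
    return gibbs_lmm(spec, kinship=None, mcmc=mcmc, seed=seed)


def pca_inbreeding(panel: pd.DataFrame):
    """PCA of the standardized (unit-variance) coefficient matrix.

    Returns (loadings, scores, explained_fractions).  Loadings are
    orthonormal columns, sign-fixed so each vector's largest-magnitude
    element is positive; explained fractions sum to 1.
    """
    cols = _coef_columns(panel)
    data = panel[cols].dropna()
    if len(data) < 3 or len(cols) < 2:
        raise ValueError("need >=3 animals and >=2 coefficients")
    vals = data.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant coefficient column(s): {bad}")
    Z = (vals - vals.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    loadings = loadings * flip
    scores = Z @ loadings
    explained = s ** 2 / np.sum(s ** 2)
    pcs = [f"PC{i+1}" for i in range(len(s))]
    return (
        pd.DataFrame(loadings, index=cols, columns=pcs),
        pd.DataFrame(scores, index=data.index, columns=pcs),
        pd.Series(explained, index=pcs, name="explained"),
    )


def trend_by_cohort(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-birth-year mean of each coefficient, with animal counts.

    Output columns: year, count, then one mean column per coefficient.
    """
    if "birth_year" not in panel.columns:
        raise ValueError("panel has no birth_year column")
    cols = _coef_columns(panel)
    out = None
    for c in cols:
        t = mean_f_by_cohort(panel[c], panel["birth_year"]).rename(
            columns={"mean": c, "count": f"n_{c}"}
        )
        out = t if out is None else out.merge(t, on="year", how="outer")
    if out is None or out.empty:
        return pd.DataFrame(columns=["year", "count"] + cols)
    counts = out[[f"n_{c}" for c in cols]].max(axis=1).astype(int)
    out = out[["year"] + cols]
    out.insert(1, "count", counts)
    return out.sort_values("year").reset_index(drop=True)
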