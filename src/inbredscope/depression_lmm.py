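"""Bayesian linear mixed models for inbreeding depression.

The genome-wide model regresses a reproductive trait on an inbreeding
coefficient while absorbing environment and additive genetics:

    y = X b + beta F + Z u + e,
    u ~ N(0, K sigma_u^2),   e ~ N(0, I sigma_e^2),

with X the fixed-effect design (sex of calf, calving month, herd-year
contemporary group; linear + quadratic age-at-first-calving covariates for
the calving-difficulty and gestation-length traits), F the inbreeding
covariate and K either the pedigree numerator relationship matrix A or a
genomic relationship matrix G.  The chromosomal model replaces ``beta F``
by ``sum_i beta_i F_i`` over the 29 autosomes, fitted jointly.

Fitting is a Gibbs sampler with flat priors on the location parameters and
scaled-inverse-chi-square priors (df 5, prior modes splitting the
phenotypic variance equally) on the two variance components.  The additive
effects are sampled in the eigenbasis of K, which makes their full
conditional diagonal.  Significance of an inbreeding effect uses
``t = beta_hat / PSD`` against standard-normal two-sided thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MCMC = (100_000, 50_000, 10)
TEST_MCMC = (5_000, 2_500, 5)   # reduced preset for fast runs

_PRIOR_DF = 5.0


@dataclass
class LMMSpec:
    """Aligned model inputs for one trait.

    ``F`` is (n x q): one column for the genome-wide model, 29 for the
    chromosomal model.  One record per animal.
    """

    y: np.ndarray
    X: np.ndarray
    F: np.ndarray
    animal_ids: list[str]
    fixed_names: list[str]
    f_names: list[str]
    trait: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim == 1:
            self.F = self.F[:, None]
        n = self.y.size
        if self.X.shape[0] != n or self.F.shape[0] != n or len(self.animal_ids) != n:
            raise ValueError("y, X, F and animal_ids must be row-aligned")


TRAITS = ("AFC", "CD", "GL")


def build_design(phen: pd.DataFrame, trait: str) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Fixed-effects design for one trait.

    Returns (filtered phenotype rows, X, column names).  Age-at-first-
    calving records beyond mean +/- 3 SD are removed first; calving
    difficulty scores of 5 are removed; the CD and GL designs carry
    centred linear and quadratic AFC covariates.  Factors are treatment
    coded against their first level, with an intercept.
    """
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    df = phen[phen["trait"] == trait].copy()
    if trait == "AFC":
        mu, sd = df["value"].mean(), df["value"].std()
        if sd > 0:
            df = df[(df["value"] - mu).abs() <= 3 * sd]
    if trait == "CD":
        df = df[df["value"] != 5]
    df = df.reset_index(drop=True)

    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    for factor in ("sex", "month", "herd_year"):
        dummies = pd.get_dummies(
            df[factor].astype(str), prefix=factor, drop_first=True, dtype=float
        )
        parts.append(dummies)
    if trait in ("CD", "GL"):
        afc = df["afc"].astype(float)
        afc_c = afc - afc.mean()
        parts.append(afc_c.rename("afc_lin"))
        parts.append((afc_c ** 2).rename("afc_quad"))
    X = pd.concat(parts, axis=1)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name columns whose removal restores full rank
        aliased = []
        for j in range(Xv.shape[1]):
            keep = [k for k in range(Xv.shape[1]) if k != j]
            if np.linalg.matrix_rank(Xv[:, keep]) == rank:
                aliased.append(X.columns[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return df, Xv, list(X.columns)


@dataclass
class DepressionFit:
    """Posterior summaries and retained samples from one Gibbs run."""

    beta_mean: np.ndarray
    beta_psd: np.ndarray
    f_names: list[str]
    b_mean: np.ndarray
    b_psd: np.ndarray
    fixed_names: list[str]
    sigma2_u: tuple[float, float]    # posterior mean, PSD
    sigma2_e: tuple[float, float]
    u_mean: pd.Series
    samples: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            (name, m, s, significance(m, s))
            for name, m, s in zip(self.f_names, self.beta_mean, self.beta_psd)
        ]
        return pd.DataFrame(rows, columns=["covariate", "beta", "psd", "signif"])


def _prepare_kinship(kinship: pd.DataFrame, animal_ids: list[str]):
    K = kinship.loc[animal_ids, animal_ids].to_numpy(dtype=float)
    K = 0.5 * (K + K.T)
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-6 * max(1.0, vals.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    keep = vals > 1e-8 * max(1.0, vals.max())
    return vals[keep], vecs[:, keep]


def gibbs_lmm(
    spec: LMMSpec,
    kinship: pd.DataFrame | None,
    mcmc: tuple[int, int, int] = TEST_MCMC,
    seed: int = 0,
    fixed_variances: tuple[float, float] | None = None,
) -> DepressionFit:
    """Gibbs sampler for the inbreeding-depression mixed model.

    ``kinship=None`` drops the random additive effect (plain Bayesian
    regression, used e.g. for regressions between inbreeding measures).
    ``fixed_variances=(s2u, s2e)`` holds the variance components fixed, in
    which case the location posteriors have a generalized-least-squares
    closed form that the chain should agree with.

    One record per animal is required: the additive effects are sampled in
    the eigenbasis of the kinship matrix, which makes their full
    conditional diagonal only when Z = I.
    """
    cycles, burnin, thin = mcmc
    if not (0 < burnin < cycles):
        raise ValueError("need 0 < burn-in < cycles")
    if not np.all(np.isfinite(spec.y)):
        raise ValueError("non-finite phenotype values")
    if len(set(spec.animal_ids)) != len(spec.animal_ids):
        raise ValueError("one record per animal required")
    rng = np.random.default_rng(seed)
    y = spec.y
    n = y.size
    W = np.hstack([spec.X, spec.F])
    p_fix = spec.X.shape[1]
    q = spec.F.shape[1]
    WtW = W.T @ W
    R = np.linalg.cholesky(WtW).T            # upper triangular
    from scipy.linalg import solve_triangular

    use_u = kinship is not None
    if use_u:
        if list(kinship.index) != list(kinship.columns):
            raise ValueError("kinship index/columns mismatch")
        missing = [a for a in spec.animal_ids if a not in kinship.index]
        if missing:
            raise ValueError(f"animals missing from kinship: {missing[:5]}")
        d, U = _prepare_kinship(kinship, spec.animal_ids)

    vary = float(np.var(y)) or 1.0
    nu0 = _PRIOR_DF
    s0 = (nu0 + 2.0) / nu0 * vary / 2.0      # prior mode = vary / 2
    if fixed_variances is not None:
        s2u, s2e = fixed_variances
    else:
        s2u, s2e = vary / 2, vary / 2

    theta = np.zeros(W.shape[1])
    u = np.zeros(n)
    a = np.zeros(d.size) if use_u else None

    n_keep = (cycles - burnin) // thin
    keep_theta = np.empty((n_keep, W.shape[1]))
    keep_s2 = np.empty((n_keep, 2))
    u_sum = np.zeros(n)
    k = 0
    for it in range(cycles):
        # locations
        rhs = W.T @ (y - u)
        theta_hat = solve_triangular(R, solve_triangular(R.T, rhs, lower=True))
        z = rng.standard_normal(W.shape[1])
        theta = theta_hat + solve_triangular(R, z) * np.sqrt(s2e)
        resid_fixed = y - W @ theta
        # additive effects in the eigenbasis of K
        if use_u and s2u > 0:
            ytil = U.T @ resid_fixed
            lam = d * s2u
            post_var = lam * s2e / (lam + s2e)
            post_mean = lam / (lam + s2e) * ytil
            a = post_mean + rng.standard_normal(d.size) * np.sqrt(post_var)
            u = U @ a
        else:
            u = np.zeros(n)
        # variance components
        if fixed_variances is None:
            if use_u:
                ss_u = float(np.sum(a * a / d))
                s2u = (nu0 * s0 + ss_u) / rng.chisquare(nu0 + d.size)
            resid = resid_fixed - u
            ss_e = float(resid @ resid)
            s2e = (nu0 * s0 + ss_e) / rng.chisquare(nu0 + n)
        if it >= burnin and (it - burnin) % thin == 0:
            keep_theta[k] = theta
            keep_s2[k] = (s2u if use_u else 0.0, s2e)
            u_sum += u
            k += 1
    keep_theta = keep_theta[:k]
    keep_s2 = keep_s2[:k]
    beta = keep_theta[:, p_fix:]
    b = keep_theta[:, :p_fix]
    return DepressionFit(
        beta_mean=beta.mean(axis=0),
        beta_psd=beta.std(axis=0, ddof=1),
        f_names=list(spec.f_names),
        b_mean=b.mean(axis=0),
        b_psd=b.std(axis=0, ddof=1),
        fixed_names=list(spec.fixed_names),
        sigma2_u=(float(keep_s2[:, 0].mean()), float(keep_s2[:, 0].std(ddof=1))),
        sigma2_e=(float(keep_s2[:, 1].mean()), float(keep_s2[:, 1].std(ddof=1))),
        u_mean=pd.Series(u_sum / max(k, 1), index=spec.animal_ids, name="u"),
        samples={"beta": beta, "sigma2": keep_s2},
        settings={"cycles": cycles, "burnin": burnin, "thin": thin, "seed": seed},
    )


def chromosomal_regression(
    spec: LMMSpec,
    kinship: pd.DataFrame | None,
    mcmc: tuple[int, int, int] = TEST_MCMC,
    seed: int = 0,
) -> DepressionFit:
    """Joint regression on all 29 chromosomal inbreeding coefficients.

    All beta_i are sampled simultaneously in one model; near-collinear
    covariate pairs (|r| > 0.99) are rejected because a joint fit cannot
    separate them.
    """
    if spec.F.shape[1] < 2:
        raise ValueError("chromosomal model needs multiple F columns")
    sd = spec.F.std(axis=0)
    nz = sd > 0
    C = np.corrcoef(spec.F[:, nz].T)
    off = np.abs(C - np.eye(C.shape[0]))
    if off.max() > 0.99:
        i, j = np.unravel_index(np.argmax(off), off.shape)
        names = [n for n, keep in zip(spec.f_names, nz) if keep]
        raise ValueError(
            f"near-collinear chromosomal covariates: {names[i]} vs {names[j]}"
        )
    return gibbs_lmm(spec, kinship, mcmc=mcmc, seed=seed)


_STAR1 = stats.norm.ppf(0.975)    # 1.959964
_STAR2 = stats.norm.ppf(0.995)    # 2.575829


def significance(beta_hat: float, psd: float) -> str:
    """Two-sided stars from t = beta_hat / PSD against the normal reference:
    '*' for p < 0.05, '**' for p < 0.01."""
    if psd <= 0:
        raise ValueError("PSD must be positive")
    t = abs(beta_hat / psd)
    if t > _STAR2:
        return "**"
    if t > _STAR1:
        return "*"
    return ""


def ebv_sensitivity(
    fit_with: DepressionFit, fit_without: DepressionFit
) -> tuple[float, float]:
    """Pearson and Spearman correlations of posterior-mean breeding values
    between fits with and without the inbreeding covariate."""
    if list(fit_with.u_mean.index) != list(fit_without.u_mean.index):
        raise ValueError("fits cover different animal sets")
    a = fit_with.u_mean.to_numpy()
    b = fit_without.u_mean.to_numpy()
    return (
        float(stats.pearsonr(a, b).statistic),
        float(stats.spearmanr(a, b).statistic),
    )
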