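"""Mixed-model phenotypic analysis: outlier filtering, REML/BLUP, Cullis
broad-sense heritability, descriptive statistics and trait correlations.

The core model for one trait is

    y_ijkl = mu + chamber_i + (chamber:block)_ij
             + (chamber:block:sub-block)_ijk + genotype_l + e_ijkl

with chamber fixed and everything else an independent normal random effect.
Variance components are estimated by REML on the profiled scale (variance
ratios relative to the residual), genotype BLUPs and their prediction-error
(co)variances come from Henderson's mixed-model equations at the REML
estimates, and broad-sense heritability uses the Cullis form

    H^2 = 1 - Vdelta / (2 * sigma2_g)

where ``Vdelta`` is the mean variance of a difference of two genotypic
BLUPs — the appropriate generalization of the balanced-design formula to
unbalanced data.  Unbalanced tables are handled without imputation.

REML is implemented directly (rather than through a packaged mixed-model
fitter) because the Cullis numerator needs the full genotype block of the
prediction-error covariance matrix, which desk-scale problems allow exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "MixedModelSpec",
    "BlupResult",
    "tukey_filter",
    "fit_mixed_model",
    "cullis_heritability",
    "descriptive_stats",
    "trait_correlations",
]


@dataclass(frozen=True)
class MixedModelSpec:
    """Model structure: response, fixed chamber effect, nested random terms.

    Random terms are named by ``:``-joined column interactions; the term
    ``"genotype"`` must be present — it is the block whose BLUPs and
    prediction-error variances feed the heritability.
    """

    response: str
    fixed: str | None = "chamber"
    random: tuple[str, ...] = ("chamber:block", "chamber:block:sub_block", "genotype")

    def __post_init__(self) -> None:
        if "genotype" not in self.random:
            raise ValueError("spec.random must include the 'genotype' term")


@dataclass
class BlupResult:
    """REML fit summary for one trait."""

    variance_components: dict[str, float]  # per random term + "residual"
    blups: pd.Series  # genotype effect + overall intercept, trait units
    genotype_effects: pd.Series  # centered BLUP effects
    pev: np.ndarray  # genotype prediction-error covariance block (g x g)
    vdblup: float  # mean variance of a BLUP difference
    heritability: float
    intercept: float
    deviance: float  # -2 * REML log-likelihood at the optimum
    converged: bool
    n_obs: int
    n_iter: int
    flags: list[str] = field(default_factory=list)

    @property
    def sigma2_g(self) -> float:
        return self.variance_components["genotype"]


def tukey_filter(
    table: pd.DataFrame,
    trait: str,
    k: float = 1.5,
    group: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag and remove Tukey box-plot outliers for one trait.

    Values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are flagged and dropped;
    quartiles use the linear-interpolation convention (numpy default).
    ``group`` applies the fences within groups (e.g. per day); the default
    is a single global fence per trait.  Groups with fewer than 4
    non-missing values, and groups with zero IQR, flag nothing.

    Returns ``(filtered_table, flags)`` with ``flags`` indexed like
    ``table``.
    """
    flags = pd.Series(False, index=table.index)

    def _flag(values: pd.Series) -> pd.Series:
        x = values.dropna()
        if len(x) < 4:
            return pd.Series(False, index=values.index)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        return (values < lo) | (values > hi)

    if group:
        for _, idx in table.groupby(group, dropna=False).groups.items():
            flags.loc[idx] = _flag(table.loc[idx, trait])
    else:
        flags = _flag(table[trait])
    return table.loc[~flags].copy(), flags


def _design_matrices(table: pd.DataFrame, spec: MixedModelSpec):
    y = table[spec.response].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    table = table.loc[keep]
    y = y[keep]
    n = len(y)

    if spec.fixed and spec.fixed in table.columns:
        levels = pd.unique(table[spec.fixed])
        codes = pd.Categorical(table[spec.fixed], categories=levels).codes
        X = np.zeros((n, len(levels)))
        X[:, 0] = 1.0
        for j in range(1, len(levels)):
            X[codes == j, j] = 1.0
        fixed_levels = list(levels)
    else:
        X = np.ones((n, 1))
        fixed_levels = []

    blocks = {}
    Z_parts = []
    col_terms = []
    for term in spec.random:
        cols = term.split(":")
        key = table[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + ":" + table[c].astype(str)
        codes, levels = pd.factorize(key)
        Zt = np.zeros((n, len(levels)))
        Zt[np.arange(n), codes] = 1.0
        blocks[term] = list(levels)
        Z_parts.append(Zt)
        col_terms.extend([term] * len(levels))
    Z = np.hstack(Z_parts)
    return y, X, Z, np.array(col_terms), blocks, fixed_levels, n


def _neg2_reml(gam_per_col, A, BX, cy, XtX, Xty, yty, n, p):
    """Profiled -2 REML log-likelihood; returns (crit, sigma2_e)."""
    d = np.sqrt(gam_per_col)
    K = np.eye(len(d)) + (d[:, None] * A) * d[None, :]
    cf = linalg.cho_factor(K, lower=True)
    logdet_K = 2.0 * np.sum(np.log(np.diag(cf[0])))
    DB = d[:, None] * BX  # q x p
    Dc = d * cy
    KiDB = linalg.cho_solve(cf, DB)
    KiDc = linalg.cho_solve(cf, Dc)
    XHiX = XtX - DB.T @ KiDB
    XHiy = Xty - DB.T @ KiDc
    yHiy = yty - Dc @ KiDc
    sgn, logdet_XHiX = np.linalg.slogdet(XHiX)
    if sgn <= 0:
        return np.inf, np.nan
    qy = yHiy - XHiy @ np.linalg.solve(XHiX, XHiy)
    if qy <= 0:
        return np.inf, np.nan
    s2 = qy / (n - p)
    crit = (n - p) * (math.log(s2) + 1.0 + math.log(2.0 * math.pi)) + logdet_K + logdet_XHiX
    return crit, s2


def fit_mixed_model(
    table: pd.DataFrame,
    spec: MixedModelSpec | str,
    pev_mode: str = "full",
    max_iter: int = 200,
) -> BlupResult:
    """Fit the chamber/block/sub-block/genotype model by REML.

    Variance components are constrained non-negative (boundary estimates
    are flagged); BLUPs and the genotype prediction-error covariance block
    come from the mixed-model equations at the REML estimates.

    ``pev_mode="average"`` replaces the exact pairwise-difference variance
    with the diagonal-only approximation ``2 * mean(PEV_ii)`` (and records
    its relative error versus the exact value in the flags) — the exact
    computation is the default at desk scale (g up to ~1000).
    """
    if isinstance(spec, str):
        spec = MixedModelSpec(response=spec)
    for term in spec.random:
        for c in term.split(":"):
            if c not in table.columns:
                raise ValueError(f"random term {term!r}: column {c!r} missing from table")
    n_gen = table["genotype"].nunique()
    if n_gen < 2:
        raise ValueError("need >= 2 genotypes")

    y, X, Z, col_terms, blocks, fixed_levels, n = _design_matrices(table, spec)
    p = X.shape[1]
    if n <= p:
        raise ValueError("not enough observations for the fixed effects")

    A = Z.T @ Z
    BX = Z.T @ X
    cy = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    terms = list(spec.random)
    k = len(terms)
    term_idx = [col_terms == t for t in terms]

    def expand(gam):
        out = np.empty(Z.shape[1])
        for g, m in zip(gam, term_idx):
            out[m] = max(g, 0.0)
        return out

    def objective(gam):
        crit, _ = _neg2_reml(expand(gam), A, BX, cy, XtX, Xty, yty, n, p)
        return crit

    best = None
    n_iter = 0
    for x0 in ([1.0] * k, [0.1] * k, [5.0] * k):
        res = optimize.minimize(
            objective,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * k,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"REML did not converge: {best.message}")
    gam = np.maximum(best.x, 0.0)
    deviance, s2e = _neg2_reml(expand(gam), A, BX, cy, XtX, Xty, yty, n, p)

    flags = []
    if not best.success:
        flags.append(f"optimizer: {best.message}")
    for t, g in zip(terms, gam):
        if g <= 1e-10:
            flags.append(f"boundary: {t} variance estimated at 0")

    vcs = {t: float(g * s2e) for t, g in zip(terms, gam)}
    vcs["residual"] = float(s2e)

    # Henderson MME at the REML estimates (gamma floored for zero components)
    gam_mme = np.maximum(expand(gam), 1e-8)
    q = Z.shape[1]
    C = np.zeros((p + q, p + q))
    C[:p, :p] = XtX
    C[:p, p:] = BX.T
    C[p:, :p] = BX
    C[p:, p:] = A + np.diag(1.0 / gam_mme)
    rhs = np.concatenate([Xty, cy])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"singular mixed-model equations: {err}") from err
    sol = Cinv @ rhs
    beta = sol[:p]
    u = sol[p:]

    g_mask = col_terms == "genotype"
    u_g = u[g_mask]
    pev = s2e * Cinv[p:, p:][np.ix_(g_mask, g_mask)]

    g = int(g_mask.sum())
    tr = float(np.trace(pev))
    S = float(pev.sum())
    vdblup_full = 2.0 * (g * tr - S) / (g * (g - 1))
    if pev_mode == "average":
        vdblup = 2.0 * tr / g
        if vdblup_full > 0:
            flags.append(
                f"average-PEV approximation; relative error {abs(vdblup - vdblup_full) / vdblup_full:.3g}"
            )
    else:
        vdblup = vdblup_full

    sigma2_g = vcs["genotype"]
    H, h_flags = cullis_heritability(vdblup, sigma2_g, return_flags=True)
    flags.extend(h_flags)

    intercept = float(beta[0] + (np.sum(beta[1:]) / len(fixed_levels) if fixed_levels else 0.0))
    levels = blocks["genotype"]
    effects = pd.Series(u_g, index=levels, name=spec.response).sort_index()
    blups = (effects + intercept).rename(spec.response)

    return BlupResult(
        variance_components=vcs,
        blups=blups,
        genotype_effects=effects,
        pev=pev,
        vdblup=float(vdblup),
        heritability=H,
        intercept=intercept,
        deviance=float(deviance),
        converged=bool(best.success),
        n_obs=n,
        n_iter=int(n_iter),
        flags=flags,
    )


def cullis_heritability(
    vdblup: float, sigma2_g: float, return_flags: bool = False
) -> float | tuple[float, list[str]]:
    """Cullis broad-sense heritability ``1 - Vdelta / (2 sigma2_g)``.

    ``sigma2_g = 0`` gives H = 0 with a degenerate-fit flag; values outside
    [0, 1] from numerical noise are clipped and flagged.
    """
    flags: list[str] = []
    if vdblup < 0:
        raise ValueError("vdblup must be >= 0")
    if sigma2_g <= 0:
        flags.append("degenerate: sigma2_g = 0, H reported as 0")
        H = 0.0
    else:
        H = 1.0 - vdblup / (2.0 * sigma2_g)
        if H < 0.0 or H > 1.0:
            flags.append(f"H={H:.4f} outside [0, 1]; clipped")
            H = min(max(H, 0.0), 1.0)
    return (H, flags) if return_flags else H


def descriptive_stats(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    level: str = "raw",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Per-trait mean, median, min, max, SD (n-1) and CV%.

    ``level="genotype"`` first averages within genotype, matching summaries
    computed on genotype-level values rather than raw observations.  CV is
    reported missing when the mean is 0.
    """
    if traits is None:
        traits = [c for c in table.columns if pd.api.types.is_float_dtype(table[c])]
    data = table
    if level == "genotype":
        data = table.groupby(genotype_col, observed=True)[traits].mean().reset_index()
    rows = {}
    for t in traits:
        x = data[t].dropna()
        if len(x) < 2:
            raise ValueError(f"trait {t!r}: need >= 2 values")
        sd = float(x.std(ddof=1))
        mean = float(x.mean())
        rows[t] = {
            "mean": mean,
            "median": float(x.median()),
            "min": float(x.min()),
            "max": float(x.max()),
            "sd": sd,
            "cv_pct": 100.0 * sd / mean if mean != 0 else math.nan,
        }
    return pd.DataFrame(rows).T


def trait_correlations(blups: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pearson correlations among traits on the per-genotype matrix.

    Pairwise-complete over missing values; zero-variance traits are dropped
    with a warning (their correlation is undefined).
    """
    numeric = blups.select_dtypes("number")
    keep = []
    for c in numeric.columns:
        if numeric[c].std(ddof=1) > 0:
            keep.append(c)
        else:
            warnings.warn(f"trait {c!r} has zero variance; dropped from correlations")
    return numeric[keep].corr(method="pearson", min_periods=min_periods)
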