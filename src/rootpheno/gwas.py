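"""Mixed-linear-model genome-wide association scan.

The scan follows standard MLM practice for structured panels: filter sites
on missingness and minor allele frequency, build a centered (VanRaden)
kinship matrix, estimate the null-model variance components once by REML
and reuse them for every marker test (P3D — "population parameters
previously determined"), with principal-component covariates absorbing
population structure, and Bonferroni control of the family-wise error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rootpheno.genotypes import GenotypeMatrix
from rootpheno.popgen import pca

__all__ = [
    "GwasResult",
    "filter_sites",
    "kinship",
    "mlm_scan",
    "bonferroni_threshold",
    "manhattan_table",
]


@dataclass
class GwasResult:
    """Per-marker association results plus scan metadata."""

    table: pd.DataFrame  # marker, chrom, pos, maf, n, p, add_effect, marker_r2
    threshold: float  # per-test Bonferroni p threshold
    neglog10_threshold: float
    meta: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] <= self.threshold]


def filter_sites(
    g: GenotypeMatrix,
    max_missing: float = 0.15,
    min_maf: float = 0.01,
    literal_maf_reading: bool = False,
) -> tuple[GenotypeMatrix, dict]:
    """Remove sites by missingness and minor allele frequency.

    Default reading (standard practice): drop sites with missing fraction
    > ``max_missing`` or MAF < ``min_maf``. ``literal_maf_reading=True``
    instead drops sites with MAF > ``min_maf`` — the literal wording of
    some protocol descriptions — and is provided for comparison only.
    """
    miss = g.missing_fraction()
    maf = g.minor_allele_frequency()
    bad_miss = miss > max_missing
    bad_maf = (maf > min_maf) if literal_maf_reading else (maf < min_maf)
    bad_maf = bad_maf | np.isnan(maf)
    keep = ~(bad_miss | bad_maf)
    report = {
        "n_input": g.n_sites,
        "removed_missing": int(bad_miss.sum()),
        "removed_maf": int(bad_maf.sum()),
        "removed_total": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(f"all sites removed by filters: {report}")
    return g.take_sites(np.where(keep)[0]), report


def kinship(g: GenotypeMatrix) -> np.ndarray:
    """Centered (VanRaden) genomic relationship matrix.

    ``K = Z Z' / (2 * sum p_j (1 - p_j))`` with ``Z`` the per-site
    2p-centered, mean-imputed dosages. Symmetric and positive
    semi-definite by construction.
    """
    p = g.allele_frequency()
    denom = 2.0 * np.nansum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all sites monomorphic; kinship undefined")
    Z = g.imputed() - 2.0 * p
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0


def bonferroni_threshold(m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Per-test p threshold ``alpha / m`` and its -log10."""
    if m < 1:
        raise ValueError("m must be >= 1")
    t = alpha / m
    return t, -math.log10(t)


def _null_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """One-time REML of ``y = X b + u + e`` with ``u ~ N(0, sigma2_g K)``.

    Works in the eigenbasis of K, profiling the residual variance and
    optimizing the ratio ``delta = sigma2_g / sigma2_e`` in log space.
    Returns ``(sigma2_g, sigma2_e, eigvals, eigvecs)``.
    """
    n, p = X.shape
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise ValueError(f"kinship not positive semi-definite (min eig {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    def crit(log_delta: float) -> float:
        d = math.exp(log_delta)
        h = d * lam + 1.0
        Xw = Xs / h[:, None]
        XtHX = Xs.T @ Xw
        sgn, ld_XtHX = np.linalg.slogdet(XtHX)
        if sgn <= 0:
            return np.inf
        beta = np.linalg.solve(XtHX, Xw.T @ ys)
        res = ys - Xs @ beta
        qy = float(res @ (res / h))
        if qy <= 0:
            return np.inf
        s2 = qy / (n - p)
        return (n - p) * math.log(s2) + float(np.log(h).sum()) + ld_XtHX

    grid = np.linspace(math.log(1e-6), math.log(1e6), 25)
    vals = [crit(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded")
    delta = math.exp(res.x)
    # residual variance at the optimum; delta -> 0 reduces to OLS
    if crit(math.log(1e-8)) < res.fun:
        delta = 0.0
    h = delta * lam + 1.0
    Xw = Xs / h[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    resid = ys - Xs @ beta
    s2e = float(resid @ (resid / h)) / (n - p)
    return delta * s2e, s2e, lam, U


def mlm_scan(
    y,
    g: GenotypeMatrix,
    K: np.ndarray | None = None,
    n_pcs: int = 3,
    alpha: float = 0.05,
) -> GwasResult:
    """P3D mixed-linear-model association scan.

    The null model ``y = X beta + u + e`` (X = intercept + the first
    ``n_pcs`` dosage principal components; ``u ~ N(0, sigma2_g K)``) is
    fitted once by REML; its variance components whiten the data, and each
    marker's additive dosage effect is then a generalized-least-squares
    fit with a two-sided t test. ``marker_r2`` is the fraction of the
    covariate-adjusted, whitened phenotypic variance explained by the
    marker. Markers collinear with the covariates get missing p-values.

    ``y`` may be a pandas Series indexed by individual id (aligned and
    checked against the panel) or a plain array in panel order.
    """
    if isinstance(y, pd.Series):
        missing = [i for i in g.individual_ids if i not in y.index]
        if missing:
            raise ValueError(f"phenotype missing for individuals: {missing[:5]}...")
        y = y.loc[list(g.individual_ids)].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != g.n_individuals:
            raise ValueError(
                f"phenotype length {y.shape[0]} != individuals {g.n_individuals}"
            )
    if K is None:
        K = kinship(g)
    K = np.asarray(K, dtype=float)
    if K.shape != (g.n_individuals, g.n_individuals):
        raise ValueError("kinship shape does not match the panel")

    n = g.n_individuals
    X = np.ones((n, 1))
    if n_pcs > 0:
        scores, _, _ = pca(g, n_components=n_pcs)
        X = np.hstack([X, scores[:, :n_pcs]])
    p_cov = X.shape[1]

    s2g, s2e, lam, U = _null_reml(y, X, K)
    w = 1.0 / np.sqrt(s2g * lam + s2e)
    yw = w * (U.T @ y)
    Xw = w[:, None] * (U.T @ X)
    Mw = w[:, None] * (U.T @ g.imputed())

    XtX = Xw.T @ Xw
    ry = yw - Xw @ np.linalg.solve(XtX, Xw.T @ yw)
    RG = Mw - Xw @ np.linalg.solve(XtX, Xw.T @ Mw)

    gQg = (RG**2).sum(axis=0)
    gQy = RG.T @ ry
    yQy = float(ry @ ry)
    df = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gQy / gQg
        sse = yQy - beta * gQy
        se = np.sqrt(np.maximum(sse, 0.0) / df / gQg)
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        r2 = beta * gQy / yQy
    degenerate = gQg <= 1e-10 * n
    beta[degenerate] = np.nan
    pvals[degenerate] = np.nan
    r2[degenerate] = np.nan
    pvals = np.where(np.isnan(pvals), np.nan, np.clip(pvals, np.finfo(float).tiny, 1.0))

    m_tested = int(np.isfinite(pvals).sum())
    thr, nlt = bonferroni_threshold(max(m_tested, 1), alpha)
    table = pd.DataFrame(
        {
            "marker": g.site_ids,
            "chrom": g.chrom,
            "pos": g.pos,
            "maf": g.minor_allele_frequency(),
            "n": (~np.isnan(g.dosages)).sum(axis=0),
            "p": pvals,
            "add_effect": beta,
            "marker_r2": r2,
        }
    )
    return GwasResult(
        table=table,
        threshold=thr,
        neglog10_threshold=nlt,
        meta={
            "kinship": "vanraden_centered",
            "n_pcs": n_pcs,
            "alpha": alpha,
            "m_tested": m_tested,
            "sigma2_g": s2g,
            "sigma2_e": s2e,
            "n_collinear": int(degenerate.sum()),
            "method": "p3d_mlm",
        },
    )


def manhattan_table(result: GwasResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular Manhattan export: -log10(p) on a cumulative genome axis.

    Returns ``(full_table, significant)`` where the significant table
    mirrors the usual report columns (marker, chromosome, position, p,
    additive effect, marker R^2).
    """
    tab = result.table.copy()
    tab["neglog10_p"] = -np.log10(tab["p"])
    offset = 0
    cum = np.empty(len(tab), dtype=float)
    for c in pd.unique(tab["chrom"]):
        m = (tab["chrom"] == c).to_numpy()
        cum[m] = tab.loc[m, "pos"].to_numpy() + offset
        offset = cum[m].max() if m.any() else offset
    tab["cum_pos"] = cum
    sig = tab[tab["p"] <= result.threshold][
        ["marker", "chrom", "pos", "p", "add_effect", "marker_r2", "neglog10_p"]
    ].sort_values("p")
    return tab, sig
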