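"""Structured diploid SNP panels under the Balding–Nichols model.

Subpopulation allele frequencies are Beta-distributed around an ancestral
frequency with dispersion set by the target fixation index F, so the
Weir–Cockerham estimator downstream has a known truth to recover.
"""

from __future__ import annotations

import numpy as np

from rootpheno.genotypes import GenotypeMatrix

#: Mung bean karyotype; sites are spread round-robin over these chromosomes.
DEFAULT_N_CHROM = 11


def simulate_genotypes(
    n_individuals: int,
    n_sites: int,
    fst: float = 0.05,
    n_subpops: int = 2,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    qtl: list[tuple[int, float]] | None = None,
    n_chromosomes: int = DEFAULT_N_CHROM,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a structured biallelic SNP panel.

    Per site, an ancestral frequency is drawn uniformly from ``maf_range``
    and randomly complemented; when ``fst > 0`` each subpopulation's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding–Nichols), otherwise
    the ancestral frequency is used directly. Dosages are Binomial(2, p_sub);
    missing calls are dropped in at ``missing_rate``. Individuals are split
    evenly across subpopulations (the remainder goes to the last one).

    ``qtl`` is an optional list of ``(site_index, additive_effect)`` pairs
    recorded in the truth dict (see :func:`simulate_qtl_phenotype`).
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)

    maf = rng.uniform(lo, hi, size=n_sites)
    flip = rng.random(n_sites) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)

    if fst > 0.0:
        a = p_anc * (1.0 - fst) / fst
        b = (1.0 - p_anc) * (1.0 - fst) / fst
        p_sub = rng.beta(a[None, :], b[None, :], size=(n_subpops, n_sites))
    else:
        # F = 0: the Beta parameterization degenerates; all subpopulations
        # share the ancestral frequency.
        p_sub = np.tile(p_anc, (n_subpops, 1))

    base = n_individuals // n_subpops
    labels = np.repeat(np.arange(n_subpops), base)
    labels = np.concatenate([labels, np.full(n_individuals - len(labels), n_subpops - 1)])
    dosages = rng.binomial(2, p_sub[labels, :]).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan

    chrom = np.array([f"{(i % n_chromosomes) + 1}" for i in range(n_sites)])
    pos = np.empty(n_sites, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        # strictly increasing positions via cumulative random gaps
        pos[idx] = np.cumsum(rng.integers(100, 50_000, size=len(idx)))
    order = np.lexsort((pos, chrom.astype(int)))

    g = GenotypeMatrix(
        dosages=dosages[:, order],
        chrom=chrom[order],
        pos=pos[order],
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "T"),
        individual_ids=[f"IND{i + 1:04d}" for i in range(n_individuals)],
        truth={
            "fst": fst,
            "subpop_labels": labels,
            "ancestral_freq": p_anc[order],
            "qtl": [] if qtl is None else [(int(np.where(order == s)[0][0]), float(b)) for s, b in qtl],
        },
    )
    return g


def simulate_qtl_phenotype(
    g: GenotypeMatrix,
    qtl: list[tuple[int, float]] | None = None,
    qtl_variance_fraction: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Phenotype from planted QTL plus unit-variance residual noise.

    If ``qtl_variance_fraction`` is given with a single QTL, the effect size
    is rescaled so the QTL term explains exactly that fraction of the
    realized phenotypic variance.
    """
    rng = np.random.default_rng(seed)
    qtl = qtl if qtl is not None else g.truth.get("qtl", [])
    if not qtl:
        return rng.normal(size=g.n_individuals)
    X = g.imputed()
    signal = np.zeros(g.n_individuals)
    for site, beta in qtl:
        signal += beta * X[:, site]
    if qtl_variance_fraction is not None:
        frac = qtl_variance_fraction
        var_sig = signal.var()
        if var_sig <= 0:
            raise ValueError("planted QTL is monomorphic; cannot scale variance")
        # residual sd chosen so var(signal) / (var(signal)+sigma2) = frac
        sigma2 = var_sig * (1.0 - frac) / frac
        return signal + rng.normal(0.0, np.sqrt(sigma2), size=g.n_individuals)
    return signal + rng.normal(size=g.n_individuals)
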