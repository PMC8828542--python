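import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootpheno.gwas import (
    bonferroni_threshold,
    filter_sites,
    kinship,
    manhattan_table,
    mlm_scan,
)
from rootpheno.sim import simulate_genotypes, simulate_qtl_phenotype


# ---------------------------------------------------------------- site filters
def test_filter_rules_on_engineered_sites():
    g = simulate_genotypes(100, 3, fst=0.0, maf_range=(0.3, 0.5), seed=0)
    g.dosages[:25, 0] = np.nan  # 25% missing -> removed
    g.dosages[:, 1] = 0.0
    g.dosages[0, 1] = 1.0  # MAF 0.005 -> removed
    kept, report = filter_sites(g)
    assert kept.n_sites == 1
    assert report["removed_missing"] == 1 and report["n_kept"] == 1


def test_filter_matches_brute_force_recount():
    g = simulate_genotypes(120, 400, fst=0.05, maf_range=(0.01, 0.5), missing_rate=0.1, seed=1)
    kept, report = filter_sites(g, max_missing=0.15, min_maf=0.01)
    survivors = 0
    for j in range(g.n_sites):
        col = g.dosages[:, j]
        miss = np.isnan(col).mean()
        obs = col[~np.isnan(col)]
        p = obs.mean() / 2
        maf = min(p, 1 - p)
        if miss <= 0.15 and maf >= 0.01:
            survivors += 1
    assert kept.n_sites == survivors == report["n_kept"]


def test_literal_maf_reading_flag():
    # literally removing MAF > 0.01 empties a common-variant panel...
    g = simulate_genotypes(100, 200, fst=0.0, maf_range=(0.05, 0.5), seed=2)
    with pytest.raises(ValueError, match="all sites removed"):
        filter_sites(g, literal_maf_reading=True)
    # ...and keeps only the rare end of a mixed panel
    g2 = simulate_genotypes(400, 200, fst=0.0, maf_range=(0.005, 0.5), seed=2)
    kept, _ = filter_sites(g2, literal_maf_reading=True)
    assert (kept.minor_allele_frequency() <= 0.01).all()


def test_heavy_missingness_mostly_filtered():
    g = simulate_genotypes(100, 500, missing_rate=0.2, seed=3)
    _, report = filter_sites(g, max_missing=0.15)
    assert report["removed_missing"] > 0.5 * 500


# --------------------------------------------------------------------- kinship
def test_duplicated_individual_matches_twin_diagonal():
    g = simulate_genotypes(40, 800, fst=0.0, seed=4)
    g.dosages[1] = g.dosages[0]
    K = kinship(g)
    assert K[0, 1] == pytest.approx(K[0, 0])
    assert K[0, 1] == pytest.approx(K[1, 1])


def test_kinship_gram_structure_and_unrelatedness():
    n = 200
    g = simulate_genotypes(n, 5000, fst=0.0, seed=5)
    K = kinship(g)
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-8
    off = K[~np.eye(n, dtype=bool)]
    # centering forces off-diagonals to ~ -1/(n-1), i.e. near 0 at panel size
    assert abs(off.mean()) < 0.01
    assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)


# ------------------------------------------------------------------ Bonferroni
def test_bonferroni_arithmetic():
    assert bonferroni_threshold(1)[0] == 0.05
    t, nl = bonferroni_threshold(26_550)
    assert t == pytest.approx(1.883e-6, rel=1e-3)
    assert nl == pytest.approx(5.725, abs=0.005)
    assert bonferroni_threshold(1000)[0] == pytest.approx(5e-5)
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


# -------------------------------------------------------------------- MLM scan
def test_identity_kinship_matches_ols():
    rng = np.random.default_rng(0)
    g = simulate_genotypes(50, 100, fst=0.0, seed=6)
    y = rng.normal(size=50)
    res = mlm_scan(y, g, K=np.eye(50), n_pcs=0)
    X = np.ones((50, 1))
    M = g.imputed()
    for j in range(0, 100, 7):
        xj = np.column_stack([X, M[:, j]])
        beta, *_ = np.linalg.lstsq(xj, y, rcond=None)
        resid = y - xj @ beta
        s2 = resid @ resid / (50 - 2)
        se = np.sqrt(s2 * np.linalg.inv(xj.T @ xj)[1, 1])
        t = beta[1] / se
        p_ols = 2 * stats.t.sf(abs(t), 50 - 2)
        assert res.table.loc[j, "p"] == pytest.approx(p_ols, abs=1e-6)
        assert res.table.loc[j, "add_effect"] == pytest.approx(beta[1], abs=1e-8)


def test_null_pvalues_uniform():
    rng = np.random.default_rng(1)
    g = simulate_genotypes(120, 1000, fst=0.0, seed=7)
    y = rng.normal(size=120)
    res = mlm_scan(y, g, K=np.eye(120), n_pcs=0)
    ks = stats.kstest(res.table["p"].dropna(), "uniform")
    assert ks.pvalue > 0.01


def test_collinear_marker_flagged_missing():
    g = simulate_genotypes(60, 50, fst=0.0, seed=8)
    g.dosages[:, 10] = 2.0  # constant: collinear with the intercept
    y = np.random.default_rng(2).normal(size=60)
    res = mlm_scan(y, g, K=np.eye(60), n_pcs=0)
    assert np.isnan(res.table.loc[10, "p"])
    assert res.meta["n_collinear"] >= 1
    assert res.meta["m_tested"] == np.isfinite(res.table["p"]).sum()


def test_structure_correction_controls_genomic_inflation():
    """lambda_GC calibrated with K + PCs, inflated without them."""
    g = simulate_genotypes(200, 2000, fst=0.05, n_subpops=2, seed=9)
    labels = g.truth["subpop_labels"]
    rng = np.random.default_rng(3)
    y = 1.0 * labels + rng.normal(size=200)  # structured null: no marker effect

    def lambda_gc(res):
        chi2 = stats.chi2.isf(res.table["p"].dropna(), df=1)
        return np.median(chi2) / stats.chi2.ppf(0.5, 1)

    corrected = mlm_scan(y, g, n_pcs=3)
    naive = mlm_scan(y, g, K=np.eye(200), n_pcs=0)
    assert 0.9 <= lambda_gc(corrected) <= 1.1
    assert lambda_gc(naive) > 1.2


def test_misalignment_errors():
    g = simulate_genotypes(30, 20, seed=10)
    with pytest.raises(ValueError, match="length"):
        mlm_scan(np.zeros(29), g)
    with pytest.raises(ValueError, match="missing"):
        mlm_scan(pd.Series(np.zeros(29), index=[f"x{i}" for i in range(29)]), g)
    with pytest.raises(ValueError, match="kinship"):
        mlm_scan(np.zeros(30), g, K=np.eye(29))
    with pytest.raises(ValueError, match="positive semi-definite"):
        mlm_scan(np.zeros(30), g, K=-np.eye(30))


# ------------------------------------------------------------ manhattan export
def test_manhattan_table_shapes_and_significance():
    g = simulate_genotypes(200, 500, fst=0.0, seed=11)
    y_null = np.random.default_rng(4).normal(size=200)
    res = mlm_scan(y_null, g, K=np.eye(200), n_pcs=0)
    full, sig = manhattan_table(res)
    assert len(full) == 500
    assert sig.empty  # no marker expected below ~1e-4 Bonferroni... usually
    # strong planted QTL appears in the significant list
    y = simulate_qtl_phenotype(g, qtl=[(250, 1.0)], qtl_variance_fraction=0.25, seed=5)
    res2 = mlm_scan(y, g, K=np.eye(200), n_pcs=0)
    _, sig2 = manhattan_table(res2)
    assert g.site_ids[250] in set(sig2["marker"])
    # cumulative coordinate strictly increasing within chromosome
    for c in np.unique(full["chrom"]):
        assert (np.diff(full.loc[full.chrom == c, "cum_pos"]) > 0).all()
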