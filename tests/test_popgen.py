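import numpy as np
import pytest

from rootpheno.popgen import hcluster, pca, select_k, wc84_fst
from rootpheno.sim import simulate_genotypes


# ------------------------------------------------------------------------- PCA
def test_points_on_a_line_have_one_component():
    t = np.linspace(0, 1, 20)
    X = np.column_stack([t, 2 * t])
    scores, _, explained = pca(X, 2)
    assert explained[0] == pytest.approx(1.0)


def test_rotation_leaves_spectrum_unchanged():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 4)) * [3.0, 2.0, 1.0, 0.5]
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    _, _, e1 = pca(X, 4)
    _, _, e2 = pca(X @ q, 4)
    assert np.allclose(e1, e2, atol=1e-10)


def test_pc1_separates_balding_nichols_subpopulations():
    g = simulate_genotypes(200, 2000, fst=0.1, n_subpops=2, seed=1)
    with pytest.warns(UserWarning):  # some sites drift to monomorphic
        scores, _, _ = pca(g, 2)
    labels = g.truth["subpop_labels"]
    r = np.corrcoef(scores[:, 0], labels)[0, 1]
    assert abs(r) > 0.9


def test_explained_fractions_non_increasing_and_bounded():
    rng = np.random.default_rng(3)
    _, _, e = pca(rng.normal(size=(30, 10)), 10)
    assert (np.diff(e) <= 1e-12).all()
    assert e.sum() <= 1.0 + 1e-9


# ------------------------------------------------------------------ clustering
def test_two_blobs_recovered_exactly():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(6, 0.3, (25, 2))])
    out = hcluster(X, 2)
    labels = out.labels
    assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
    assert labels[0] != labels[-1]  # Rand index 1.0


def test_k1_single_cluster_and_k_out_of_range():
    X = np.random.default_rng(1).normal(size=(10, 2))
    assert set(hcluster(X, 1).labels) == {1}
    with pytest.raises(ValueError):
        hcluster(X, 11)


def test_duplicated_points_merge_first_at_height_zero():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
    out = hcluster(X, 2)
    assert out.linkage_matrix[0, 2] == 0.0
    assert {int(out.linkage_matrix[0, 0]), int(out.linkage_matrix[0, 1])} == {0, 1}


def test_newick_export_is_parseable():
    import dendropy

    rng = np.random.default_rng(2)
    out = hcluster(rng.normal(size=(8, 3)), 2)
    tree = dendropy.Tree.get(data=out.to_newick(), schema="newick")
    assert len(tree.leaf_nodes()) == 8


def test_select_k_three_blobs_unanimous():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(c, 0.3, (30, 2)) for c in ((0, 0), (5, 0), (0, 5))])
    k, report = select_k(X, (2, 8), B=20, seed=1)
    assert k == 3
    assert report.attrs["votes"] == [3, 3, 3]


def test_select_k_trivial_range_and_errors():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 2))
    k, _ = select_k(X, (2, 2), B=5, seed=0)
    assert k == 2
    with pytest.raises(ValueError, match="n >="):
        select_k(X[:5], (2, 8), B=5)


# ------------------------------------------------------------------------- Fst
def brute_force_wc84(dosages, labels):
    """Scalar per-locus Weir-Cockerham components, written independently."""
    import math

    groups = sorted(set(labels))
    assert len(groups) == 2
    r = 2
    A = B = C = 0.0
    for locus in range(dosages.shape[1]):
        n, p, h = [], [], []
        for grp in groups:
            d = dosages[np.array(labels) == grp, locus]
            d = d[~np.isnan(d)]
            if len(d) < 2:
                break
            n.append(len(d))
            p.append(d.sum() / (2 * len(d)))
            h.append(np.mean(d == 1))
        else:
            nbar = (n[0] + n[1]) / 2
            pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
            if pbar <= 0 or pbar >= 1:
                continue
            nc = (r * nbar - (n[0] ** 2 + n[1] ** 2) / (r * nbar)) / (r - 1)
            s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A += a
            B += b
            C += c
    return A / (A + B + C)


def test_wc84_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for trial in range(10):
        dosages = rng.integers(0, 3, size=(30, 10)).astype(float)
        dosages[rng.random(dosages.shape) < 0.05] = np.nan
        labels = np.array([1] * 15 + [2] * 15)
        g = simulate_genotypes(30, 10, fst=0.0, seed=trial)  # container only
        g.dosages = dosages
        theta = wc84_fst(g, labels).theta
        assert theta == pytest.approx(brute_force_wc84(dosages, labels), abs=1e-10)


def test_identical_clusters_give_theta_near_zero():
    rng = np.random.default_rng(1)
    half = rng.integers(0, 3, size=(40, 50)).astype(float)
    g = simulate_genotypes(80, 50, fst=0.0, seed=0)
    g.dosages = np.vstack([half, half])  # second cluster identical
    labels = np.array([1] * 40 + [2] * 40)
    assert abs(wc84_fst(g, labels).theta) < 0.02


def test_alternate_fixation_gives_theta_one():
    g = simulate_genotypes(40, 30, fst=0.0, seed=0)
    g.dosages = np.vstack([np.zeros((20, 30)), np.full((20, 30), 2.0)])
    labels = np.array([1] * 20 + [2] * 20)
    assert wc84_fst(g, labels).theta == pytest.approx(1.0)


def test_fst_requires_exactly_two_clusters():
    g = simulate_genotypes(30, 10, fst=0.0, seed=0)
    with pytest.raises(ValueError, match="exactly 2"):
        wc84_fst(g, np.array([1] * 10 + [2] * 10 + [3] * 10))


def test_balding_nichols_target_recovered():
    thetas = [
        wc84_fst(
            (g := simulate_genotypes(200, 2000, fst=0.05, n_subpops=2, seed=s)),
            g.truth["subpop_labels"],
        ).theta
        for s in range(5)
    ]
    assert all(0.03 <= t <= 0.07 for t in thetas)
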