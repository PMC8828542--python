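"""Population-level structure: PCA, complete-linkage clustering with a
data-driven cluster count, and Weir–Cockerham (1984) pairwise Fst.

Genotypic analyses operate on the mean-imputed, centered dosage matrix;
phenotypic analyses on the per-genotype trait matrix (optionally scaled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from rootpheno.genotypes import GenotypeMatrix

__all__ = ["ClusterAssignment", "FstResult", "pca", "hcluster", "select_k", "wc84_fst"]


@dataclass
class ClusterAssignment:
    """Labels 1..k plus the linkage tree they were cut from."""

    ids: list[str]
    labels: np.ndarray
    k: int
    linkage_matrix: np.ndarray
    metric: str = "euclidean"
    method: str = "complete"
    k_report: pd.DataFrame | None = None

    def to_newick(self) -> str:
        """Export the linkage tree as a Newick string (heights as lengths)."""
        tree = to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


@dataclass
class FstResult:
    """Weir–Cockerham variance components and the multi-locus estimate."""

    theta: float
    a: np.ndarray  # among-population component, per locus
    b: np.ndarray  # among-individual-within-population
    c: np.ndarray  # within-individual
    loci_used: np.ndarray  # indices of informative loci
    n_loci_total: int


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, GenotypeMatrix):
        return data.imputed(), list(data.individual_ids)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(i) for i in data.index]
    arr = np.asarray(data, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def pca(
    data, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a samples x features matrix.

    Missing entries are mean-imputed per feature and the matrix is centered
    (unit-scaled if ``scale``); constant features are dropped with a
    warning. Returns ``(scores, loadings, explained_fraction)`` with
    components ordered by decreasing explained variance (signs arbitrary).
    """
    X, _ = _as_matrix(data)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 rows and 1 column")
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = col_mean[idx[1]]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} constant feature(s) dropped before PCA")
    X = X[:, keep] - X[:, keep].mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    n_components = min(n_components, min(X.shape) - (X.shape[0] <= X.shape[1]))
    n_components = max(n_components, 1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    explained = var / var.sum()
    scores = U * s
    return scores[:, :n_components], Vt[:n_components].T, explained[:n_components]


def hcluster(data, k: int, scale: bool = False) -> ClusterAssignment:
    """Complete-linkage agglomeration on Euclidean distances, cut at ``k``.

    Deterministic given the input order; at equal merge heights SciPy
    merges the earliest-formed pair, which for identical points means
    duplicates merge first at height 0.
    """
    X, ids = _as_matrix(data)
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = col_mean[idx[1]]
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} out of range for n={X.shape[0]}")
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(ids=ids, labels=labels, k=int(labels.max()), linkage_matrix=Z)


def _gap_statistic(
    X: np.ndarray, ks: list[int], B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Tibshirani gap statistic on complete-linkage clusterings."""

    def log_wk(M: np.ndarray, k: int) -> float:
        lab = fcluster(linkage(M, method="complete"), t=k, criterion="maxclust")
        w = 0.0
        for c in np.unique(lab):
            pts = M[lab == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return np.log(max(w, 1e-300))

    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = np.empty((B, len(ks)))
    for b in range(B):
        M = rng.uniform(lo, hi, size=X.shape)
        ref[b] = [log_wk(M, k) for k in ks]
    obs = np.array([log_wk(X, k) for k in ks])
    gap = ref.mean(axis=0) - obs
    sk = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    choice = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            choice = ks[i]
            break
    return gap, sk, choice


def select_k(
    data,
    k_range: range | tuple[int, int] = (2, 10),
    B: int = 50,
    scale: bool = False,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by majority vote of internal indices.

    The panel — silhouette, Calinski–Harabasz, and the gap statistic with
    ``B`` uniform reference sets — is a reduced version of the large
    index-comparison packages used in practice; each index votes for its
    preferred k over complete-linkage cuts and the full per-index table is
    returned for audit. Vote ties resolve to the smaller k (flagged in the
    report attributes).
    """
    X, _ = _as_matrix(data)
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        ks = list(range(k_range[0], k_range[1] + 1))
    if X.shape[0] < max(ks) + 1:
        raise ValueError(f"need n >= {max(ks) + 1} items for k_range up to {max(ks)}")
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)

    Z = linkage(X, method="complete")
    sil, ch = [], []
    for k in ks:
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            sil.append(np.nan)
            ch.append(np.nan)
        else:
            sil.append(silhouette_score(X, lab))
            ch.append(calinski_harabasz_score(X, lab))
    gap, sk, gap_choice = _gap_statistic(X, ks, B, rng)

    report = pd.DataFrame(
        {"k": ks, "silhouette": sil, "calinski_harabasz": ch, "gap": gap, "gap_se": sk}
    ).set_index("k")
    votes = [
        int(report["silhouette"].idxmax()),
        int(report["calinski_harabasz"].idxmax()),
        int(gap_choice),
    ]
    report.attrs["votes"] = votes
    counts = pd.Series(votes).value_counts()
    winners = counts[counts == counts.max()].index
    k_best = int(min(winners))
    report.attrs["tie"] = len(winners) > 1
    return k_best, report


def wc84_fst(g: GenotypeMatrix, assignment: ClusterAssignment | np.ndarray) -> FstResult:
    """Pairwise Weir–Cockerham (1984) Fst between two clusters.

    Per biallelic locus the among-population (a), among-individual (b) and
    within-individual (c) variance components are computed from allele
    frequencies, per-cluster sample sizes and observed heterozygosity
    (dosage-1 counts); the multi-locus estimate is the ratio of averages
    ``theta = sum(a) / sum(a + b + c)``. Monomorphic and zero-variance loci
    are excluded, as are loci with fewer than 2 genotyped individuals in
    either cluster.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"pairwise Fst needs exactly 2 clusters, got {len(groups)}")
    D = g.dosages
    r = 2

    n_i = np.stack([(~np.isnan(D[labels == grp])).sum(axis=0) for grp in groups])  # (2, L)
    with np.errstate(invalid="ignore"):
        p_i = np.stack([np.nanmean(D[labels == grp], axis=0) / 2.0 for grp in groups])
        # observed heterozygote fraction among *genotyped* individuals
        h_i = np.stack([(D[labels == grp] == 1.0).sum(axis=0) for grp in groups]) / n_i

    ok = (n_i >= 2).all(axis=0)
    if not ok.any():
        raise ValueError("every locus has a cluster with < 2 genotyped individuals")

    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    denom = a + b + c
    use = ok & poly & np.isfinite(denom) & (denom != 0)
    loci = np.where(use)[0]
    if loci.size == 0:
        raise ValueError("no informative loci for Fst")
    theta = float(a[use].sum() / denom[use].sum())
    return FstResult(
        theta=theta, a=a, b=b, c=c, loci_used=loci, n_loci_total=g.n_sites
    )
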