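"""Coexpression module detection, eigengenes, trait filtering, preservation.

Two complementary clustering schemes are provided over the topological
overlap matrix (TOM) of an unsigned weighted coexpression network:

* agglomerative — average-linkage hierarchical clustering on dissTOM
  (1 - TOM) with a static cut; each gene lands in at most one module;
* divisive — recursive k-medoids on shortest-path distances over a
  sparsified dissTOM graph; multiscale, a gene may appear in one module
  per scale.

Modules are summarized by their eigengene (first principal component of the
gene-standardized submatrix) and filtered by Pearson correlation with a
trait; the false positive rate of the filter is calibrated with random gene
sets.  Cross-dataset module preservation is scored with a permutation
Z-summary (density + connectivity), preserved when Z-summary > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import squareform

from .errors import ConfigError, DataError


# ----------------------------------------------------------------- adjacency

def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |corr(i, j)|^beta, zero diagonal.

    ``expr`` is genes x samples.  Pearson invariance makes the result
    independent of per-gene affine rescaling.
    """
    if expr.shape[1] < 3:
        raise DataError("need at least 3 samples for correlations")
    if beta < 1:
        raise ConfigError("beta must be >= 1")
    corr = np.corrcoef(expr.to_numpy(float))
    if np.isnan(corr).any():
        raise DataError("NaN correlation (zero-variance gene?)")
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM[i,j] = (sum_u a[i,u] a[u,j] + a[i,j]) / (min(k_i, k_j) + 1 - a[i,j])
    with k_i the weighted connectivity; diagonal set to 1.
    """
    a = adj.to_numpy(float)
    if not np.allclose(a, a.T):
        raise DataError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise DataError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 0:
        raise DataError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------- clustering

@dataclass
class ModuleAssignment:
    """Gene -> module assignment from one clustering scheme.

    ``modules`` maps module id to its gene set; divisive modules additionally
    carry their scale (tree depth) in ``scale`` and are named ``D<k>@<scale>``.
    """

    scheme: str
    modules: dict[str, set[str]] = field(default_factory=dict)
    scale: dict[str, int] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)


def _name_modules(clusters: list[set[str]], prefix: str = "M") -> dict[str, set[str]]:
    ordered = sorted(clusters, key=lambda c: (-len(c), min(c)))
    return {f"{prefix}{i + 1:02d}": c for i, c in enumerate(ordered)}


def cluster_agglomerative(
    tom: pd.DataFrame, min_module_size: int = 20, cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage hierarchical clustering on dissTOM with a static cut.

    Clusters smaller than ``min_module_size`` go to the unassigned pool.
    Module ids are deterministic: ordered by size, then by smallest gene id.
    """
    if not 0 < cut_height < 1:
        raise ConfigError("cut_height must lie in (0, 1)")
    if min_module_size < 2:
        raise ConfigError("min_module_size must be >= 2")
    genes = list(tom.index)
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    assignment = ModuleAssignment(scheme="agglomerative")
    clusters: list[set[str]] = []
    for lab in np.unique(labels):
        members = {genes[i] for i in np.flatnonzero(labels == lab)}
        if len(members) >= min_module_size:
            clusters.append(members)
        else:
            assignment.unassigned |= members
    assignment.modules = _name_modules(clusters)
    return assignment


def _kmedoids(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids (PAM-style alternation) on a distance matrix.

    Initialization: the 1-medoid first, then farthest-point seeding; all ties
    broken by the lowest index so the result is reproducible.
    """
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        d_near[medoids] = -1.0
        medoids.append(int(np.argmax(d_near)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                new.append(medoids[c])
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(within)]))
        new = sorted(set(new))
        while len(new) < k:  # collapsed medoids: keep previous extras
            for m in medoids:
                if m not in new:
                    new.append(m)
                    break
            new = sorted(new)
        if new == medoids:
            break
        medoids = new
    return np.argmin(dist[:, medoids], axis=1)


def _mean_within(dist: np.ndarray, labels: np.ndarray) -> float:
    """Pooled mean over all within-cluster pairwise shortest-path distances."""
    total, count = 0.0, 0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        sub = dist[np.ix_(members, members)]
        total += sub.sum() / 2.0
        count += len(members) * (len(members) - 1) // 2
    return total / count if count else 0.0


def cluster_divisive_kmedoids(
    tom: pd.DataFrame,
    k_max: int = 4,
    min_module_size: int = 10,
    improvement_tol: float = 0.05,
    sparsity: float = 0.05,
) -> ModuleAssignment:
    """Multiscale divisive clustering on shortest-path distances.

    The dissTOM graph is sparsified to the strongest ``sparsity`` fraction of
    edges; shortest-path distances are computed per connected component and
    each component seeds a branch of the cluster tree.  At every node the
    best k in 2..k_max medoid split is accepted when the pooled mean
    within-cluster shortest-path distance improves by more than
    ``improvement_tol`` relative to the parent.  Accepted levels emit modules
    tagged with their scale; a gene belongs to at most one module per scale.
    """
    if k_max < 2:
        raise ConfigError("k_max must be >= 2")
    genes = np.array(tom.index)
    n = len(genes)
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, np.inf)

    iu = np.triu_indices(n, k=1)
    weights = diss[iu]
    n_keep = max(int(round(sparsity * len(weights))), n - 1 if n > 1 else 0)
    n_keep = min(n_keep, len(weights))
    keep = np.argsort(weights, kind="stable")[:n_keep]
    rows, cols = iu[0][keep], iu[1][keep]
    graph = csr_matrix(
        (np.concatenate([weights[keep], weights[keep]]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n))

    n_comp, comp = connected_components(graph, directed=False)
    assignment = ModuleAssignment(scheme="divisive")
    counter = 0

    def emit(indices: np.ndarray, scale: int) -> None:
        nonlocal counter
        if len(indices) < min_module_size:
            return
        counter += 1
        name = f"D{counter}@{scale}"
        assignment.modules[name] = set(genes[indices].tolist())
        assignment.scale[name] = scale

    def split(indices: np.ndarray, dist: np.ndarray, scale: int) -> None:
        if len(indices) < 2 * 2:  # nothing meaningful to split
            return
        parent = _mean_within(dist, np.zeros(len(indices), dtype=int))
        if parent <= 0:
            return
        best_labels, best_score = None, np.inf
        for k in range(2, min(k_max, len(indices) - 1) + 1):
            labels = _kmedoids(dist, k)
            if len(np.unique(labels)) < 2:
                continue
            score = _mean_within(dist, labels)
            if score < best_score:
                best_labels, best_score = labels, score
        if best_labels is None:
            return
        if (parent - best_score) / parent <= improvement_tol:
            return
        for c in np.unique(best_labels):
            sub = np.flatnonzero(best_labels == c)
            emit(indices[sub], scale + 1)
            split(indices[sub], dist[np.ix_(sub, sub)], scale + 1)

    for c in range(n_comp):
        indices = np.flatnonzero(comp == c)
        emit(indices, 0)
        if len(indices) < 2:
            continue
        dist = dijkstra(graph, directed=False, indices=indices)[:, indices]
        split(indices, dist, 0)
    return assignment


# ---------------------------------------------------------------- eigengenes

@dataclass
class Eigengene:
    module_id: str
    values: pd.Series  # per sample
    variance_explained: float


def module_eigengene(expr: pd.DataFrame, module: set[str],
                     module_id: str = "module") -> Eigengene:
    """First principal component of the gene-standardized module submatrix.

    The loading is unit-norm; the sign is fixed so the average
    gene-eigengene correlation is non-negative.
    """
    present = sorted(set(module) & set(expr.index))
    if len(present) < 2:
        raise DataError(f"module {module_id!r} has fewer than 2 genes in the matrix")
    x = expr.loc[present].to_numpy(float)
    x = (x - x.mean(axis=1, keepdims=True))
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = vt[0]
    if u[:, 0].mean() < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return Eigengene(module_id, pd.Series(eig, index=expr.columns), var_explained)


@dataclass
class TraitCorrelation:
    module_id: str
    r: float
    p: float
    passes: bool


def module_trait_correlation(
    eig: Eigengene, trait: pd.Series, p_threshold: float = 1e-3,
) -> TraitCorrelation:
    """Pearson correlation between a module eigengene and the trait.

    Two-sided P from the t-distribution with n-2 df; ``passes`` applies the
    filter threshold (default P < 1e-3).
    """
    common = eig.values.index.intersection(trait.index)
    if len(common) < 4:
        raise DataError("need at least 4 matching samples")
    t = trait.loc[common].to_numpy(float)
    if np.ptp(t) == 0:
        raise DataError("trait is constant")
    r, p = stats.pearsonr(eig.values.loc[common].to_numpy(float), t)
    return TraitCorrelation(eig.module_id, float(r), float(p), bool(p < p_threshold))


# ----------------------------------------------------------- FPR calibration

def fpr_from_counts(false_positives: int, true_negatives: int) -> float:
    """false positive rate = FP / (FP + TN)."""
    return false_positives / (false_positives + true_negatives)


def format_fpr(fpr: float) -> str:
    """Display an FPR at one significant figure (0.102 -> '0.1')."""
    return f"{fpr:.1g}"


def calibrate_fpr(
    expr: pd.DataFrame,
    trait: pd.Series,
    n_sets: int = 1000,
    size_range: tuple[int, int] = (20, 500),
    p_threshold: float = 1e-3,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Negative-control calibration of the eigengene-trait filter.

    Draws ``n_sets`` random gene sets with sizes uniform over ``size_range``,
    correlates each eigengene with the trait, and reports
    FP / (FP + TN) at ``p_threshold`` together with the per-set table.
    """
    import logging
    if n_sets < 100:
        logging.getLogger(__name__).warning(
            "n_sets=%d < 100: unstable FPR estimate", n_sets)
    rng = np.random.default_rng(seed)
    genes = np.array(expr.index)
    hi = min(size_range[1], len(genes))
    lo = min(size_range[0], hi)
    rows = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(genes, size=size, replace=False).tolist())
        eig = module_eigengene(expr, members, f"random_{i + 1}")
        tc = module_trait_correlation(eig, trait, p_threshold)
        rows.append((tc.module_id, size, tc.r, tc.p, tc.passes))
    table = pd.DataFrame(rows, columns=["set_id", "size", "r", "p", "passes"])
    fp = int(table["passes"].sum())
    return fpr_from_counts(fp, n_sets - fp), table


# -------------------------------------------------------------- preservation

@dataclass
class PreservationResult:
    module_id: str
    z_density: float
    z_connectivity: float
    z_summary: float
    preserved: bool


def _module_stats(ref: np.ndarray, test: np.ndarray, idx: np.ndarray,
                  beta: float) -> tuple[float, float]:
    """Density and connectivity statistics for one gene-index set.

    Density: mean within-set adjacency in the test data.  Connectivity:
    correlation of the intramodular connectivity vectors between datasets.
    """
    a_ref = np.abs(np.corrcoef(ref[idx])) ** beta
    a_test = np.abs(np.corrcoef(test[idx])) ** beta
    np.fill_diagonal(a_ref, 0.0)
    np.fill_diagonal(a_test, 0.0)
    m = len(idx)
    density = a_test.sum() / (m * (m - 1))
    k_ref, k_test = a_ref.sum(axis=1), a_test.sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_ref, k_test)[0, 1])
    return float(density), conn


def module_preservation(
    modules: dict[str, set[str]],
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    beta: float = 1.0,
    min_shared: int = 10,
) -> list[PreservationResult]:
    """Permutation Z-summary preservation of reference modules in test data.

    For each module with >= ``min_shared`` genes shared between datasets, the
    density and connectivity statistics are converted to Z-scores against
    ``n_perm`` random gene sets of equal size from the shared universe, and
    Z-summary is their mean.  Preserved when Z-summary > 2.  Modules with too
    few shared genes are skipped with a warning.
    """
    import logging
    log = logging.getLogger(__name__)
    shared = sorted(set(expr_ref.index) & set(expr_test.index))
    ref = expr_ref.loc[shared].to_numpy(float)
    test = expr_test.loc[shared].to_numpy(float)
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)

    results = []
    for name, members in modules.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos))
        if len(idx) < min_shared:
            log.warning("module %s: only %d shared genes, skipped", name, len(idx))
            continue
        d_obs, c_obs = _module_stats(ref, test, idx, beta)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for i in range(n_perm):
            rand = rng.choice(len(shared), size=len(idx), replace=False)
            null_d[i], null_c[i] = _module_stats(ref, test, rand, beta)

        def z(obs: float, null: np.ndarray) -> float:
            sd = null.std(ddof=1)
            diff = obs - null.mean()
            if sd < 1e-12:
                return 0.0 if abs(diff) < 1e-12 else float(np.sign(diff)) * np.inf
            return float(diff / sd)

        zd, zc = z(d_obs, null_d), z(c_obs, null_c)
        zs = (zd + zc) / 2.0
        results.append(PreservationResult(name, zd, zc, zs, bool(zs > 2)))
    return results
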