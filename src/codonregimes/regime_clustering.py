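"""Hypothesizing mutation-bias regimes from codon usage.

Genes evolving under different non-adaptive nucleotide biases are
hypothesized by (1) correspondence analysis (CA) of per-gene sense-codon
frequencies, (2) CLARA k-medoids clustering on the first few principal
coordinates, and (3) labeling clusters by ascending median GC3 — the
cluster with the lower median GC3 is ``lower_gc3``.

CA is the chi-square-metric SVD of the standardized residuals of the
correspondence matrix; rows are per-gene frequency profiles so gene length
does not weight the decomposition. PAM is the classic BUILD+SWAP k-medoids
with Euclidean distance; CLARA runs PAM on random subsets and keeps the
medoid set with the lowest mean dissimilarity over the full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import CodonCountTable
from .genetic_code import SENSE_CODONS

LOWER = "lower_gc3"
HIGHER = "higher_gc3"


@dataclass
class CAResult:
    row_coordinates: np.ndarray  # (n_rows, d) principal coordinates
    singular_values: np.ndarray  # (d,)
    total_inertia: float
    dropped_columns: list[int]


@dataclass
class RegimeAssignment:
    """Per-gene cluster label plus the CA coordinates and medoids behind it."""

    gene_ids: list[str]
    labels: np.ndarray  # (n_genes,) of strings
    medoid_gene_ids: list[str]
    k: int
    median_gc3_per_cluster: dict[str, float]
    delta_median_gc3: float
    ca_coordinates: np.ndarray | None = None
    label_names: list[str] = field(default_factory=list)

    def regime_index(self) -> np.ndarray:
        """Integer regime per gene, ordered by ascending median GC3."""
        order = self.label_names or sorted(set(self.labels))
        mapping = {name: i for i, name in enumerate(order)}
        return np.array([mapping[l] for l in self.labels], dtype=np.int64)


def correspondence_analysis(frequency_matrix: np.ndarray, n_components: int = 4) -> CAResult:
    """Correspondence analysis of a nonnegative table.

    Rows are normalized to profiles (sum 1) first, equalizing row masses so
    long genes do not dominate; coordinates are therefore invariant to
    rescaling any row by a positive constant. Returns row principal
    coordinates (standard coordinates scaled by the singular values),
    singular values, and total inertia (= chi-square statistic of the
    row-normalized table / its grand total). Columns with zero total mass
    are dropped first.
    """
    X = np.asarray(frequency_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be a 2-D table")
    if np.any(X < 0):
        raise ValueError("input must be nonnegative")
    row_sums = X.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("every row must have positive sum")
    col_mass_raw = X.sum(axis=0)
    dropped = np.flatnonzero(col_mass_raw == 0).tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-mass columns from CA")
        X = X[:, col_mass_raw > 0]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 usable columns")
    X = X / X.sum(axis=1, keepdims=True)  # row profiles: equal row masses

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    # standardized residuals S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float(np.sum(sv**2))
    d = min(n_components, len(sv))
    # row principal coordinates F = D_r^{-1/2} U Sigma
    F = (U[:, :d] / np.sqrt(r)[:, None]) * sv[:d]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(d):
        col = F[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            F[:, j] = -col
    return CAResult(
        row_coordinates=F,
        singular_values=sv[:d].copy(),
        total_inertia=total_inertia,
        dropped_columns=dropped,
    )


def _pairwise_dist(points: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    from scipy.spatial.distance import cdist

    if idx is None:
        return cdist(points, points)
    return cdist(points, points[idx])


def pam(points: np.ndarray, k: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning Around Medoids (BUILD + SWAP), Euclidean distance.

    Returns (medoid indices, labels, total cost). SWAP iterates to a local
    optimum, always taking the best improving swap; ties break toward the
    lowest point index. Deterministic (no randomness is required).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    D = _pairwise_dist(pts)

    # BUILD: greedily add the medoid giving the largest cost decrease
    medoids: list[int] = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, D[:, best])

    med = np.array(sorted(medoids))
    while True:
        Dm = D[:, med]  # (n, k)
        order = np.argsort(Dm, axis=1)
        nearest_d = Dm[np.arange(n), order[:, 0]]
        cost = nearest_d.sum()
        second_d = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest_m = order[:, 0]

        best_delta, best_swap = 1e-12, None
        in_med = np.zeros(n, dtype=bool)
        in_med[med] = True
        candidates = np.flatnonzero(~in_med)
        for mi in range(k):
            served = nearest_m == mi
            # if medoid mi is removed, points it serves fall back to their
            # second-nearest medoid unless the candidate h is closer
            base = np.where(served, second_d, nearest_d)
            for h in candidates:
                new_d = np.minimum(base, D[:, h])
                delta = cost - new_d.sum()
                # strict > keeps the first (lowest mi, then lowest h) on ties
                if delta > best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        med[mi] = h
        med = np.sort(med)

    labels = np.argmin(D[:, med], axis=1)
    total_cost = float(D[np.arange(n), med[labels]].sum())
    return med, labels, total_cost


def clara(
    points: np.ndarray,
    k: int,
    n_subsets: int = 5,
    subset_fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """CLARA: PAM on random subsets, scored by full-data mean dissimilarity.

    Each subset (sampled without replacement) is clustered with PAM; all
    points are then assigned to the nearest medoid and the medoid set with
    the lowest mean dissimilarity wins. Deterministic given ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must be in (0, 1]")
    m = max(int(round(subset_fraction * n)), 1)
    if m < k:
        raise ValueError(f"subset size {m} smaller than k={k}")
    rng = np.random.default_rng(seed)

    from scipy.spatial.distance import cdist

    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_subsets):
        sub = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        med_sub, _, _ = pam(pts[sub], k)
        med = sub[med_sub]
        dists = cdist(pts, pts[med])
        mean_diss = float(dists.min(axis=1).mean())
        if best is None or mean_diss < best[0]:
            best = (mean_diss, med)
    mean_diss, med = best
    labels = np.argmin(cdist(pts, pts[med]), axis=1)
    return med, labels, mean_diss


def cluster_genes(
    count_table: CodonCountTable,
    k: int = 2,
    seed: int | None = None,
    n_components: int = 4,
    n_subsets: int = 5,
    subset_fraction: float = 0.5,
) -> RegimeAssignment:
    """Full regime-hypothesis pipeline: frequencies → CA(4) → CLARA(k) → label.

    Cluster labels are assigned by ascending median GC3; with k=2 these are
    ``lower_gc3`` / ``higher_gc3``, with k=3 an intermediate ``mid_gc3``
    label is inserted.
    """
    if count_table.n_genes < 2 * k:
        raise ValueError("need at least 2k genes")
    ca = correspondence_analysis(count_table.frequencies(), n_components)
    med, raw_labels, _ = clara(
        ca.row_coordinates, k, n_subsets=n_subsets, subset_fraction=subset_fraction, seed=seed
    )
    medians = np.array(
        [np.median(count_table.gc3[raw_labels == j]) for j in range(k)]
    )
    order = np.argsort(medians, kind="stable")
    if k == 2:
        names = [LOWER, HIGHER]
    elif k == 3:
        names = [LOWER, "mid_gc3", HIGHER]
    else:
        names = [f"gc3_rank{j}" for j in range(k)]
    name_of_raw = {int(raw): names[rank] for rank, raw in enumerate(order)}
    labels = np.array([name_of_raw[int(j)] for j in raw_labels])
    med_by_name = {names[rank]: float(medians[raw]) for rank, raw in enumerate(order)}
    return RegimeAssignment(
        gene_ids=list(count_table.gene_ids),
        labels=labels,
        medoid_gene_ids=[count_table.gene_ids[i] for i in med],
        k=k,
        median_gc3_per_cluster=med_by_name,
        delta_median_gc3=float(med_by_name[names[-1]] - med_by_name[names[0]]),
        ca_coordinates=ca.row_coordinates,
        label_names=names,
    )


def ks_compare_gc3(gc3_lower: np.ndarray, gc3_higher: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test between GC3 samples."""
    a = np.asarray(gc3_lower, dtype=float)
    b = np.asarray(gc3_higher, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
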