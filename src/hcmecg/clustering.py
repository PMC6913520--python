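"""Cohort feature assembly, unsupervised feature selection and clustering.

The phenotype-discovery stage is fully unsupervised: nothing in this module
may see ground-truth labels or clinical covariates (labels exist only in the
synthetic cohort object and in explicit evaluation calls such as
:func:`compare_partitions`).

Feature vectors combine, per requested lead, the Hermite QRS descriptor
(c0..c{N-1} plus the fitted width sigma) and — in ``qrs_plus_t`` mode — the
T-wave polarity (kept at +-1, unscaled) and amplitude.  Continuous features
are z-scored across the cohort.

Default clustering is agglomerative with Ward linkage (deterministic), the
cluster count chosen by the silhouette maximum over k = 2..6 with ties
broken toward the smaller k.  A seeded PAM-style k-medoids is available as
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "CohortFeatureMatrix",
    "ClusterResult",
    "assemble_features",
    "select_features",
    "cluster",
    "compare_partitions",
]


@dataclass
class CohortFeatureMatrix:
    """Subject-by-feature matrix with its normalization record."""

    subject_ids: list
    feature_names: list
    values: np.ndarray               # [n_subjects, n_features], normalized
    center: np.ndarray               # per-feature center (0 for untouched cols)
    scale: np.ndarray                # per-feature scale (1 for untouched cols)
    selection: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")

    def denormalized(self) -> np.ndarray:
        return self.values * self.scale + self.center

    def subset(self, keep_idx, selection: dict) -> "CohortFeatureMatrix":
        keep_idx = list(keep_idx)
        return CohortFeatureMatrix(
            self.subject_ids,
            [self.feature_names[i] for i in keep_idx],
            self.values[:, keep_idx],
            self.center[keep_idx],
            self.scale[keep_idx],
            selection,
        )


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    validity_by_k: dict
    seed: int
    feature_subset: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        k_found = np.unique(self.labels)
        if not (np.all(k_found >= 0) and np.all(k_found < self.k)
                and len(k_found) == self.k):
            raise ValueError("labels must cover 0..k-1 with no empty cluster")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def assemble_features(fits: pd.DataFrame, biomarkers: pd.DataFrame,
                      leads, mode: str = "qrs_plus_t") -> CohortFeatureMatrix:
    """Build the cohort matrix from the Hermite-fit and biomarker tables.

    ``fits``: columns subject_id, lead, sigma_ms, c0..c{N-1} (wide).
    ``biomarkers``: long format with columns subject_id, lead, biomarker,
    value.  ``qrs_only`` takes c0..c{N-1} and sigma per lead; ``qrs_plus_t``
    adds t_polarity (unscaled +-1) and t_amplitude.  Continuous columns are
    z-scored; the center/scale pair is stored for exact de-normalization.
    """
    if mode not in ("qrs_only", "qrs_plus_t"):
        raise ValueError("mode must be 'qrs_only' or 'qrs_plus_t'")
    leads = list(leads)
    subject_ids = sorted(fits["subject_id"].unique())
    coeff_cols = sorted(c for c in fits.columns if c.startswith("c")
                        and c[1:].isdigit())

    fits_ix = fits.set_index(["subject_id", "lead"]).sort_index()
    missing = [(s, l) for s in subject_ids for l in leads
               if (s, l) not in fits_ix.index]
    if mode == "qrs_plus_t":
        bm_ix = biomarkers.set_index(["subject_id", "lead", "biomarker"])["value"]
        missing += [(s, l) for s in subject_ids for l in leads
                    if (s, l, "t_polarity") not in bm_ix.index
                    or (s, l, "t_amplitude_mv") not in bm_ix.index]
    if missing:
        subjects = sorted({s for s, _ in missing})
        raise ValueError(f"subjects with missing lead data: {subjects}")

    names, cols, binary = [], [], []
    for lead in leads:
        block = fits_ix.loc[[(s, lead) for s in subject_ids]]
        for c in coeff_cols:
            names.append(f"{lead}:{c}")
            cols.append(block[c].to_numpy(float))
            binary.append(False)
        names.append(f"{lead}:sigma")
        cols.append(block["sigma_ms"].to_numpy(float))
        binary.append(False)
        if mode == "qrs_plus_t":
            names.append(f"{lead}:t_polarity")
            cols.append(np.array([bm_ix[(s, lead, "t_polarity")]
                                  for s in subject_ids], float))
            binary.append(True)
            names.append(f"{lead}:t_amplitude")
            cols.append(np.array([bm_ix[(s, lead, "t_amplitude_mv")]
                                  for s in subject_ids], float))
            binary.append(False)

    raw = np.column_stack(cols)
    center = np.zeros(raw.shape[1])
    scale = np.ones(raw.shape[1])
    for j in range(raw.shape[1]):
        if binary[j]:
            continue  # polarity stays at +-1, unscaled
        mu = raw[:, j].mean()
        sd = raw[:, j].std()
        center[j] = mu
        scale[j] = sd if sd > 0 else 1.0
    values = (raw - center) / scale
    return CohortFeatureMatrix(subject_ids, names, values, center, scale)


# ---------------------------------------------------------------------------
# unsupervised feature selection
# ---------------------------------------------------------------------------

def _knn_graph(X, k_neighbors=5):
    W = kneighbors_graph(X, n_neighbors=min(k_neighbors, X.shape[0] - 1),
                         mode="connectivity")
    W = ((W + W.T) > 0).astype(float).toarray()
    return W, W.sum(axis=1)


def _laplacian_score(f, W, d):
    """Laplacian relevance of one feature on a fixed kNN graph.

    Lower = the feature varies smoothly over the neighborhood graph, i.e.
    it carries the cohort's local structure; a pure-noise feature scores
    near the value of its own permutation null.
    """
    f = f - (f @ d) / d.sum()
    denom = f @ (d * f)
    if denom <= 1e-12:
        return np.inf
    return (f @ (d * f) - f @ (W @ f)) / denom


def select_features(matrix: CohortFeatureMatrix,
                    method_config: dict | None = None) -> CohortFeatureMatrix:
    """Unsupervised column selection; never sees any label information.

    Default ``variance_redundancy``: drop (near-)constant columns, then for
    any pair with |Pearson r| > ``max_correlation`` (0.95) drop the later
    column.  ``laplacian`` additionally drops columns whose Laplacian score
    is not clearly below its own permutation null (a pure-noise column
    carries no neighborhood structure and fails that comparison).
    ``none`` returns the matrix unchanged.
    """
    cfg = dict(method_config or {})
    method = cfg.get("method", "laplacian")
    if method == "none":
        return matrix.subset(range(len(matrix.feature_names)),
                             {"method": "none",
                              "retained": list(matrix.feature_names)})
    if method not in ("variance_redundancy", "laplacian"):
        raise ValueError(f"unknown selection method {method!r}")

    X = matrix.values
    min_var = cfg.get("min_variance", 1e-10)
    max_corr = cfg.get("max_correlation", 0.95)
    binary = [bool(np.isin(np.unique(X[:, j]), (-1.0, 1.0)).all()
                   and matrix.scale[j] == 1.0 and matrix.center[j] == 0.0)
              for j in range(X.shape[1])]
    keep = [j for j in range(X.shape[1]) if X[:, j].var() > min_var]

    # pairwise-redundancy removal applies to continuous features; the +-1
    # categorical polarity columns are kept as a block (Pearson r between
    # binary indicators over-states their exchangeability)
    kept: list[int] = []
    for j in keep:
        redundant = False
        if not binary[j]:
            for i in kept:
                if binary[i]:
                    continue
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                if abs(r) > max_corr:
                    redundant = True
                    break
        if not redundant:
            kept.append(j)

    if method == "laplacian" and len(kept) > 1:
        rng = np.random.default_rng(cfg.get("seed", 0))
        n_perm = cfg.get("n_permutations", 50)
        alpha = cfg.get("alpha", 0.05)
        Xk = X[:, kept]
        final = []
        for jj, j in enumerate(kept):
            # leave-one-out graph: a feature must be smooth over the
            # neighborhood structure defined by the OTHER features, else a
            # high-variance noise column would validate itself
            others = np.delete(Xk, jj, axis=1)
            W, d = _knn_graph(others, cfg.get("k_neighbors", 5))
            obs = _laplacian_score(Xk[:, jj], W, d)
            null = np.array([
                _laplacian_score(rng.permutation(Xk[:, jj]), W, d)
                for _ in range(n_perm)
            ])
            if obs < np.quantile(null, alpha):
                final.append(j)
        kept = final

    if not kept:
        raise ValueError("feature selection removed all features")
    return matrix.subset(kept, {
        "method": method,
        "retained": [matrix.feature_names[j] for j in kept],
        "config": cfg,
    })


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _kmedoids(X, k, rng, n_restarts=5, max_iter=100):
    """PAM-style k-medoids on Euclidean distances (seeded restarts)."""
    D = cdist(X, X)
    n = X.shape[0]
    best_cost, best_labels = np.inf, None
    for _ in range(n_restarts):
        medoids = list(rng.choice(n, size=k, replace=False))
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = []
            for c in range(k):
                members = np.nonzero(labels == c)[0]
                if members.size == 0:
                    new_medoids.append(medoids[c])
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids.append(int(members[np.argmin(within)]))
            if new_medoids == medoids:
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), np.asarray(medoids)[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def cluster(matrix: CohortFeatureMatrix, k_range=range(2, 7), seed: int = 0,
            algorithm: str = "ward") -> ClusterResult:
    """Partition the cohort; pick k by the silhouette maximum.

    ``ward`` (default) is deterministic; ``kmedoids`` uses seeded restarts.
    Silhouette ties break toward the smaller k.
    """
    X = matrix.values
    n = X.shape[0]
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("degenerate feature matrix: fewer than 2 distinct rows")
    k_range = [k for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n // 2:
        raise ValueError("k_range must lie within [2, n_subjects/2]")
    if algorithm not in ("ward", "kmedoids"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    rng = np.random.default_rng(seed)
    validity, labelings = {}, {}
    for k in k_range:
        if algorithm == "ward":
            lab = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
        else:
            lab = _kmedoids(X, k, rng)
        labelings[k] = lab
        validity[k] = float(silhouette_score(X, lab)) if len(np.unique(lab)) > 1 \
            else -1.0
    best_k = max(sorted(validity), key=lambda k: (validity[k], -k))
    labels = labelings[best_k]
    # relabel to 0..k-1 in order of first appearance (stable across reruns)
    _, labels = np.unique(labels, return_inverse=True)
    remap = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, l in enumerate(labels):
        if l not in remap:
            remap[l] = nxt
            nxt += 1
        out[i] = remap[l]
    return ClusterResult(out, int(best_k), validity, seed,
                         list(matrix.feature_names))


def compare_partitions(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same subjects."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))
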