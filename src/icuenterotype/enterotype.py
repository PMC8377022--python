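"""Enterotype discovery: Jensen-Shannon distances, PAM clustering, cluster
number selection by the Calinski-Harabasz index with silhouette support, and
PCoA embedding.

The clustering operates directly on the distance matrix.  PAM runs a
deterministic multi-start BUILD+SWAP (no seed needed), so repeated runs are
bit-identical.  The CH index for a distance-only dataset is evaluated on the
positive-eigenvalue PCoA coordinates, the common practice for non-Euclidean
dissimilarities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)

E1 = "ICU_E1"
E2 = "ICU_E2"

DEFAULT_E1_MARKERS = ("Bacteroides",)


def jsd_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Jensen-Shannon distance (sqrt of the divergence, log base 2)
    between samples; values live in [0, 1] and satisfy the metric axioms."""
    if table.mode != "relative":
        raise ValueError("JSD requires a relative-abundance table")
    values = table.values()
    condensed = pdist(values, metric=lambda p, q: jensenshannon(p, q, base=2))
    condensed = np.nan_to_num(condensed)  # identical rows give 0/0 -> 0
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class EnterotypePartition:
    k: int
    labels: np.ndarray  # integer cluster index per sample
    medoids: list[str]  # sample ids
    ids: list[str]
    ch: float | None = None
    si: float | None = None
    label_names: dict[int, str] = field(default_factory=dict)

    def named_labels(self) -> list[str]:
        if not self.label_names:
            return [f"cluster_{c}" for c in self.labels]
        return [self.label_names[int(c)] for c in self.labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.ids, "enterotype": self.named_labels()}
        ).set_index("sample_id", drop=False)


# -- PAM ---------------------------------------------------------------------

def _pam_objective(d: np.ndarray, medoids) -> float:
    return float(d[:, list(medoids)].min(axis=1).sum())


def _build_seed(d: np.ndarray, k: int) -> list[int]:
    """Classical BUILD: first medoid minimises total distance, each later one
    maximises the objective decrease.  Ties -> lowest index."""
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
        nearest = np.minimum(nearest, d[:, medoids[-1]])
    return sorted(medoids)


def _farthest_first_seed(d: np.ndarray, k: int) -> list[int]:
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dist = d[:, medoids].min(axis=1)
        dist[medoids] = -1
        medoids.append(int(np.argmax(dist)))
    return sorted(medoids)


_N_EXTRA_STARTS = 8
_START_STREAM_SEED = 0x5EED  # fixed internal stream: pam stays seedless


def _swap_descent(d: np.ndarray, medoids: list[int], k: int) -> np.ndarray:
    """Steepest-descent SWAP: repeatedly apply the single best
    (medoid, non-medoid) exchange until none lowers the objective."""
    n = d.shape[0]
    medoid_arr = np.array(sorted(medoids))
    while k < n:
        dist_to_medoids = d[:, medoid_arr]  # n x k
        order = np.argsort(dist_to_medoids, axis=1)
        nearest_val = dist_to_medoids[np.arange(n), order[:, 0]]
        if k > 1:
            second_val = dist_to_medoids[np.arange(n), order[:, 1]]
        else:
            second_val = np.full(n, np.inf)
        nearest_idx = order[:, 0]  # position within medoid_arr

        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoid_arr)
        for pos in range(k):
            owns = nearest_idx == pos
            # after removing medoid at `pos`, points it owned fall back to
            # their second-nearest unless the new medoid h is closer
            fallback = np.where(owns, second_val, nearest_val)
            # objective delta for every candidate h at once
            new_nearest = np.minimum(fallback[None, :], d[non_medoids])
            deltas = new_nearest.sum(axis=1) - nearest_val.sum()
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta = float(deltas[j])
                best_swap = (pos, int(non_medoids[j]))
        if best_swap is None:
            break
        pos, h = best_swap
        medoid_arr = np.sort(np.concatenate(
            [np.delete(medoid_arr, pos), [h]]))
    return medoid_arr


def pam_cluster(dm: DistanceMatrix, k: int) -> EnterotypePartition:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic multi-start BUILD+SWAP: the classical BUILD seeding, a
    farthest-first seeding, and a fixed battery of pseudo-random seedings
    (internal fixed stream) are each refined by steepest-descent SWAP; the
    lowest-objective solution wins.  The extra starts guard against the
    local optima the single-start heuristic is known to reach on small
    instances, at negligible cost for cohort-sized matrices.
    """
    d = dm.data
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")

    starts = [_build_seed(d, k), _farthest_first_seed(d, k)]
    stream = np.random.default_rng(_START_STREAM_SEED)
    for _ in range(_N_EXTRA_STARTS):
        starts.append(sorted(stream.choice(n, k, replace=False).tolist()))

    best_obj, best_medoids = np.inf, None
    seen: set[tuple[int, ...]] = set()
    for start in starts:
        key = tuple(start)
        if key in seen:
            continue
        seen.add(key)
        medoid_arr = _swap_descent(d, start, k)
        obj = _pam_objective(d, medoid_arr)
        if obj < best_obj - 1e-12:
            best_obj, best_medoids = obj, medoid_arr

    labels = np.argmin(d[:, best_medoids], axis=1)
    ids = list(dm.ids)
    return EnterotypePartition(
        k=k, labels=labels, medoids=[ids[m] for m in best_medoids], ids=ids)


def pam_objective(dm: DistanceMatrix, partition: EnterotypePartition) -> float:
    idx = {s: i for i, s in enumerate(dm.ids)}
    return _pam_objective(dm.data, [idx[m] for m in partition.medoids])


# -- ordination and cluster diagnostics --------------------------------------

@dataclass
class PcoaEmbedding:
    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaEmbedding:
    """Classical scaling of the distance matrix (negative eigenvalues clamped
    to zero and excluded from the explained fraction)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*all dimensions.*")
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.values
    pos = eig > max(eig.max(), 0) * 1e-10
    coords = res.samples.values[:, pos]
    eigvals = eig[pos]
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            logger.warning(
                "requested %d axes but only %d positive; truncating",
                n_axes, coords.shape[1])
        coords = coords[:, :n_axes]
        eigvals = eigvals[:n_axes]
    explained = eigvals / eig[eig > 0].sum()
    return PcoaEmbedding(list(dm.ids), coords, eigvals, explained)


def ch_index(dm: DistanceMatrix, labels: np.ndarray) -> float:
    """Calinski-Harabasz ratio of between- to within-cluster dispersion,
    computed on the positive-axis PCoA coordinates of the distance matrix."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    n = len(labels)
    if k < 2 or k >= n:
        raise ValueError("CH index undefined for k < 2 or k = n")
    coords = pcoa(dm).coordinates
    return float(calinski_harabasz_score(coords, labels))


def silhouette(dm: DistanceMatrix, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths on the distance matrix (singletons get 0)
    and their mean."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    widths = silhouette_samples(dm.data, labels, metric="precomputed")
    return widths, float(widths.mean())


def _name_clusters(partition: EnterotypePartition, table: AbundanceTable,
                   e1_markers=DEFAULT_E1_MARKERS) -> None:
    """When k=2, name the cluster with higher mean E1-marker (Bacteroides)
    abundance ICU_E1 and the other ICU_E2."""
    if partition.k != 2:
        return
    marker_cols = [c for c, lin in zip(table.data.columns, table.lineages)
                   if any(n in e1_markers for n in lin.names if n)]
    if not marker_cols:
        logger.warning("no E1 marker taxa (%s) in table; keeping index order",
                       e1_markers)
        partition.label_names = {0: E1, 1: E2}
        return
    marker = table.data[marker_cols].sum(axis=1).to_numpy()
    means = [marker[partition.labels == c].mean() for c in (0, 1)]
    if means[0] >= means[1]:
        partition.label_names = {0: E1, 1: E2}
    else:
        partition.label_names = {0: E2, 1: E1}


def evaluate_partition(dm: DistanceMatrix, partition: EnterotypePartition,
                       table: AbundanceTable | None = None) -> EnterotypePartition:
    partition.ch = ch_index(dm, partition.labels)
    _, partition.si = silhouette(dm, partition.labels)
    if table is not None:
        _name_clusters(partition, table)
    return partition


def select_k(dm: DistanceMatrix, k_range=range(2, 11),
             table: AbundanceTable | None = None
             ) -> tuple[EnterotypePartition, pd.DataFrame]:
    """Cluster at each k, score by CH (silhouette reported alongside), and
    return the best-CH partition plus the full diagnostics table."""
    n = len(dm.ids)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no feasible k in {list(k_range)} for n={n}")
    rows, parts = [], {}
    for k in ks:
        part = evaluate_partition(dm, pam_cluster(dm, k))
        parts[k] = part
        rows.append({"k": k, "ch": part.ch, "si": part.si})
    diag = pd.DataFrame(rows)
    best_k = int(diag.loc[diag["ch"].idxmax(), "k"])
    best_si_k = int(diag.loc[diag["si"].idxmax(), "k"])
    if best_si_k != best_k:
        logger.info("CH favours k=%d but silhouette favours k=%d; selecting "
                    "by CH", best_k, best_si_k)
    best = parts[best_k]
    if table is not None:
        _name_clusters(best, table)
    return best, diag
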