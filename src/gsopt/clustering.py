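"""Candidate-set clustering and the two non-search selection methods.

Hierarchical clustering (Ward's minimum-variance linkage on Euclidean
distances over dosages) defines the partitions used by stratified sampling
and the clustered CDmean orchestrations; PAM (partitioning around medoids)
selects the medoids themselves as the training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core import MarkerMatrix


@dataclass
class Partition:
    """Cluster assignment per sample id; labels lie in [0, k) and every
    cluster is nonempty."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("one label per sample id required")
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError(f"labels must cover 0..{self.k - 1} with no empty cluster")

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def label_of(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.labels.tolist()))

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def cluster_assignments(markers: MarkerMatrix, k: int) -> Partition:
    """Agglomerative Ward clustering of the dosage rows, cut at k clusters.

    scipy's ``method="ward"`` on raw observations is the ward.D2 variant
    (squared-distance updates on Euclidean input). Labels are renumbered by
    first appearance so the partition is stable up to sample order.
    """
    if not 2 <= k <= markers.n:
        raise ValueError(f"k must be in [2, {markers.n}]")
    if k == markers.n:
        return Partition(list(markers.sample_ids), np.arange(markers.n), k)
    z = linkage(markers.dosages, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(markers.n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(r, len(relabel))
    return Partition(list(markers.sample_ids), labels, k)


def apportion(counts, total: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` by cluster share.

    Quotas differ from exact proportionality by less than one; remainder ties
    are broken by the supplied generator (or lowest index when absent).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if total > n:
        raise ValueError(f"cannot apportion {total} among {int(n)} individuals")
    exact = total * counts / n
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    short = total - quotas.sum()
    if short > 0:
        order = np.arange(len(counts))
        if rng is not None:
            order = rng.permutation(len(counts))  # seeded tie-break
        ranked = order[np.argsort(-remainder[order], kind="stable")]
        quotas[ranked[:short]] += 1
    return quotas


def stratified_sample(
    partition: Partition, total_size: int, rng_seed: int | np.random.Generator = 0
) -> list[str]:
    """Cluster-proportional random sample: per-cluster quotas by largest
    remainder, then uniform sampling without replacement inside clusters."""
    n = len(partition.sample_ids)
    if total_size > n:
        raise ValueError(f"total_size {total_size} exceeds {n} individuals")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    quotas = apportion(partition.cluster_sizes(), total_size, rng)
    selected: list[str] = []
    for label in range(partition.k):
        members = partition.members(label)
        take = quotas[label]
        if take:
            picks = rng.choice(len(members), size=take, replace=False)
            selected.extend(members[i] for i in sorted(picks))
    return selected


def _pam_objective(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_select(markers: MarkerMatrix, candidate_ids, size: int) -> list[str]:
    """k-medoids (BUILD + SWAP) on Euclidean dosage distances; the returned
    training set is the medoid ids, swap-optimal at convergence."""
    candidate = list(candidate_ids)
    nc = len(candidate)
    if size < 1:
        raise ValueError("size must be >= 1")
    if size > nc:
        raise ValueError(f"size {size} exceeds candidate set of {nc}")
    if size == nc:
        return candidate
    sub = markers.subset(candidate)
    d = squareform(pdist(sub.dosages, metric="euclidean"))

    # BUILD: greedy accretion minimizing total dissimilarity to nearest medoid
    medoids: list[int] = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < size:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])

    # SWAP: steepest-descent single swaps until no improvement
    current = _pam_objective(d, np.array(medoids))
    improved = True
    while improved:
        improved = False
        med_set = set(medoids)
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            partial = d[:, others].min(axis=1) if others else np.full(nc, np.inf)
            for h in range(nc):
                if h in med_set:
                    continue
                obj = np.minimum(partial, d[:, h]).sum()
                delta = current - obj
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is not None and best_delta > 1e-12:
            mi, h = best_swap
            medoids[mi] = h
            current = _pam_objective(d, np.array(medoids))
            improved = True
    return [candidate[i] for i in sorted(medoids)]


def pam_objective(markers: MarkerMatrix, candidate_ids, medoid_ids) -> float:
    """Total dissimilarity of candidates to their nearest medoid (for oracles)."""
    candidate = list(candidate_ids)
    sub = markers.subset(candidate)
    d = squareform(pdist(sub.dosages, metric="euclidean"))
    pos = {s: i for i, s in enumerate(candidate)}
    idx = np.array([pos[s] for s in medoid_ids], dtype=int)
    return _pam_objective(d, idx)


def exhaustive_pam(markers: MarkerMatrix, candidate_ids, size: int) -> list[str]:
    """Exact k-medoids by enumeration (test oracle for small instances)."""
    candidate = list(candidate_ids)
    sub = markers.subset(candidate)
    d = squareform(pdist(sub.dosages, metric="euclidean"))
    best_obj, best_set = np.inf, None
    for combo in itertools.combinations(range(len(candidate)), size):
        obj = _pam_objective(d, np.array(combo))
        if obj < best_obj - 1e-12:
            best_obj, best_set = obj, combo
    return [candidate[i] for i in best_set]


def assign_to_clusters(
    markers: MarkerMatrix, partition: Partition, ids
) -> dict[int, list[str]]:
    """Assign external individuals (e.g. a test set) to the nearest cluster
    centroid in dosage space; used by within-cluster targeted optimization."""
    centroids = np.stack(
        [markers.subset(partition.members(l)).dosages.mean(axis=0) for l in range(partition.k)]
    )
    out: dict[int, list[str]] = {l: [] for l in range(partition.k)}
    for s in ids:
        row = markers.dosages[markers.index_of([s])[0]]
        label = int(np.argmin(((centroids - row) ** 2).sum(axis=1)))
        out[label].append(s)
    return out


def write_partition(partition: Partition, path: str, sep: str = "\t") -> None:
    with open(path, "w") as handle:
        handle.write(f"sample_id{sep}cluster\n")
        for s, l in zip(partition.sample_ids, partition.labels):
            handle.write(f"{s}{sep}{int(l)}\n")
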