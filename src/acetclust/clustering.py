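"""Kolmogorov-distance matrix over cumulative profiles, PAM k-medoids, and
semantic cluster labeling.

The distance between two promoters is the maximum absolute difference between
their normalized cumulative bin profiles.  Clustering is partitioning around
medoids (PAM): a deterministic greedy BUILD phase followed by best-improvement
SWAP until no single medoid/non-medoid exchange strictly lowers the objective
(total distance of every point to its nearest medoid).  With k = 3, clusters
are named upstream / centered / downstream by the rank of the center of mass
of their mean strand-oriented binned profile.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .profiles import BinnedProfile, CumulativeProfile

SEMANTIC_LABELS = ("upstream", "centered", "downstream")
_EPS = 1e-12


def kolmogorov_distance(a: CumulativeProfile, b: CumulativeProfile) -> float:
    """max_i |a_i − b_i| between two equal-length cumulative profiles."""
    if len(a.cdf) != len(b.cdf):
        raise ValueError(f"bin-count mismatch: {len(a.cdf)} vs {len(b.cdf)}")
    return float(np.max(np.abs(np.asarray(a.cdf) - np.asarray(b.cdf))))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")

    def __len__(self) -> int:
        return len(self.ids)


def build_distance_matrix(
    profiles: Mapping[str, CumulativeProfile] | Sequence[CumulativeProfile],
) -> DistanceMatrix:
    """All-pairs Kolmogorov distances; each unique pair computed once."""
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    if len(items) < 2:
        raise ValueError("need at least two profiles")
    ids = [cp.promoter_id for cp in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate promoter ids in profile set")
    lengths = {len(cp.cdf) for cp in items}
    if len(lengths) != 1:
        raise ValueError("profiles have differing bin counts")
    X = np.array([cp.cdf for cp in items], dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    # accumulate the max over bins to avoid an n×n×bins intermediate
    for k in range(X.shape[1]):
        np.maximum(d, np.abs(X[:, k][:, None] - X[:, k][None, :]), out=d)
    return DistanceMatrix(tuple(ids), d)


@dataclass(frozen=True)
class ClusterResult:
    """PAM output: medoids, assignment, objective, optional semantic labels."""

    k: int
    medoid_ids: tuple[str, ...]
    assignment: Mapping[str, int]  # promoter id -> cluster index
    objective: float
    labels: Mapping[int, str] | None = None

    def label_of(self, pid: str) -> str | int:
        idx = self.assignment[pid]
        return self.labels[idx] if self.labels is not None else idx

    def sizes(self) -> dict:
        out: dict = {}
        for pid in self.assignment:
            key = self.label_of(pid)
            out[key] = out.get(key, 0) + 1
        return out


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    totals = d.sum(axis=1)
    medoids = [int(np.argmin(totals))]  # argmin takes the lowest index on ties
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        np.minimum(nearest, d[j], out=nearest)
    return medoids


def _objective(d: np.ndarray, medoids: Sequence[int]) -> float:
    return float(d[list(medoids)].min(axis=0).sum())


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = d.shape[0]
    medoids = sorted(medoids)
    current = _objective(d, medoids)
    while True:
        best_delta = -_EPS
        best: tuple[int, int] | None = None
        in_medoids = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            base = (
                d[others].min(axis=0)
                if others
                else np.full(n, np.inf)
            )
            for h in range(n):
                if h in in_medoids:
                    continue
                candidate = float(np.minimum(base, d[h]).sum())
                delta = candidate - current
                if delta < best_delta:
                    best_delta = delta
                    best = (mi, h)
        if best is None:
            return medoids, current
        mi, h = best
        medoids[mi] = h
        medoids.sort()
        current = _objective(d, medoids)


def k_medoids(
    dm: DistanceMatrix, k: int = 3, seed: int | None = None, restarts: int = 0
) -> ClusterResult:
    """PAM on a precomputed distance matrix.

    Deterministic by default (greedy BUILD).  ``restarts`` > 0 additionally
    tries that many random medoid initializations (seeded by ``seed``) and
    keeps the lowest-objective solution.
    """
    n = len(dm)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k == n:
        medoids = list(range(n))
        objective = 0.0
    else:
        medoids, objective = _pam_swap(dm.d, _pam_build(dm.d, k))
        if restarts > 0:
            rng = np.random.default_rng(seed)
            for _ in range(restarts):
                init = list(rng.choice(n, size=k, replace=False))
                cand, cand_obj = _pam_swap(dm.d, init)
                if cand_obj < objective - _EPS:
                    medoids, objective = cand, cand_obj
    medoids = sorted(medoids)
    # nearest-medoid assignment; ties go to the lowest medoid index
    sub = dm.d[medoids]
    assignment = {
        dm.ids[i]: int(np.argmin(sub[:, i])) for i in range(n)
    }
    for ci, m in enumerate(medoids):
        assignment[dm.ids[m]] = ci  # a medoid always belongs to its own cluster
    return ClusterResult(
        k=k,
        medoid_ids=tuple(dm.ids[m] for m in medoids),
        assignment=assignment,
        objective=objective,
    )


def profile_center_of_mass(scores: np.ndarray) -> float:
    """Σ i·s_i / Σ s_i over bin indices; center bin for an all-zero profile."""
    scores = np.asarray(scores, dtype=float)
    total = scores.sum()
    if total == 0:
        return (scores.size - 1) / 2
    return float(np.dot(np.arange(scores.size), scores) / total)


def label_clusters(
    result: ClusterResult, profiles: Mapping[str, BinnedProfile]
) -> ClusterResult:
    """Name the three clusters by where their mean profile's mass sits.

    Each cluster's mean strand-oriented binned profile is reduced to its
    center of mass over bin indices; clusters are ranked by it and labeled
    upstream (smallest) / centered / downstream (largest).  Ties rank the
    lower cluster index first.  For k ≠ 3 the result is returned unlabeled.
    """
    if result.k != 3:
        return replace(result, labels=None)
    coms = []
    for ci in range(result.k):
        members = [pid for pid, c in result.assignment.items() if c == ci]
        matrix = np.array([profiles[pid].scores for pid in members], dtype=float)
        coms.append(profile_center_of_mass(matrix.mean(axis=0)))
    order = sorted(range(result.k), key=lambda ci: (coms[ci], ci))
    labels = {ci: SEMANTIC_LABELS[rank] for rank, ci in enumerate(order)}
    return replace(result, labels=labels)


def cross_tabulate_clusterings(a: ClusterResult, b: ClusterResult) -> pd.DataFrame:
    """Contingency table of cluster membership between two clusterings.

    Cell (i, j) counts promoters with label i in ``a`` and j in ``b``; rows
    and columns are ordered upstream/centered/downstream when labeled.
    """
    if set(a.assignment) != set(b.assignment):
        raise ValueError("clusterings cover different promoter universes")
    rows = {pid: a.label_of(pid) for pid in a.assignment}
    cols = {pid: b.label_of(pid) for pid in b.assignment}
    table = pd.crosstab(
        pd.Series(rows, name="a"), pd.Series(cols, name="b")
    )

    def _order(values):
        present = list(values)
        if all(v in SEMANTIC_LABELS for v in present):
            return [v for v in SEMANTIC_LABELS if v in present]
        return sorted(present)

    table = table.reindex(
        index=_order(table.index), columns=_order(table.columns), fill_value=0
    )
    return table


def write_assignments(result: ClusterResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster_index\tlabel\n")
        for pid in sorted(result.assignment):
            idx = result.assignment[pid]
            label = result.labels[idx] if result.labels is not None else ""
            fh.write(f"{pid}\t{idx}\t{label}\n")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, pid in enumerate(dm.ids):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in dm.d[i]) + "\n")
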