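"""Hierarchical clustering of participants on the untargeted metabolome.

Ward's agglomerative method on squared Euclidean distances: each merge is
the pair of clusters whose union increases the within-cluster sum of squares
the least, computed through the Lance-Williams recurrence. Intensities are
log10-transformed and autoscaled per ion first, so abundant ions do not
dominate the distances. The convention flag records whether heights are
reported as the Ward dissimilarity itself (squared-distance scale, the
classic objective and the default) or its square root ("euclidean"), which
matches scipy's ward linkage heights; the merge sequence is identical under
both.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: dict[str, str]  # participant id -> cluster letter
    k: int
    merge_heights: np.ndarray
    preprocessing: str = "log10 + per-ion autoscale"

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.labels.values()))


def preprocess_matrix(matrix) -> pd.DataFrame:
    """Participant x ion table: log10, then per-ion mean 0 / SD 1.

    Ions constant across participants carry no distance information and are
    dropped with a warning.
    """
    if len(matrix.participants) < 2:
        raise InputError("clustering requires >= 2 participants")
    log = np.log10(matrix.intensities.to_numpy(dtype=float)).T  # samples x ions
    sd = log.std(axis=0, ddof=0)
    # relative floor: identical values can yield sd ~ 1 ULP, not exactly 0
    keep = sd > 1e-10 * (np.abs(log).max(axis=0) + 1.0)
    if not keep.all():
        dropped = [i for i, k in zip(matrix.ion_ids, keep) if not k]
        logger.warning("dropping %d constant ion(s): %s", len(dropped), dropped[:5])
    z = (log[:, keep] - log[:, keep].mean(axis=0)) / sd[keep]
    cols = [i for i, k in zip(matrix.ion_ids, keep) if k]
    return pd.DataFrame(z, index=matrix.participants, columns=cols)


def ward_cluster(standardized, convention: str = "squared_euclidean") -> np.ndarray:
    """Ward linkage matrix [left, right, height, size] over observation rows.

    Lance-Williams recurrence on squared Euclidean distances; the pair with
    the minimal Ward dissimilarity merges, ties broken by the smallest
    (left, right) cluster-index pair. Heights under the default convention
    equal twice the increase in within-cluster sum of squares.
    """
    if convention not in ("squared_euclidean", "euclidean"):
        raise InputError(f"unknown distance convention {convention!r}")
    x = np.asarray(standardized, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("non-finite values in standardized matrix")
    n = x.shape[0]
    if n < 2:
        raise InputError("ward_cluster requires >= 2 observations")

    diff = x[:, None, :] - x[None, :, :]
    d = np.einsum("ijk,ijk->ij", diff, diff)  # squared Euclidean
    big = np.inf
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    merges = []
    next_id = n
    for _ in range(n - 1):
        best, best_pair = big, None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (i, j) if i < j else (j, i)
                val = dist[key]
                if val < best - 1e-12 or (
                    abs(val - best) <= 1e-12 and (best_pair is None or key < best_pair)
                ):
                    best, best_pair = val, key
        i, j = best_pair
        si, sj = sizes[i], sizes[j]
        merges.append([i, j, best, si + sj])
        # Lance-Williams update for Ward on squared distances
        for k in active:
            if k in (i, j):
                continue
            sk = sizes[k]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new = (
                (si + sk) * dik + (sj + sk) * djk - sk * best
            ) / (si + sj + sk)
            dist[(min(k, next_id), max(k, next_id))] = new
        active.remove(i)
        active.remove(j)
        active.append(next_id)
        sizes[next_id] = si + sj
        next_id += 1

    linkage = np.array(merges, dtype=float)
    if convention == "euclidean":
        linkage[:, 2] = np.sqrt(linkage[:, 2])
    return linkage


def cut_clusters(linkage: np.ndarray, k: int = 4, ids=None) -> ClusterAssignment:
    """Partition into exactly k clusters by undoing the last k-1 merges.

    Labels are letters A, B, ... assigned in order of each cluster's first
    participant (row order).
    """
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise InputError(f"k={k} outside [1, {n}]")
    if ids is None:
        ids = [str(i) for i in range(n)]
    parent = list(range(2 * n - 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for m in range(n - k):
        i, j = int(linkage[m, 0]), int(linkage[m, 1])
        parent[find(i)] = parent[find(j)] = n + m
    roots: dict[int, str] = {}
    letters = string.ascii_uppercase
    labels = {}
    for row, pid in enumerate(ids):
        r = find(row)
        if r not in roots:
            idx = len(roots)
            roots[r] = letters[idx] if idx < 26 else f"C{idx}"
        labels[str(pid)] = roots[r]
    return ClusterAssignment(labels=labels, k=k, merge_heights=linkage[:, 2].copy())


def cluster_composition(assignment: ClusterAssignment, cohort):
    """Cluster sizes and diet-group make-up, plus each diet's modal cluster.

    Returns (by_cluster, by_diet): by_cluster has one row per cluster with
    counts and fractions per diet group (fractions sum to 1 within a row);
    by_diet reports, per diet group, the cluster holding most of its members
    and the fraction of the group found there.
    """
    diets = cohort.participants.set_index("id")["diet"]
    unknown = [p for p in assignment.labels if p not in diets.index]
    if unknown:
        raise InputError(f"participants not in cohort: {unknown}")
    df = pd.DataFrame(
        {"cluster": pd.Series(assignment.labels), "diet": diets}
    ).dropna()
    groups = list(cohort.groups)
    rows = []
    for cluster, sub in df.groupby("cluster"):
        row = {"cluster": cluster, "size": len(sub)}
        for g in groups:
            cnt = int((sub["diet"] == g).sum())
            row[f"n_{g}"] = cnt
            row[f"frac_{g}"] = cnt / len(sub)
        rows.append(row)
    by_cluster = pd.DataFrame(rows)
    diet_rows = []
    for g in groups:
        sub = df[df["diet"] == g]
        modal = sub["cluster"].value_counts().idxmax()
        diet_rows.append(
            {"diet": g, "n": len(sub), "modal_cluster": modal,
             "modal_fraction": (sub["cluster"] == modal).mean()}
        )
    return by_cluster, pd.DataFrame(diet_rows)


def to_newick(linkage: np.ndarray, ids) -> str:
    """Dendrogram as a newick string with branch lengths from merge heights."""
    n = linkage.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node = {i: str(ids[i]) for i in range(n)}
    for m in range(n - 1):
        i, j, h = int(linkage[m, 0]), int(linkage[m, 1]), float(linkage[m, 2])
        bi, bj = max(h - height[i], 0.0), max(h - height[j], 0.0)
        node[n + m] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
        height[n + m] = h
    return node[2 * n - 2] + ";"
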