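"""Unsupervised hierarchical clustering of samples on DEG expression.

Samples are compared by Pearson correlation distance (1 − r) over their DEG
vectors and agglomerated by average linkage (UPGMA).  The two-cluster cut is
scored against the known case/control classes with a confusion matrix, each
cluster being assigned the class that predominates in it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: pd.Series               # cluster index (0..k-1) per sample
    merges: list[tuple]             # (i, j, height, new_size) per step
    distance: pd.DataFrame          # sample × sample, values in [0, 2]
    leaf_order: list[str]           # dendrogram leaf order of sample IDs


@dataclass
class ConfusionSummary:
    matrix: pd.DataFrame            # rows = observed class, cols = predicted class
    per_cluster_accuracy: dict      # predicted class -> rounded percent (or None)
    per_cluster_ratio: dict         # predicted class -> exact fraction (or None)


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample–sample distance d(a, b) = 1 − Pearson r of the DEG vectors."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 gene rows")
    sd = matrix.std(axis=0, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"sample(s) with zero variance across DEGs: {flat[:5]}")
    corr = np.corrcoef(matrix.to_numpy(float), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def average_linkage(dist: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Agglomerative UPGMA clustering cut to exactly ``k`` clusters.

    Inter-cluster dissimilarity is the unweighted mean of all cross-pair
    distances.  When two candidate merges tie in height, the pair with the
    smallest (row, col) index is merged, which fixes the merge sequence
    across runs and platforms.
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    # Lance–Williams update for UPGMA: after merging a and b,
    # d(a∪b, c) = (|a|·d(a,c) + |b|·d(b,c)) / (|a| + |b|).
    # The active matrix keeps rows in ascending cluster-id order, so a
    # row-major argmin over the upper triangle realises the smallest
    # (row, col) tie-break.
    D = dist.to_numpy(float).copy()
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    while len(ids) > 1:
        m = len(ids)
        iu = np.triu_indices(m, k=1)
        flat = D[iu]
        pos = int(np.argmin(flat))
        i, j = int(iu[0][pos]), int(iu[1][pos])
        a, b = ids[i], ids[j]
        h = float(flat[pos])
        na, nb = sizes[a], sizes[b]
        merges.append((a, b, h, na + nb))
        children[next_id] = (a, b)
        newrow = (na * D[i, :] + nb * D[j, :]) / (na + nb)
        keep = [p for p in range(m) if p not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       newrow[keep][None, :]])
        D = np.hstack([D, np.append(newrow[keep], 0.0)[:, None]])
        ids = [ids[p] for p in keep] + [next_id]
        sizes[next_id] = na + nb
        del sizes[a], sizes[b]
        next_id += 1

    # cut: undo the last k-1 merges
    labels = np.zeros(n, dtype=int)
    root = ids[0]
    kept = {root: _collect(children, root, n)}
    for step in range(k - 1):
        # split the most recently formed cluster present
        top = max(kept)
        if top < n:
            break
        a, b = children[top]
        members_a = _collect(children, a, n)
        members_b = _collect(children, b, n)
        del kept[top]
        kept[a] = members_a
        kept[b] = members_b
    for idx, (_, members) in enumerate(sorted(kept.items())):
        labels[members] = idx

    leaf_order = _leaf_order(children, n)
    samples = list(dist.index)
    return ClusterResult(
        labels=pd.Series(labels, index=samples, name="cluster"),
        merges=merges,
        distance=dist,
        leaf_order=[samples[i] for i in leaf_order],
    )


def _collect(children, node, n):
    if node < n:
        return [node]
    a, b = children[node]
    return _collect(children, a, n) + _collect(children, b, n)


def _leaf_order(children, n):
    if not children:
        return list(range(n))
    return _collect(children, max(children), n)


def evaluate_clusters(labels, truth) -> ConfusionSummary:
    """Confusion matrix of observed classes vs majority-assigned clusters.

    Each cluster predicts the class that predominates in it; a 50/50 tie is
    broken toward the class no other cluster has claimed yet (with a
    warning).  Per-cluster accuracy is the fraction of that predicted
    column's samples whose observed class matches, reported both exactly and
    rounded to the nearest integer percent.
    """
    labels = pd.Series(labels)
    truth = pd.Series(truth)
    if not labels.index.equals(truth.index):
        truth = truth.reindex(labels.index)
        if truth.isna().any():
            raise ValueError("labels and truth must cover the same samples")
    classes = sorted(truth.unique())
    if len(classes) != 2:
        raise ValueError("exactly 2 observed classes required")

    assignment: dict[int, str] = {}
    for cl in sorted(labels.unique()):
        counts = truth[labels == cl].value_counts()
        top = counts.index[counts == counts.max()].tolist()
        if len(top) > 1:
            unclaimed = [c for c in classes if c not in assignment.values()]
            choice = unclaimed[0] if unclaimed else sorted(top)[0]
            warnings.warn(f"cluster {cl} is tied; assigned to {choice!r}")
            assignment[cl] = choice
        else:
            assignment[cl] = top[0]

    predicted = labels.map(assignment)
    matrix = pd.crosstab(truth, predicted).reindex(
        index=classes, columns=classes, fill_value=0
    )
    matrix.index.name = "observed"
    matrix.columns.name = "predicted"
    return _summarise(matrix)


def confusion_accuracy(matrix: pd.DataFrame) -> ConfusionSummary:
    """Per-cluster accuracies from an existing observed×predicted count table."""
    return _summarise(matrix.astype(int))


def _summarise(matrix: pd.DataFrame) -> ConfusionSummary:
    acc, ratio = {}, {}
    for col in matrix.columns:
        total = int(matrix[col].sum())
        if total == 0:
            warnings.warn(f"predicted class {col!r} is empty; accuracy undefined")
            acc[col] = None
            ratio[col] = None
            continue
        correct = int(matrix.loc[col, col]) if col in matrix.index else 0
        ratio[col] = correct / total
        acc[col] = int(round(100.0 * correct / total))
    return ConfusionSummary(matrix=matrix, per_cluster_accuracy=acc, per_cluster_ratio=ratio)
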