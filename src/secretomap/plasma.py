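"""Plasma screen: internal-standard normalization, pregnancy folds, clustering.

Targeted peak areas from mouse plasma are expressed as a ratio to a spiked
internal standard peptide (bovine insulin) in the same run, which removes
run-to-run intensity drift.  Per-protein pregnancy fold changes compare
pregnant (P) to non-pregnant (NP) animals; the heat-map matrix is row
Z-scored and clustered by average linkage under the Spearman rank
correlation distance d = 1 - rho, on both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

logger = logging.getLogger("secretomap")

STANDARD_ROW = "__STANDARD__"


def normalize_to_standard(
    quant: pd.DataFrame, standard_row: str = STANDARD_ROW
) -> pd.DataFrame:
    """Divide every column by its internal-standard value; drop the standard row.

    The result is invariant to any per-column rescaling of raw intensities.
    A zero or missing standard value is rejected naming the column.
    """
    if standard_row not in quant.index:
        raise ValueError(f"internal-standard row {standard_row!r} missing")
    std = quant.loc[standard_row]
    bad = [c for c in quant.columns
           if not np.isfinite(std[c]) or std[c] <= 0]
    if bad:
        raise ValueError(f"non-positive internal standard in column(s) {bad}")
    out = quant.drop(index=standard_row)
    return out / std


def pregnancy_fold_change(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = 1.5,
    central: str = "mean",
) -> pd.DataFrame:
    """Per-protein fold change P/NP with classification at ``threshold``.

    ``groups`` maps column (animal) id to 'NP' or 'P'.  The central value is
    the arithmetic mean of normalized abundances by default (median via
    ``central='median'``).  Zeros are floored at half the smallest positive
    value of the matrix before division, so proteins undetected in NP get a
    large finite fold rather than infinity.  A fold >= threshold (inclusive)
    is classified higher in pregnancy.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if central not in ("mean", "median"):
        raise ValueError(f"unknown central value {central!r}")
    np_cols = [c for c in normalized.columns if groups.get(c) == "NP"]
    p_cols = [c for c in normalized.columns if groups.get(c) == "P"]
    if not np_cols or not p_cols:
        raise ValueError("both NP and P groups must be non-empty")
    vals = normalized.to_numpy(dtype=float)
    positive = vals[vals > 0]
    floor = positive.min() / 2 if positive.size else 1.0
    agg = (lambda df: df.mean(axis=1)) if central == "mean" \
        else (lambda df: df.median(axis=1))
    c_np = agg(normalized[np_cols]).clip(lower=floor)
    c_p = agg(normalized[p_cols]).clip(lower=floor)
    fold = c_p / c_np
    return pd.DataFrame({
        "fold_p_vs_np": fold,
        "higher_in_pregnancy": fold >= threshold,
        "central_np": c_np,
        "central_p": c_p,
    })


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, SD 1 (population SD, ddof=0).

    Constant rows are mapped to all zeros with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("row Z-score needs at least two columns")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("%d constant row(s) mapped to zeros", int(const.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mean) / sd, index=matrix.index,
                        columns=matrix.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: labels, merges [(i, j, height)], leaf order.

    Cluster indices follow the scipy convention: 0..n-1 are leaves, the
    merge at step t creates cluster n+t.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def leaf_order(self) -> list[str]:
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for t, (i, j, _) in enumerate(self.merges):
            members[n + t] = members.pop(i) + members.pop(j)
        (root,) = members.values()
        return [self.labels[i] for i in root]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (scipy pdist ordering)."""
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        full = np.zeros((n, n))
        for t, (i, j, h) in enumerate(self.merges):
            for a in members[i]:
                for b in members[j]:
                    full[a, b] = full[b, a] = h
            members[n + t] = members.pop(i) + members.pop(j)
        return full[np.triu_indices(n, k=1)]

    def to_newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for t, (i, j, h) in enumerate(self.merges):
            bi, bj = h - height[i], h - height[j]
            node[n + t] = f"({node.pop(i)}:{bi:.6g},{node.pop(j)}:{bj:.6g})"
            height[n + t] = h
        (root,) = [node[k] for k in node]
        return root + ";"


def spearman_distance_matrix(vectors: np.ndarray, labels: list[str]) -> np.ndarray:
    """Pairwise d = 1 - Spearman rho; rejects constant vectors by name."""
    ranks = np.empty_like(vectors, dtype=float)
    for i, v in enumerate(vectors):
        if np.all(v == v[0]):
            raise ValueError(
                f"constant vector {labels[i]!r}: Spearman correlation undefined")
        ranks[i] = rankdata(v)
    rho = np.corrcoef(ranks)
    return 1.0 - rho


def hcluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Average-linkage agglomeration under Spearman distance.

    Ties in the minimal inter-cluster distance are broken by the smallest
    lexicographic leaf label contained in each candidate cluster, so the
    merge order (and hence leaf order) is deterministic.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix if axis == "rows" else matrix.T
    labels = [str(x) for x in data.index]
    vectors = data.to_numpy(dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least two vectors to cluster")
    if vectors.shape[1] < 3:
        raise ValueError("Spearman distance needs vectors of length >= 3")
    dist = spearman_distance_matrix(vectors, labels)
    return average_linkage(dist, labels)


def average_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Agglomerate a precomputed distance matrix under average linkage."""
    n = len(labels)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # id -> leaf ids
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        # smallest distance; ties by sorted (minlabel_a, minlabel_b)
        best = min(
            d.items(),
            key=lambda kv: (kv[1], *sorted((minlab[kv[0][0]], minlab[kv[0][1]]))),
        )
        (a, b), h = best
        # order merged pair by lexicographic min label for determinism
        if minlab[b] < minlab[a]:
            a, b = b, a
        size_a, size_b = len(active[a]), len(active[b])
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            dac = d[tuple(sorted((a, c)))]
            dbc = d[tuple(sorted((b, c)))]
            d[(min(c, new), max(c, new))] = (
                size_a * dac + size_b * dbc) / (size_a + size_b)
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        active[new] = active.pop(a) + active.pop(b)
        minlab[new] = min(minlab.pop(a), minlab.pop(b))
        merges.append((a, b, h))
    return Dendrogram(labels=labels, merges=merges)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two vectors (scipy)."""
    return float(spearmanr(x, y).statistic)
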