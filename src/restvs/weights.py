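"""Network decomposition of the averaged connectivity weight vector.

Edge-space model weights are refolded into a symmetric ROI x ROI matrix
(inverse of the upper-triangle vectorisation), nodes are ranked by the sum
of |weight| over incident edges, single edges by |weight|, and weights are
aggregated into a 9 x 9 network matrix over the seven functional networks
plus basal ganglia and cerebellum.  Absolute values are the default for
node sums and aggregation — the weight pattern does not by itself say
whether a connection relates positively or negatively to the target —
with signed variants behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import NETWORKS

__all__ = ["WeightMatrix", "refold", "rank_nodes", "rank_edges", "network_aggregate"]


def refold(weight_vector: np.ndarray, n_roi: int) -> np.ndarray:
    """Edge vector back to a symmetric zero-diagonal ROI x ROI matrix."""
    v = np.asarray(weight_vector, dtype=float).ravel()
    expected = n_roi * (n_roi - 1) // 2
    if v.size != expected:
        raise ValueError(f"weight vector length {v.size} != n_roi*(n_roi-1)/2 = {expected}")
    W = np.zeros((n_roi, n_roi))
    iu = np.triu_indices(n_roi, k=1)
    W[iu] = v
    return W + W.T


def rank_nodes(W: np.ndarray, k: int = 5, roi_set=None, absolute: bool = True) -> pd.DataFrame:
    """Top-k ROIs by summed incident |weight| (or signed sum).

    Ties break by ROI index.  ``k`` larger than the ROI count is truncated
    with a warning.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if k > n:
        warnings.warn(f"k={k} exceeds {n} ROIs; truncated", stacklevel=2)
        k = n
    scores = np.abs(W).sum(axis=1) if absolute else W.sum(axis=1)
    order = np.argsort(-scores, kind="stable")[:k]
    rows = []
    for rank, i in enumerate(order, start=1):
        row = {"rank": rank, "roi": int(i), "score": scores[i]}
        if roi_set is not None:
            row["network"] = str(roi_set.network_labels[i])
            row["x"], row["y"], row["z"] = roi_set.coordinates[i]
        rows.append(row)
    return pd.DataFrame(rows)


def rank_edges(W: np.ndarray, k: int = 5, roi_set=None) -> pd.DataFrame:
    """Top-k undirected edges by |weight|; the signed weight is reported."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    w = W[iu]
    order = np.argsort(-np.abs(w), kind="stable")[:min(k, w.size)]
    rows = []
    for rank, e in enumerate(order, start=1):
        i, j = int(iu[0][e]), int(iu[1][e])
        row = {"rank": rank, "roi_i": i, "roi_j": j, "weight": w[e]}
        if roi_set is not None:
            row["network_i"] = str(roi_set.network_labels[i])
            row["network_j"] = str(roi_set.network_labels[j])
        rows.append(row)
    return pd.DataFrame(rows)


def network_aggregate(
    W: np.ndarray, network_labels, absolute: bool = True
) -> pd.DataFrame:
    """9 x 9 mean-|weight| matrix over network blocks.

    Cell (A, B) is the mean over edges with one endpoint in A and the other
    in B; the diagonal uses the unordered pairs inside the network.  Blocks
    with no edges (absent or singleton networks) are NaN.
    """
    W = np.asarray(W, dtype=float)
    labels = np.asarray(network_labels)
    if labels.size != W.shape[0]:
        raise ValueError("every ROI must carry a network label")
    vals = np.abs(W) if absolute else W
    out = np.full((len(NETWORKS), len(NETWORKS)), np.nan)
    masks = {lab: labels == lab for lab in NETWORKS}
    iu = np.triu_indices(W.shape[0], k=1)
    for a, la in enumerate(NETWORKS):
        for b, lb in enumerate(NETWORKS[a:], start=a):
            sel = (masks[la][iu[0]] & masks[lb][iu[1]]) | (masks[lb][iu[0]] & masks[la][iu[1]])
            if sel.any():
                out[a, b] = out[b, a] = vals[iu][sel].mean()
    return pd.DataFrame(out, index=list(NETWORKS), columns=list(NETWORKS))


@dataclass
class WeightMatrix:
    """Refolded weight matrix with node and network aggregates."""

    W: np.ndarray
    roi_set: object = None

    @classmethod
    def from_vector(cls, weight_vector, n_roi: int | None = None, roi_set=None) -> "WeightMatrix":
        if n_roi is None:
            if roi_set is None:
                raise ValueError("give n_roi or roi_set")
            n_roi = roi_set.n_roi
        return cls(W=refold(weight_vector, n_roi), roi_set=roi_set)

    @property
    def node_sums(self) -> np.ndarray:
        return np.abs(self.W).sum(axis=1)

    def rank_nodes(self, k: int = 5, absolute: bool = True) -> pd.DataFrame:
        return rank_nodes(self.W, k=k, roi_set=self.roi_set, absolute=absolute)

    def rank_edges(self, k: int = 5) -> pd.DataFrame:
        return rank_edges(self.W, k=k, roi_set=self.roi_set)

    def network_matrix(self, absolute: bool = True) -> pd.DataFrame:
        if self.roi_set is None:
            raise ValueError("network aggregation needs an ROI set with labels")
        return network_aggregate(self.W, self.roi_set.network_labels, absolute=absolute)
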