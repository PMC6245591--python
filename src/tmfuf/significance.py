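"""Significant side-effect feature pairs from the projection matrix Theta.

Beyond prediction, the fitted projection matrix is interpretable: entry
theta_rs weighs how much the co-occurrence of side effects f_r and f_s in a
drug pair pushes it toward an enhancive (theta_rs > 0) or degressive
(theta_rs < 0) interaction.  With many feature columns the raw entries sit
close to zero, so the adjacency is scaled (x1000 by default) before solving;
entries whose absolute value then exceeds 1 are *significant*, and ranking
them by |theta| yields top-k lists per direction.

For large p, Theta (p x p) is never fully materialized: row blocks are
streamed from the factored form B B' and a bounded heap keeps the running
top-k.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .tmf import TmfModel

__all__ = ["FeaturePair", "ThetaSummary", "summarize_theta", "significant_pairs"]


@dataclass(frozen=True)
class FeaturePair:
    """One significant entry theta_rs reported as a feature pair."""

    feature_a: str
    feature_b: str
    theta: float
    direction: Literal["enhancive", "degressive"]
    rank: int
    is_self_pair: bool = False


@dataclass(frozen=True)
class ThetaSummary:
    """Histogram and significance counts over Theta's upper triangle
    (diagonal included)."""

    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    n_significant_positive: int
    n_significant_negative: int
    threshold: float

    @property
    def n_entries(self) -> int:
        return int(self.histogram_counts.sum())


def _iter_upper_blocks(model: TmfModel, block: int):
    """Yield (row_offset, theta_rows) for streaming upper-triangle scans."""
    p = model.coefficients.shape[0]
    for start in range(0, p, block):
        stop = min(start + block, p)
        yield start, model.theta_rows(slice(start, stop))


def summarize_theta(
    model: TmfModel,
    bins: int = 100,
    threshold: float = 1.0,
    block_size: int = 512,
) -> ThetaSummary:
    """Histogram the upper-triangle entries of Theta and count significant ones.

    The distribution is typically sharply peaked at zero with thin signed
    tails; entries with ``|theta| > threshold`` are counted per sign.
    """
    p = model.coefficients.shape[0]
    # first pass: global range for common bin edges
    lo, hi = np.inf, -np.inf
    for start, rows in _iter_upper_blocks(model, block_size):
        for i in range(rows.shape[0]):
            seg = rows[i, start + i:]
            lo, hi = min(lo, seg.min()), max(hi, seg.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    counts = np.zeros(bins, dtype=np.int64)
    n_pos = n_neg = 0
    for start, rows in _iter_upper_blocks(model, block_size):
        for i in range(rows.shape[0]):
            seg = rows[i, start + i:]
            counts += np.histogram(seg, bins=edges)[0]
            n_pos += int((seg > threshold).sum())
            n_neg += int((seg < -threshold).sum())
    return ThetaSummary(counts, edges, n_pos, n_neg, float(threshold))


def significant_pairs(
    model: TmfModel,
    threshold: float = 1.0,
    top_k: int = 10,
    include_self_pairs: bool = False,
    block_size: int = 512,
) -> dict[str, list[FeaturePair]]:
    """Top-k significant feature pairs per direction, ranked by |theta|.

    Scans the upper triangle of Theta (r <= s) in streamed row blocks,
    keeps entries with ``|theta| > threshold`` in a bounded heap, and
    reports separate enhancive (theta > 0) and degressive (theta < 0)
    lists, each ranked 1..top_k by descending |theta|.  Diagonal entries
    theta_rr are self-pairs: excluded by default and flagged when kept.

    Returns ``{"enhancive": [...], "degressive": [...]}``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    names = model.training_features.feature_names
    heaps: dict[str, list] = {"enhancive": [], "degressive": []}

    def _push(heap: list, absval: float, r: int, s: int, theta: float) -> None:
        item = (absval, -r, -s, theta)  # deterministic tie-break on indices
        if len(heap) < top_k:
            heapq.heappush(heap, item)
        elif item > heap[0]:
            heapq.heapreplace(heap, item)

    for start, rows in _iter_upper_blocks(model, block_size):
        for i in range(rows.shape[0]):
            r = start + i
            s0 = r if include_self_pairs else r + 1
            seg = rows[i, s0:]
            for off in np.flatnonzero(np.abs(seg) > threshold):
                s = s0 + int(off)
                theta = float(seg[off])
                key = "enhancive" if theta > 0 else "degressive"
                _push(heaps[key], abs(theta), r, s, theta)

    out: dict[str, list[FeaturePair]] = {}
    for direction, heap in heaps.items():
        ordered = sorted(heap, reverse=True)
        out[direction] = [
            FeaturePair(
                feature_a=names[-nr],
                feature_b=names[-ns],
                theta=theta,
                direction=direction,  # type: ignore[arg-type]
                rank=rank,
                is_self_pair=(-nr == -ns),
            )
            for rank, (absval, nr, ns, theta) in enumerate(ordered, start=1)
        ]
    return out
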