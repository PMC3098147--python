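"""Matching measured clusters against a phantom's ground-truth catalog."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ClusterRecord

__all__ = ["MatchResult", "match_clusters"]


@dataclass
class MatchResult:
    pairs: list[tuple[ClusterRecord, ClusterRecord]]   # (truth, measured)
    unmatched_truth: list[ClusterRecord]
    unmatched_measured: list[ClusterRecord]

    @property
    def fraction_matched(self) -> float:
        n = len(self.pairs) + len(self.unmatched_truth)
        return len(self.pairs) / n if n else float("nan")

    def size_errors(self) -> np.ndarray:
        """Relative size errors |measured - truth| / truth per matched pair."""
        return np.array([abs(m.size_nm - t.size_nm) / t.size_nm
                         for t, m in self.pairs])


def match_clusters(truth: Sequence[ClusterRecord],
                   measured: Sequence[ClusterRecord],
                   max_distance_nm: float | None = None) -> MatchResult:
    """Greedy nearest-centroid matching of measured records to ground truth.

    Each truth cluster claims its nearest unclaimed measured cluster within
    ``max_distance_nm`` (default: the truth cluster's own size), closest
    truth-measured pairs first.
    """
    if not truth or not measured:
        return MatchResult([], list(truth), list(measured))
    t_cent = np.array([t.centroid_nm for t in truth])
    m_cent = np.array([m.centroid_nm for m in measured])
    dists = np.linalg.norm(t_cent[:, None, :] - m_cent[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    used_t: set[int] = set()
    used_m: set[int] = set()
    pairs = []
    for ti, mi in order:
        if ti in used_t or mi in used_m:
            continue
        limit = max_distance_nm if max_distance_nm is not None else truth[ti].size_nm
        if dists[ti, mi] > limit:
            continue
        pairs.append((truth[ti], measured[mi]))
        used_t.add(ti)
        used_m.add(mi)
    return MatchResult(
        pairs=pairs,
        unmatched_truth=[t for i, t in enumerate(truth) if i not in used_t],
        unmatched_measured=[m for i, m in enumerate(measured) if i not in used_m],
    )
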