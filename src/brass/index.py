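"""Aggregation of accepted duplicate scaffolds into the BrassIndex.

Each protein's accepted matches yield a raw index -- by default simply
the number of distinct duplicate scaffolds; optionally quality-weighted,
each match contributing (s_thresh - score)/s_thresh so that perfect
replicas count 1 and near-threshold ones near 0.  Raw indices are then
normalized over a protein set so the broadest-specificity protein gets
BrassIndex 1; proteins with no duplicates get 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .congruence import ScoreConfig
from .errors import BrassError
from .search import ScaffoldMatch
from .structure import Motif


@dataclass
class BrassResult:
    structure_id: str
    motif: Optional[Motif]
    matches: list[ScaffoldMatch] = field(default_factory=list)
    raw_index: float = 0.0
    brass_index: Optional[float] = None
    length: Optional[int] = None
    description: str = ""


def raw_index(
    accepted: Sequence[ScaffoldMatch],
    config: ScoreConfig,
    motif_n: int,
    weighted: bool = False,
) -> float:
    """Raw specificity-breadth index of one protein.

    Counting mode (default): the number of accepted duplicate scaffolds.
    Weighted mode: sum of (s_thresh - score)/s_thresh over them, folding
    match quality into the count.
    """
    if not weighted:
        return float(len(accepted))
    thresh = config.threshold_for(motif_n)
    return float(sum((thresh - m.score.total) / thresh for m in accepted))


def normalize(results: Sequence[BrassResult]) -> list[BrassResult]:
    """Fill ``brass_index`` in place: raw / max(raw); all-zero set -> all 0."""
    if not results:
        raise BrassError("cannot normalize an empty result set")
    top = max(r.raw_index for r in results)
    for r in results:
        r.brass_index = r.raw_index / top if top > 0 else 0.0
    return list(results)


def frequency_distribution(
    results: Sequence[BrassResult], bin_width: float = 0.1, use_raw: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the (normalized or raw) index over a protein set.

    Bins are half-open [k*w, (k+1)*w); the last bin additionally includes
    its right edge so an index of exactly 1 is counted.  Returns
    (bin_edges, counts); total count equals len(results).
    """
    if bin_width <= 0:
        raise BrassError("bin width must be positive")
    if not results:
        raise BrassError("cannot histogram an empty result set")
    if use_raw:
        values = np.array([r.raw_index for r in results])
    else:
        if any(r.brass_index is None for r in results):
            raise BrassError("results must be normalized first")
        values = np.array([r.brass_index for r in results])
    top = float(values.max())
    n_bins = max(1, int(np.ceil(max(top, bin_width) / bin_width - 1e-9)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    # np.histogram uses half-open bins with the last bin right-closed,
    # which is exactly the convention wanted here
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
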