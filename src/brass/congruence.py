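"""Scaffold congruence scoring.

Two scaffolds (ordered residue sets, each residue reduced to one
functional atom) are compared through their pairwise-distance matrices D
(A) and pairwise potential-difference matrices PD (kT/e).  The score is
an L1 sum of the per-pair deviations,

    total = sum_{i<j} |D_c - D_r|  +  lambda_pd * sum_{i<j} |PD_c - PD_r|
            + big_penalty * #{pairs with |D_c - D_r| > d_max},

so a perfect replica scores exactly 0 and lower is better.  Any pair
deviating more than ``d_max`` (2 A by default, 5 A in relaxed mode) is
penalized out of contention.  An optional hard electrostatic filter
rejects scaffolds with any |PD deviation| above ``pd_filter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Atom

#: Spatial deviation cap (A): default and relaxed search modes.
DEFAULT_DMAX = 2.0
RELAXED_DMAX = 5.0


@dataclass
class ScoreConfig:
    """Knobs of the congruence score and acceptance rules.

    d_max        -- per-pair spatial deviation cap, A.
    big_penalty  -- score added per pair that exceeds d_max; large enough
                    that one violation alone eliminates the match.
    lambda_pd    -- weight (1/(kT/e)) of the electrostatic deviation term,
                    chosen so typical PD deviations (tens of kT/e) weigh
                    comparably to A-scale spatial deviations.
    s_thresh     -- acceptance threshold; matches scoring above it are
                    discarded.  None -> per-motif default of 1.0 per pair,
                    i.e. n(n-1)/2.
    pd_filter    -- hard cap on any single |PD deviation| (kT/e); None
                    disables the electrostatic filter.
    """

    d_max: float = DEFAULT_DMAX
    big_penalty: float = 1e6
    lambda_pd: float = 0.01
    s_thresh: Optional[float] = None
    pd_filter: Optional[float] = 150.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.lambda_pd < 0:
            raise ValueError("lambda_pd must be non-negative")

    def threshold_for(self, n: int) -> float:
        """Effective acceptance threshold for a motif of n residues."""
        if self.s_thresh is not None:
            return self.s_thresh
        return n * (n - 1) / 2 * 1.0


@dataclass
class ClaspScore:
    spatial: float  # A
    electrostatic: float  # kT/e
    violations: int
    lambda_pd: float
    big_penalty: float

    @property
    def total(self) -> float:
        return (
            self.spatial
            + self.lambda_pd * self.electrostatic
            + self.violations * self.big_penalty
        )


def distance_matrix(atoms: Sequence[Atom]) -> np.ndarray:
    """Symmetric Euclidean distance matrix over functional atoms (A)."""
    if len(atoms) < 2:
        raise ValueError("need at least 2 atoms for a distance matrix")
    keys = [(a.chain_id, a.res_seq, a.icode, a.atom_name) for a in atoms]
    if len(set(keys)) != len(keys):
        raise ValueError("scaffold may not reuse an atom")
    coords = np.array([a.position for a in atoms])
    return squareform(pdist(coords))


def clasp_score(
    ref_d: np.ndarray,
    cand_d: np.ndarray,
    ref_pd: Optional[np.ndarray],
    cand_pd: Optional[np.ndarray],
    config: ScoreConfig,
) -> ClaspScore:
    """Congruence score of a candidate scaffold against the reference.

    PD matrices may both be None (electrostatics disabled); then the
    electrostatic component is 0.
    """
    ref_d = np.asarray(ref_d, float)
    cand_d = np.asarray(cand_d, float)
    if ref_d.shape != cand_d.shape:
        raise ValueError(f"dimension mismatch: {ref_d.shape} vs {cand_d.shape}")
    n = ref_d.shape[0]
    iu = np.triu_indices(n, k=1)
    dev_d = np.abs(cand_d - ref_d)[iu]
    spatial = float(dev_d.sum())
    violations = int(np.count_nonzero(dev_d > config.d_max))

    if (ref_pd is None) != (cand_pd is None):
        raise ValueError("reference and candidate must both have, or lack, PD matrices")
    if ref_pd is None:
        electrostatic = 0.0
    else:
        ref_pd = np.asarray(ref_pd, float)
        cand_pd = np.asarray(cand_pd, float)
        if ref_pd.shape != ref_d.shape or cand_pd.shape != ref_d.shape:
            raise ValueError("PD matrix dimensions do not match D matrices")
        electrostatic = float(np.abs(cand_pd - ref_pd)[iu].sum())

    return ClaspScore(
        spatial=spatial,
        electrostatic=electrostatic,
        violations=violations,
        lambda_pd=config.lambda_pd,
        big_penalty=config.big_penalty,
    )


def pd_compatible(
    ref_pd: Optional[np.ndarray],
    cand_pd: Optional[np.ndarray],
    config: ScoreConfig,
) -> tuple[bool, list[tuple[int, int, bool]]]:
    """Hard electrostatic filter: every |PD deviation| <= pd_filter.

    Returns (verdict, per-pair [(i, j, ok), ...]).  Disabled filter or
    absent PD data -> trivially compatible with an empty verdict list.
    """
    if config.pd_filter is None or ref_pd is None or cand_pd is None:
        return True, []
    ref_pd = np.asarray(ref_pd, float)
    cand_pd = np.asarray(cand_pd, float)
    if ref_pd.shape != cand_pd.shape:
        raise ValueError("dimension mismatch between PD matrices")
    n = ref_pd.shape[0]
    verdicts = []
    ok_all = True
    for i in range(n):
        for j in range(i + 1, n):
            ok = abs(cand_pd[i, j] - ref_pd[i, j]) <= config.pd_filter
            verdicts.append((i, j, ok))
            ok_all = ok_all and ok
    return ok_all, verdicts
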