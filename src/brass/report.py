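"""Tab-separated report formats.

Match reports follow the layout of the published congruence tables: one
row per scaffold with the concatenated atom labels (``GLY38N,...``), the
pairwise distance row in A and the pairwise potential-difference row in
kT/e, both to 1 decimal, plus the score breakdown and the acceptance
verdict.  Header comment lines (#) name the units.
"""

from __future__ import annotations

import io
import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .congruence import ScoreConfig
from .electrostatics import upper_pairs
from .index import BrassResult, frequency_distribution
from .search import ScaffoldMatch
from .structure import Motif

_PAIR_LETTERS = "abcde"


def pair_names(n: int) -> list[str]:
    return [f"{a}{b}" for a, b in itertools.combinations(_PAIR_LETTERS[:n], 2)]


def _fmt_row(values: Optional[np.ndarray], n: int) -> list[str]:
    if values is None:
        return ["NA"] * (n * (n - 1) // 2)
    return [f"{v:.1f}" for v in values]


def format_match_report(
    matches: Sequence[ScaffoldMatch],
    motif: Motif,
    config: ScoreConfig,
    potential_mode: str = "none",
    seed: Optional[int] = None,
) -> str:
    """Scored-scaffold table; distances in A, potential differences in kT/e."""
    n = motif.n
    names = pair_names(n)
    header = (
        ["scaffold"]
        + [f"D_{p}" for p in names]
        + [f"PD_{p}" for p in names]
        + ["spatial_A", "electrostatic_kT_e", "violations", "score", "accepted", "reasons"]
    )
    lines = [
        f"# brass match report: structure={motif.structure_id} motif_n={n}",
        f"# units: D in Angstrom, PD in kT/e; potential source: {potential_mode}",
        f"# d_max={config.d_max} s_thresh={config.threshold_for(n)} "
        f"lambda_pd={config.lambda_pd} pd_filter={config.pd_filter}"
        + (f" seed={seed}" if seed is not None else ""),
        "\t".join(header),
    ]
    for m in matches:
        row = (
            [m.label]
            + _fmt_row(upper_pairs(m.d), n)
            + _fmt_row(None if m.pd is None else upper_pairs(m.pd), n)
            + [
                f"{m.score.spatial:.3f}",
                f"{m.score.electrostatic:.3f}",
                str(m.score.violations),
                f"{m.score.total:.3f}",
                "yes" if m.accepted else "no",
                ";".join(m.rejection_reasons),
            ]
        )
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_match_report(text: str) -> pd.DataFrame:
    """Read a match report back; D/PD columns come out numeric (NA allowed)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    for col in df.columns:
        if col.startswith(("D_", "PD_")):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def format_ranking(results: Sequence[BrassResult]) -> str:
    """Per-protein index table, ascending BrassIndex."""
    lines = [
        "# brass ranking: raw_index and BrassIndex per structure",
        "\t".join(
            ["structure_id", "length", "description", "n_accepted", "raw_index", "brass_index"]
        ),
    ]
    for r in sorted(results, key=lambda r: (r.brass_index or 0.0, r.structure_id)):
        lines.append(
            "\t".join(
                [
                    r.structure_id,
                    "" if r.length is None else str(r.length),
                    r.description,
                    str(len(r.matches)),
                    f"{r.raw_index:.4f}",
                    "" if r.brass_index is None else f"{r.brass_index:.4f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def format_histogram(results: Sequence[BrassResult], bin_width: float = 0.1) -> str:
    """Frequency distribution of both the normalized and the raw index."""
    lines = [
        "# brass index frequency distribution (half-open bins [lo, hi))",
        "\t".join(["index_kind", "bin_lo", "bin_hi", "count"]),
    ]
    for kind, use_raw in (("brass", False), ("raw", True)):
        edges, counts = frequency_distribution(results, bin_width, use_raw=use_raw)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            lines.append(f"{kind}\t{lo:.4f}\t{hi:.4f}\t{int(c)}")
    return "\n".join(lines) + "\n"
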