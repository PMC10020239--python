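"""Chromosome-content normalization and multiplicity classification.

The integrated (background-subtracted) DNA signal of a cell scales with the
number of chromosome copies it holds. Normalizing each cell's sum signal by
the median over reference cells with a single ori and a single ter focus
puts monomers at ~1, dimers at ~2, and so on; combined with the ori/ter
focus counts this classifies cells as monomer / dimer / multimer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MULT_MONOMER = "monomer"
MULT_DIMER = "dimer"
MULT_MULTIMER = "multimer"


@dataclass
class PloidyRecord:
    sum_dna_intensity: float
    normalized_sum: float
    ori_count: int
    ter_count: int
    multiplicity_class: str = ""
    topology: str = ""


def normalized_sum_signal(
    sum_intensities: np.ndarray | list[float],
    ori_counts: np.ndarray | list[int],
    ter_counts: np.ndarray | list[int],
) -> np.ndarray:
    """Normalize per-cell summed DNA intensity to 1-ori/1-ter reference cells.

    Each cell's background-subtracted sum DNA intensity is divided by the
    median over cells with exactly one ori and one ter focus, so the
    reference population has median 1 by construction. Raises when there is
    no reference cell. The statistic is invariant to a uniform gain applied
    to the whole field of view, since the gain cancels through the median.
    """
    sums = np.asarray(sum_intensities, float)
    ori = np.asarray(ori_counts)
    ter = np.asarray(ter_counts)
    ref = sums[(ori == 1) & (ter == 1)]
    if ref.size == 0:
        raise ValueError("no reference cells with 1 ori and 1 ter focus")
    return sums / float(np.median(ref))


def ori_per_ter_table(
    ori_counts: np.ndarray | list[int],
    ter_counts: np.ndarray | list[int],
    min_group_size: int = 6,
) -> tuple[pd.DataFrame, list[int]]:
    """Group cells by ter count; per-group mean +- sd of ori count.

    Groups smaller than ``min_group_size`` are excluded from the table and
    returned separately (mirroring low-statistics exclusions in population
    plots).

    Returns ``(table, excluded_ter_counts)``; the table has columns
    ``ter_count, n, mean_ori, sd_ori`` plus one histogram dict per group.
    """
    ori = np.asarray(ori_counts)
    ter = np.asarray(ter_counts)
    rows = []
    excluded = []
    for t in sorted(set(ter.tolist())):
        grp = ori[ter == t]
        if len(grp) < min_group_size:
            excluded.append(int(t))
            continue
        values, counts = np.unique(grp, return_counts=True)
        rows.append(
            {
                "ter_count": int(t),
                "n": int(len(grp)),
                "mean_ori": float(grp.mean()),
                "sd_ori": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
                "ori_histogram": {int(v): int(c) for v, c in zip(values, counts)},
            }
        )
    return pd.DataFrame(rows), excluded


def fit_gaussian_means(
    grouped_values: dict[int, np.ndarray | list[float]],
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Maximum-likelihood Gaussian fit (sample mean, sd) per group.

    Groups below ``min_group_size`` are skipped; a degenerate sd of 0 keeps
    the mean and flags the group.
    """
    rows = []
    for key in sorted(grouped_values):
        vals = np.asarray(grouped_values[key], float)
        if len(vals) < min_group_size:
            continue
        sd = float(vals.std(ddof=1))
        rows.append(
            {
                "group": key,
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "sd": sd,
                "degenerate_sd": bool(sd == 0.0),
            }
        )
    return pd.DataFrame(rows)


def classify_multiplicity(
    ori_count: int,
    ter_count: int,
    normalized_sum: float,
    dimer_low: float = 1.5,
    dimer_high: float = 3.0,
) -> str:
    """Monomer / dimer / multimer call from focus counts and DNA content.

    Thresholds default to the midpoints between integer chromosome
    equivalents: monomer below 1.5, dimer in [1.5, 3), multimer above (or
    whenever there are >= 2 ter foci with content outside the dimer band).
    """
    if ori_count <= 2 and ter_count <= 1 and normalized_sum < dimer_low:
        return MULT_MONOMER
    if ori_count == 2 and ter_count == 2 and dimer_low <= normalized_sum < dimer_high:
        return MULT_DIMER
    if ter_count >= 2 or normalized_sum >= dimer_high:
        return MULT_MULTIMER
    # ambiguous light cells with extra oris: call by content
    return MULT_MONOMER if normalized_sum < dimer_low else MULT_MULTIMER
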