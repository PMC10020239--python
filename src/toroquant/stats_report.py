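"""Population statistics: one-way ANOVA and significance-star conventions.

Group differences are assessed with a single-factor (one-way) ANOVA via the
classic between/within sum-of-squares decomposition; p-values come from the
F distribution with (k-1, N-k) degrees of freedom. Stars follow the usual
convention (ns above 0.05, then *, **, ***, **** at 0.05, 0.01, 0.001,
0.0001), with boundary p-values assigned to the more significant bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    labels: list[str]
    n: list[int]
    means: list[float]
    sds: list[float]
    sems: list[float]
    F: float
    p: float
    stars: str
    flags: str = ""


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Single-factor ANOVA F statistic and p-value.

    Classic decomposition: SSB = sum_g n_g (mean_g - grand)^2 with k-1
    degrees of freedom, SSW = sum_g sum_i (x_gi - mean_g)^2 with N-k. For
    two groups F equals the squared two-sample (pooled) t statistic.

    Degenerate inputs: zero within-group variance with unequal means gives
    F = inf, p = 0; fully identical data gives F = 0 (no variance to
    explain), p = 1.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    N = sum(len(a) for a in arrays)
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, N - k

    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def significance_stars(p: float) -> str:
    """Star label for a p-value; boundaries go to the more significant bin."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(
    data: dict[str, Sequence[float]],
) -> GroupComparison:
    """ANOVA across named groups with summary statistics and stars."""
    labels = list(data)
    arrays = [np.asarray(data[k], float) for k in labels]
    F, p = one_way_anova(arrays)
    return GroupComparison(
        labels=labels,
        n=[len(a) for a in arrays],
        means=[float(a.mean()) for a in arrays],
        sds=[float(a.std(ddof=1)) for a in arrays],
        sems=[float(a.std(ddof=1) / np.sqrt(len(a))) for a in arrays],
        F=F,
        p=p,
        stars=significance_stars(p),
    )


#: Reporting convention per metric: dispersion statistic and central summary.
METRIC_CONVENTIONS: dict[str, dict] = {
    "dna_in_mukb_percent": {"center": "mean", "spread": "sd"},
    "mukb_in_dna_percent": {"center": "mean", "spread": "sd"},
    "compaction_ratio": {"center": "mean", "spread": "sem"},
    "contour_length_um": {"center": "mean", "spread": "sem"},
    "width_fwhm_um": {"center": "mean", "spread": "sem"},
    "feret_diameter_um": {"center": "mean", "spread": "sd"},
    "asymmetricity_dna": {"center": "median", "spread": "sd"},
    "asymmetricity_mukb": {"center": "median", "spread": "sd"},
    "normalized_sum": {"center": "median", "spread": "sd"},
}

#: Binary (fraction-of-cells) metrics get binomial standard deviations.
BINARY_METRICS = ("ori_overlaps_mukb", "ter_overlaps_mukb")


def summarize_population(
    table: pd.DataFrame,
    grouping: str = "strain_label",
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group summary of a cell results table.

    QC-discarded cells are dropped. Numeric metrics are summarized with the
    convention registered for them (mean+-sd, mean+-sem, or median);
    binary colocalization metrics as fractions with binomial sd. Empty
    groups are omitted. Deterministic: identical tables give identical
    summaries.
    """
    df = table.copy()
    if "discarded" in df.columns:
        df = df[~df["discarded"].eq(True)]
    if metrics is None:
        metrics = [m for m in METRIC_CONVENTIONS if m in df.columns] + [
            m for m in BINARY_METRICS if m in df.columns
        ]
    rows = []
    for label, grp in df.groupby(grouping, sort=True):
        for metric in metrics:
            vals = pd.to_numeric(grp[metric], errors="coerce").dropna().to_numpy()
            n = len(vals)
            if n == 0:
                continue
            if metric in BINARY_METRICS:
                frac = float(vals.mean())
                sd = float(np.sqrt(frac * (1 - frac) / n)) if n else float("nan")
                rows.append(
                    {
                        "group": label,
                        "metric": metric,
                        "n": n,
                        "center": frac,
                        "center_stat": "fraction",
                        "spread": sd,
                        "spread_stat": "binomial_sd",
                        "flags": "",
                    }
                )
                continue
            conv = METRIC_CONVENTIONS.get(metric, {"center": "mean", "spread": "sd"})
            center = float(np.median(vals)) if conv["center"] == "median" else float(
                vals.mean()
            )
            if n < 2:
                spread, flags = float("nan"), "sd undefined (n=1)"
            elif conv["spread"] == "sem":
                spread, flags = float(vals.std(ddof=1) / np.sqrt(n)), ""
            else:
                spread, flags = float(vals.std(ddof=1)), ""
            rows.append(
                {
                    "group": label,
                    "metric": metric,
                    "n": n,
                    "center": center,
                    "center_stat": conv["center"],
                    "spread": spread,
                    "spread_stat": conv["spread"],
                    "flags": flags,
                }
            )
    return pd.DataFrame(rows)


def render_report_figures(
    table: pd.DataFrame,
    outdir,
    grouping: str = "strain_label",
    metrics: Sequence[str] = ("asymmetricity_dna", "asymmetricity_mukb", "compaction_ratio"),
):
    """Violin/histogram figures regenerated from the results table only.

    One PNG per metric with one violin per group; written into ``outdir``.
    Returns the list of written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = table.copy()
    if "discarded" in df.columns:
        df = df[~df["discarded"].eq(True)]
    written = []
    for metric in metrics:
        if metric not in df.columns:
            continue
        groups = []
        labels = []
        for label, grp in df.groupby(grouping, sort=True):
            vals = pd.to_numeric(grp[metric], errors="coerce").dropna().to_numpy()
            if len(vals):
                groups.append(vals)
                labels.append(f"{label}\n(n={len(vals)})")
        if not groups:
            continue
        fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.2))
        parts = ax.violinplot(groups, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = outdir / f"{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def render_report_markdown(summary: pd.DataFrame) -> str:
    """Render a population summary as a deterministic Markdown table."""
    lines = [
        "# Population summary",
        "",
        "| group | metric | n | value | spread |",
        "|---|---|---|---|---|",
    ]
    for _, row in summary.iterrows():
        spread = "" if np.isnan(row["spread"]) else f"{row['spread']:.4g} ({row['spread_stat']})"
        lines.append(
            f"| {row['group']} | {row['metric']} | {row['n']} | "
            f"{row['center']:.4g} ({row['center_stat']}) | {spread} |"
        )
    return "\n".join(lines) + "\n"
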