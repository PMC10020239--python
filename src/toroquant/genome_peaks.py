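"""Peak counts around the replication origin on a circular genome.

Counts binding-site peaks whose midpoints fall within a window on either
side of oriC — upstream meaning increasing genomic coordinate, downstream
decreasing, both with circular wrap — and expresses the imbalance as the
relative excess of upstream over downstream peaks in percent. Note the
upstream/downstream labels are coordinate conventions; mapping them onto
the physical right/left chromosome arm depends on the genome build's
orientation.
"""

from __future__ import annotations

import numpy as np

from .imaging_io import PeakSet


def window_peaks(peaks: PeakSet, window_bp: int) -> tuple[int, int]:
    """Count peak midpoints within window_bp up/downstream of ori.

    A midpoint at offset d = (mid - ori) mod L is upstream when
    0 < d <= window_bp and downstream when 0 < L - d <= window_bp.
    Midpoints exactly at ori count for neither side.
    """
    L = peaks.genome_length_bp
    if window_bp > L / 2:
        raise ValueError("window_bp must not exceed half the genome length")
    mids = peaks.midpoints()
    offsets = (mids - peaks.ori_position_bp) % L
    n_up = int(((offsets > 0) & (offsets <= window_bp)).sum())
    n_down = int(((offsets > 0) & ((L - offsets) <= window_bp)).sum())
    return n_up, n_down


def arm_excess(n_up: int, n_down: int) -> float:
    """Relative excess of upstream peaks: 100 * (n_up - n_down) / n_down.

    Undefined (NaN) when there are no downstream peaks.
    """
    if n_down == 0:
        return float("nan")
    return 100.0 * (n_up - n_down) / n_down


def ori_window_summary(peaks: PeakSet, window_bp: int = 500_000) -> dict:
    n_up, n_down = window_peaks(peaks, window_bp)
    return {
        "window_bp": window_bp,
        "n_upstream": n_up,
        "n_downstream": n_down,
        "upstream_excess_percent": arm_excess(n_up, n_down),
    }
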