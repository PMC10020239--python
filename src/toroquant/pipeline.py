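"""End-to-end per-cell analysis: segment, measure, tabulate.

``analyze_stack`` takes one multi-channel field of view (phase, dna, mukb,
ori, ter — any subset containing phase and dna), segments cells from phase
contrast, and computes every downstream quantity per cell: thresholded
channel masks, cluster counts, backbone morphometry (topology, contour
length, FWHM width, MukB-cluster Feret diameter), foci counts with the
more-ter-than-ori discard rule, intensity-overlap colocalization in both
directions, binary ori/ter-MukB colocalization, the compaction ratio, the
arm-asymmetry statistic for DNA and MukB, and the ploidy quantities.
Metrics whose input channels are missing are left absent; the run
continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ploidy as ploidy_mod
from .asymmetry import asymmetricity, center_of_mass
from .config import ImagingConfig, DEFAULT_CONFIG
from .imaging_io import MultiChannelStack, deconvolve_stack, max_project, results_table
from .morphometry import (
    classify_topology,
    contour_length,
    extract_backbone,
    feret_diameter,
    width_fwhm,
)
from .quantify import (
    colocalization,
    compaction_ratio,
    detect_foci,
    focus_overlaps_mask,
    qc_foci,
)
from .segmentation import QC_OK, label_clusters, segment_cells, threshold_channel

log = logging.getLogger("toroquant")


@dataclass
class CellRecord:
    """Raw per-cell analysis products (masks and sets), pre-tabulation."""

    cell_id: int
    qc_flag: str
    row: dict


def analyze_stack(
    stack: MultiChannelStack,
    strain_label: str = "",
    config: ImagingConfig = DEFAULT_CONFIG,
    keep_flagged_cells: bool = False,
) -> pd.DataFrame:
    """Analyze one field of view into a per-cell results table.

    Cells flagged by segmentation QC (touching neighbours, clipped at the
    border) are excluded from measurement unless ``keep_flagged_cells``;
    cells with more ter than ori foci are measured but marked discarded.
    """
    stack = max_project(stack)
    if config.deconvolve:
        stack = deconvolve_stack(stack, config)
    px = stack.pixel_size_um
    channels = stack.channel_names
    if "phase" not in channels or "dna" not in channels:
        raise ValueError("analysis requires at least phase and dna channels")

    phase = stack.plane("phase")
    dna = stack.plane("dna")
    mukb = stack.plane("mukb") if "mukb" in channels else None
    ori_img = stack.plane("ori") if "ori" in channels else None
    ter_img = stack.plane("ter") if "ter" in channels else None
    for name in ("mukb", "ori", "ter"):
        if name not in channels:
            log.warning("channel %r missing: dependent metrics left absent", name)

    cells = segment_cells(phase)
    rows = []
    for cid in cells.cell_ids:
        flag = cells.qc_flags[cid]
        if flag != QC_OK and not keep_flagged_cells:
            rows.append(
                {"cell_id": cid, "strain_label": strain_label, "qc_flag": flag,
                 "discarded": True}
            )
            continue
        row = _analyze_cell(
            cid, flag, cells, dna, mukb, ori_img, ter_img, px, config, strain_label
        )
        rows.append(row)
    df = results_table(rows)
    measured = df[~df["discarded"].eq(True)]
    if len(measured):
        try:
            df["normalized_sum"] = ploidy_mod.normalized_sum_signal(
                df["sum_dna_intensity"].fillna(0.0).to_numpy(),
                df["ori_count"].fillna(-1).to_numpy(),
                df["ter_count"].fillna(-1).to_numpy(),
            )
        except ValueError:
            log.warning("no 1-ori/1-ter reference cells: normalized_sum left absent")
        else:
            df["multiplicity_class"] = [
                ploidy_mod.classify_multiplicity(int(o), int(t), float(s))
                if np.isfinite(s) and o >= 0 and t >= 0
                else ""
                for o, t, s in zip(
                    df["ori_count"].fillna(-1),
                    df["ter_count"].fillna(-1),
                    df["normalized_sum"],
                )
            ]
    return df


def _analyze_cell(
    cid, flag, cells, dna, mukb, ori_img, ter_img, px, config, strain_label
) -> dict:
    cell_mask = cells.mask_of(cid)
    row: dict = {
        "cell_id": cid,
        "strain_label": strain_label,
        "qc_flag": flag,
        "discarded": False,
    }

    dna_cm = threshold_channel(dna, cells, cid, config, channel="dna")
    row["dna_threshold"] = dna_cm.threshold
    row["sum_dna_intensity"] = float(
        np.clip(dna - dna_cm.background, 0, None)[cell_mask].sum()
    )

    _, dna_clusters, _ = label_clusters(dna_cm, dna, config.min_cluster_px)
    row["dna_cluster_count"] = len(dna_clusters)

    bb = extract_backbone(dna_cm, dna, config)
    row["topology"] = classify_topology(bb)
    row["contour_length_um"] = contour_length(bb, px)
    fwhm, n_valid, _ = width_fwhm(bb, dna, px)
    row["width_fwhm_um"] = fwhm

    mukb_cm = None
    if mukb is not None:
        mukb_cm = threshold_channel(mukb, cells, cid, config, channel="mukb")
        row["mukb_threshold"] = mukb_cm.threshold
        _, mukb_clusters, _ = label_clusters(mukb_cm, mukb, config.min_cluster_px)
        row["mukb_cluster_count"] = len(mukb_clusters)
        if mukb_clusters:
            brightest = max(mukb_clusters, key=lambda c: c["sum_intensity"])
            row["feret_diameter_um"] = feret_diameter(brightest["coords"], px)
        coloc = colocalization(dna, mukb, dna_cm, mukb_cm, cell_mask)
        row["dna_in_mukb_percent"] = coloc.dna_in_mukb_percent
        row["mukb_in_dna_percent"] = coloc.mukb_in_dna_percent
        comp = compaction_ratio(dna, dna_cm, mukb_cm)
        row["compaction_ratio"] = comp.ratio

    ori_set = ter_set = None
    if ori_img is not None:
        ori_set = detect_foci(ori_img, cell_mask, "ori", config)
        row["ori_count"] = ori_set.count
    if ter_img is not None:
        ter_set = detect_foci(ter_img, cell_mask, "ter", config)
        row["ter_count"] = ter_set.count
    if ori_set is not None and ter_set is not None:
        keep, foci_flag = qc_foci(ori_set, ter_set)
        row["discarded"] = not keep
        if foci_flag:
            row["qc_flag"] = (flag + "+" + foci_flag) if flag != QC_OK else foci_flag

    if mukb_cm is not None:
        if ori_set is not None and ori_set.count:
            row["ori_overlaps_mukb"] = any(
                focus_overlaps_mask(f, mukb_cm, config, px) for f in ori_set.foci
            )
        if ter_set is not None and ter_set.count:
            row["ter_overlaps_mukb"] = any(
                focus_overlaps_mask(f, mukb_cm, config, px) for f in ter_set.foci
            )

    # arm asymmetry about the brightest ori focus
    if ori_set is not None and ori_set.count:
        if ori_set.count > 1:
            row["qc_flag"] = (row["qc_flag"] + "+multi_ori").lstrip("+") if row[
                "qc_flag"
            ] != QC_OK else "multi_ori"
        bright = ori_set.brightest()
        try:
            com = center_of_mass(
                np.clip(dna - dna_cm.background, 0, None), cell_mask
            )
            res_d = asymmetricity(
                dna, bright.center, com, config=config, channel="dna",
                background=dna_cm.background,
            )
            row["asymmetricity_dna"] = res_d.A
            if mukb is not None and mukb_cm is not None:
                res_m = asymmetricity(
                    mukb, bright.center, com, config=config, channel="mukb",
                    background=mukb_cm.background,
                )
                row["asymmetricity_mukb"] = res_m.A
        except ValueError:
            pass

    return row


def analyze_population(stack, truths=None, strain_label="", config=DEFAULT_CONFIG):
    """Analyze a rendered population; optionally join generator truth.

    When ``truths`` (list of GroundTruth) is given, measured cells are
    matched to true cells by nearest centre and truth columns are appended
    with a ``true_`` prefix for recovery studies.
    """
    df = analyze_stack(stack, strain_label=strain_label, config=config)
    if truths is None:
        return df

    phase = max_project(stack).plane("phase")
    cells = segment_cells(phase)
    centers = {}
    for cid in cells.cell_ids:
        rr, cc = np.nonzero(cells.labels == cid)
        centers[cid] = (rr.mean(), cc.mean())

    true_cols = {
        "true_topology": [],
        "true_contour_length_um": [],
        "true_fwhm_um": [],
        "true_apparent_fwhm_um": [],
        "true_dna_in_mukb_fraction": [],
        "true_arm_bias": [],
        "true_compaction_factor": [],
        "true_ori_count": [],
        "true_ter_count": [],
        "true_multiplicity": [],
    }
    for cid in df["cell_id"]:
        if np.isnan(cid) if isinstance(cid, float) else False:
            match = None
        else:
            c = centers.get(int(cid))
            match = None
            if c is not None and truths:
                dists = [
                    np.hypot(t.center_px[0] - c[0], t.center_px[1] - c[1])
                    for t in truths
                ]
                match = truths[int(np.argmin(dists))]
        if match is None:
            for col in true_cols:
                true_cols[col].append(np.nan)
            continue
        true_cols["true_topology"].append(match.topology)
        true_cols["true_contour_length_um"].append(match.true_contour_length_um)
        true_cols["true_fwhm_um"].append(match.true_fwhm_um)
        true_cols["true_apparent_fwhm_um"].append(match.true_apparent_fwhm_um)
        true_cols["true_dna_in_mukb_fraction"].append(match.true_dna_in_mukb_fraction)
        true_cols["true_arm_bias"].append(match.arm_bias)
        true_cols["true_compaction_factor"].append(match.compaction_factor)
        true_cols["true_ori_count"].append(match.true_focus_count.get("ori"))
        true_cols["true_ter_count"].append(match.true_focus_count.get("ter"))
        true_cols["true_multiplicity"].append(match.chromosome_multiplicity)
    for col, vals in true_cols.items():
        df[col] = vals
    return df
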