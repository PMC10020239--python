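"""Synthetic multi-channel images of widened *E. coli* cells with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a toroidal (or figure-eight, or open) chromosome rendered as a
Gaussian-profile tube along a parametric curve, a condensin (MukB) domain
occupying an angular arc of the ring with a controllable left/right arm
imbalance around the replication origin, locally increased DNA density
(compaction) inside the MukB domain, diffraction-limited ori/ter foci,
Gaussian PSF blur, and Poisson (plus optional Gaussian read) noise.

Every rendered cell carries a :class:`GroundTruth` record with the analytic
truths (contour length, tube FWHM, DNA fraction inside the MukB footprint,
focus positions and counts, topology, multiplicity) used by the recovery
tests.

Conventions
-----------
Angles are measured in math convention on the ring but in *image*
coordinates (origin top-left, y down): angle 90 deg places a point directly
above the ring centre on screen. The "right" arm is the clockwise side of
the oriented axis from the chromosome centre of mass to ori, which for an
ori at 90 deg is image-right.
"""

from __future__ import annotations

import json
import math
import hashlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .config import FWHM_FACTOR, DEFAULT_CONFIG

Topology = Literal["toroid", "figure_eight", "open"]
NoiseModel = Literal["none", "poisson", "poisson+gaussian"]

PHASE_BACKGROUND = 1000.0
PHASE_INTERIOR = 600.0
PHASE_HALO = 1300.0

CHANNEL_NAMES = ("phase", "dna", "mukb", "ori", "ter")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cell.

    Defaults are the wildtype study conditions: a toroid of contour length
    4.5 um (ring radius 0.716 um), tube sigma 0.187 um (pre-blur FWHM
    0.44 um), a MukB arc of +-35 deg centred on ori, compaction factor 1.8,
    MukB arm bias 0.33 and local DNA arm bias 0.27.
    """

    image_size: tuple[int, int] = (96, 96)
    pixel_size_um: float = 0.065
    topology: Topology = "toroid"
    ring_radius_um: float = 0.716
    tube_sigma_um: float = 0.187
    dna_total_intensity: float = 2.0e5
    mukb_total_intensity: float = 8.0e4
    focus_intensity: float = 8.0e3
    mukb_arc_center_deg: float = 90.0
    mukb_arc_halfwidth_deg: float = 35.0
    arm_bias: float = 0.33
    dna_arm_bias: float = 0.0
    dna_bias_radius_um: float = 0.65
    compaction_factor: float = 1.8
    ori_angles_deg: tuple[float, ...] = (90.0,)
    ter_angles_deg: tuple[float, ...] = (270.0,)
    psf_sigma_um: float = DEFAULT_CONFIG.psf_sigma_lateral_um
    noise_model: NoiseModel = "poisson"
    gaussian_sd: float = 2.0
    background_photons: float = 10.0
    chromosome_multiplicity: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.arm_bias <= 1.0):
            raise ValueError(f"arm_bias must be in [0, 1], got {self.arm_bias}")
        if not (0.0 <= self.dna_arm_bias <= 1.0):
            raise ValueError(f"dna_arm_bias must be in [0, 1], got {self.dna_arm_bias}")
        if self.compaction_factor < 1.0:
            raise ValueError(
                f"compaction_factor must be >= 1, got {self.compaction_factor}"
            )
        for name in ("ori_angles_deg", "ter_angles_deg"):
            angles = getattr(self, name)
            if not (1 <= len(angles) <= 4):
                raise ValueError(f"{name} must list 1-4 angles, got {len(angles)}")
        if self.chromosome_multiplicity < 1:
            raise ValueError("chromosome_multiplicity must be >= 1")
        # frame-fit check: ring diameter + 6 tube sigma inside the footprint,
        # footprint plus halo inside the frame
        if self.cell_radius_px + 3.0 > min(self.image_size) / 2.0:
            need = int(math.ceil(2 * (self.cell_radius_px + 3.0)))
            raise ValueError(
                "geometry does not fit the frame: cell footprint radius "
                f"{self.cell_radius_px:.1f} px needs an image of at least "
                f"{need}x{need} px, got {self.image_size[0]}x{self.image_size[1]}"
            )

    # -- pixel-unit helpers -------------------------------------------------
    @property
    def ring_radius_px(self) -> float:
        return self.ring_radius_um / self.pixel_size_um

    @property
    def tube_sigma_px(self) -> float:
        return self.tube_sigma_um / self.pixel_size_um

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um

    @property
    def cell_radius_px(self) -> float:
        """Radius of the simulated cell footprint (phase-contrast dark area)."""
        reach = self.ring_radius_px
        if self.topology == "figure_eight":
            reach = 3.0 * self.ring_radius_px  # two tangent loops side by side
        elif self.topology == "open":
            reach = math.pi * self.ring_radius_px  # half the bar length
        return reach + 3.0 * self.tube_sigma_px + 3.0


@dataclass
class GroundTruth:
    """Per-cell generative truth used as the oracle in recovery tests."""

    spec: SyntheticSpec
    center_px: tuple[float, float]  # (row, col) of the cell centre
    ori_positions_px: list[tuple[float, float]]  # (row, col)
    ter_positions_px: list[tuple[float, float]]
    true_contour_length_um: float = 0.0
    true_fwhm_um: float = 0.0
    true_apparent_fwhm_um: float = 0.0
    true_dna_in_mukb_fraction: float = 0.0
    true_focus_count: dict[str, int] = field(default_factory=dict)
    chromosome_multiplicity: int = 1
    topology: str = "toroid"
    arm_bias: float = 0.0
    compaction_factor: float = 1.0

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["spec"]["image_size"] = list(self.spec.image_size)
        return d


# ---------------------------------------------------------------------------
# geometry helpers


def _angle_diff_deg(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """Signed angular difference a - b wrapped to (-180, 180]."""
    return (np.asarray(a) - b + 180.0) % 360.0 - 180.0


def _loop_centers_px(spec: SyntheticSpec) -> list[tuple[float, float]]:
    """Centres (x, y offsets from cell centre, math coords) of each DNA loop."""
    if spec.topology == "figure_eight":
        r = spec.ring_radius_px
        return [(-r, 0.0), (r, 0.0)]
    return [(0.0, 0.0)]


def _ring_point_px(
    spec: SyntheticSpec, angle_deg: float, loop: int = 0
) -> tuple[float, float]:
    """(x, y) offset from the cell centre of the curve point at angle_deg.

    Math coordinates: x to image-right, y up-screen.
    """
    th = math.radians(angle_deg)
    if spec.topology == "open":
        half = math.pi * spec.ring_radius_px
        s = (angle_deg % 360.0) / 360.0 * 2.0 * half - half
        return (s, 0.0)
    cx, cy = _loop_centers_px(spec)[loop % len(_loop_centers_px(spec))]
    r = spec.ring_radius_px
    return (cx + r * math.cos(th), cy + r * math.sin(th))


def _field_grids(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Math-coordinate grids (x right, y up) about the frame centre."""
    h, w = spec.image_size
    c_row = (h - 1) / 2.0
    c_col = (w - 1) / 2.0
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    x = cols - c_col
    y = c_row - rows  # flip: y up
    return x + np.zeros((h, w)), y + np.zeros((h, w)), c_row, c_col


def render_noiseless(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Render the noiseless, unblurred channel fields of one cell.

    Foci are rendered at the PSF width (they are point sources, so the
    unblurred focus image already equals the blurred one); DNA and MukB are
    the pre-PSF object fields. Per-channel sums equal the spec totals to
    machine precision.
    """
    x, y, _, _ = _field_grids(spec)
    sigma = spec.tube_sigma_px

    # distance to the curve and local angle, per pixel
    if spec.topology == "open":
        half = math.pi * spec.ring_radius_px
        d = np.where(np.abs(x) <= half, np.abs(y), np.hypot(np.abs(x) - half, y))
        local_angle = ((x + half) / (2.0 * half)) * 360.0
    else:
        centers = _loop_centers_px(spec)
        dists, angles = [], []
        for cx, cy in centers:
            dx, dy = x - cx, y - cy
            dists.append(np.abs(np.hypot(dx, dy) - spec.ring_radius_px))
            angles.append(np.degrees(np.arctan2(dy, dx)) % 360.0)
        if len(centers) == 1:
            d, local_angle = dists[0], angles[0]
        else:
            stack_d = np.stack(dists)
            pick = np.argmin(stack_d, axis=0)
            d = np.take_along_axis(stack_d, pick[None], axis=0)[0]
            local_angle = np.take_along_axis(np.stack(angles), pick[None], axis=0)[0]

    profile = np.exp(-0.5 * (d / sigma) ** 2)
    profile[d > 6.0 * sigma] = 0.0

    in_arc = np.abs(_angle_diff_deg(local_angle, spec.mukb_arc_center_deg)) <= (
        spec.mukb_arc_halfwidth_deg
    )

    # side of the generative ori axis: +1 on the clockwise ("right") side of
    # the axis from the ring centre through the first ori
    ori_th = math.radians(spec.ori_angles_deg[0])
    ux, uy = math.cos(ori_th), math.sin(ori_th)
    cross = ux * y - uy * x
    sign_right = np.where(cross < 0, 1.0, np.where(cross > 0, -1.0, 0.0))

    dna = profile * (1.0 + (spec.compaction_factor - 1.0) * in_arc)
    if spec.dna_arm_bias > 0:
        ox, oy = _ring_point_px(spec, spec.ori_angles_deg[0], 0)
        r_bias = spec.dna_bias_radius_um / spec.pixel_size_um
        local = np.hypot(x - ox, y - oy) <= r_bias
        dna = dna * np.where(local, 1.0 + spec.dna_arm_bias * sign_right, 1.0)
    dna *= spec.dna_total_intensity / dna.sum()

    mukb = profile * in_arc * (1.0 + spec.arm_bias * sign_right)
    total = mukb.sum()
    if total > 0:
        mukb *= spec.mukb_total_intensity / total

    # diffraction-limited foci
    h, w = spec.image_size
    c_row, c_col = (h - 1) / 2.0, (w - 1) / 2.0
    s_psf = max(spec.psf_sigma_px, 0.0)

    def _render_foci(angles: Sequence[float]) -> np.ndarray:
        img = np.zeros((h, w))
        for i, ang in enumerate(angles):
            fx, fy = _ring_point_px(spec, ang, loop=i)
            row, col = c_row - fy, c_col + fx
            if s_psf > 0:
                spot = np.exp(
                    -0.5
                    * (
                        ((np.arange(h)[:, None] - row) ** 2)
                        + ((np.arange(w)[None, :] - col) ** 2)
                    )
                    / s_psf**2
                )
                img += spot * (spec.focus_intensity / spot.sum())
            else:
                img[int(round(row)), int(round(col))] += spec.focus_intensity
        return img

    ori_img = _render_foci(spec.ori_angles_deg)
    ter_img = _render_foci(spec.ter_angles_deg)

    # phase contrast: dark footprint on bright background with an edge halo
    centers = _loop_centers_px(spec)
    if spec.topology == "open":
        half = math.pi * spec.ring_radius_px
        dcell = np.where(np.abs(x) <= half, np.abs(y), np.hypot(np.abs(x) - half, y))
        body_r = 3.0 * spec.tube_sigma_px + 3.0
        interior = dcell <= body_r
        halo = np.abs(dcell - body_r) <= 1.5
    else:
        dcell = np.full((h, w), np.inf)
        for cx, cy in centers:
            dcell = np.minimum(dcell, np.hypot(x - cx, y - cy))
        body_r = spec.ring_radius_px + 3.0 * spec.tube_sigma_px + 3.0
        interior = dcell <= body_r
        halo = np.abs(dcell - body_r) <= 1.5
    phase = np.full((h, w), PHASE_BACKGROUND)
    phase[interior] = PHASE_INTERIOR
    phase[halo & ~interior] = PHASE_HALO

    # half-maximum footprints of the unweighted tube/arc, for ground truth
    m0 = profile * in_arc
    mukb_fp = m0 >= 0.5 * m0.max() if m0.max() > 0 else np.zeros((h, w), bool)
    dna_fp = profile >= 0.5

    return {
        "phase": phase,
        "dna": dna,
        "mukb": mukb,
        "ori": ori_img,
        "ter": ter_img,
        "_mukb_footprint": mukb_fp,
        "_dna_footprint": dna_fp,
    }


def _ground_truth(spec: SyntheticSpec, fields: dict[str, np.ndarray]) -> GroundTruth:
    h, w = spec.image_size
    c_row, c_col = (h - 1) / 2.0, (w - 1) / 2.0

    if spec.topology == "toroid":
        contour = 2.0 * math.pi * spec.ring_radius_um
    elif spec.topology == "figure_eight":
        contour = 2.0 * 2.0 * math.pi * spec.ring_radius_um
    else:
        contour = 2.0 * math.pi * spec.ring_radius_um  # bar of equal length

    dna = fields["dna"]
    footprint = fields["_mukb_footprint"]
    frac = float(dna[footprint].sum() / dna.sum()) if footprint.any() else 0.0

    def _pos(angles: Sequence[float]) -> list[tuple[float, float]]:
        out = []
        for i, ang in enumerate(angles):
            fx, fy = _ring_point_px(spec, ang, loop=i)
            out.append((c_row - fy, c_col + fx))
        return out

    return GroundTruth(
        spec=spec,
        center_px=(c_row, c_col),
        ori_positions_px=_pos(spec.ori_angles_deg),
        ter_positions_px=_pos(spec.ter_angles_deg),
        true_contour_length_um=contour,
        true_fwhm_um=FWHM_FACTOR * spec.tube_sigma_um,
        true_apparent_fwhm_um=FWHM_FACTOR
        * math.hypot(spec.tube_sigma_um, spec.psf_sigma_um),
        true_dna_in_mukb_fraction=frac,
        true_focus_count={
            "ori": len(spec.ori_angles_deg),
            "ter": len(spec.ter_angles_deg),
        },
        chromosome_multiplicity=spec.chromosome_multiplicity,
        topology=spec.topology,
        arm_bias=spec.arm_bias,
        compaction_factor=spec.compaction_factor,
    )


def _apply_optics_and_noise(
    spec: SyntheticSpec, fields: dict[str, np.ndarray], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """PSF blur (zero-padded boundaries), background, then detection noise."""
    out = {}
    s = spec.psf_sigma_px
    for name, img in fields.items():
        if name.startswith("_"):
            continue
        img = img.astype(float)
        if name in ("dna", "mukb") and s > 0:
            img = ndimage.gaussian_filter(img, sigma=s, mode="constant")
        if name != "phase" and spec.noise_model != "none":
            img = img + spec.background_photons
        if spec.noise_model in ("poisson", "poisson+gaussian"):
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.noise_model == "poisson+gaussian" and spec.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_sd, img.shape)
        out[name] = img
    return out


def render_cell(spec: SyntheticSpec):
    """Render one cell; returns ``(MultiChannelStack, GroundTruth)``.

    Before noise and blur the per-channel summed intensities equal the spec
    totals to machine precision. With ``noise_model='none'`` no background
    is added, so conservation holds on the returned image as well (up to the
    <1% loss PSF blur leaks over the frame edge).
    """
    from .imaging_io import MultiChannelStack

    fields = render_noiseless(spec)
    truth = _ground_truth(spec, fields)
    rng = np.random.default_rng([spec.seed])
    noisy = _apply_optics_and_noise(spec, fields, rng)
    stack = MultiChannelStack(
        channels={k: v[None] for k, v in noisy.items()},
        pixel_size_um=spec.pixel_size_um,
        z_step_um=DEFAULT_CONFIG.z_step_um,
    )
    return stack, truth


def render_population(
    specs: Sequence[SyntheticSpec],
    layout: str = "grid",
    margin_px: int = 8,
    seed: int = 0,
):
    """Render many cells in one field of view.

    Cells are placed on a grid (or at seeded random grid positions) with at
    least ``margin_px`` between their footprints; ``margin_px=0`` (or
    negative) produces deliberately touching cells for segmentation-QC
    fixtures. Deterministic for a given seed: each cell draws its shot noise
    from a stream derived from ``(seed, cell index)`` and the background from
    a dedicated stream, so images are bit-identical across reruns.

    Returns ``(MultiChannelStack, list[GroundTruth])``.
    """
    from .imaging_io import MultiChannelStack

    if layout not in ("grid", "random"):
        raise ValueError(f"unknown layout {layout!r}")

    n = len(specs)
    first = specs[0] if n else SyntheticSpec()
    tile_sizes = []
    for s in specs:
        t = int(math.ceil(2 * (s.cell_radius_px + 3.5)))
        tile_sizes.append(t + 1 if t % 2 == 0 else t)
    max_tile = max(tile_sizes, default=int(math.ceil(2 * (first.cell_radius_px + 3.5))))
    # pitch measures centre-to-centre distance so that footprints are
    # separated by >= margin_px of background; margin 0 is clamped to a
    # 1 px gap so that touching-cell fixtures stay individually resolvable
    gap = max(int(margin_px), 1)
    max_radius = max((s.cell_radius_px for s in specs), default=10.0)
    pitch = 2 * int(math.floor(max_radius)) + 1 + gap
    ncols = max(1, int(math.ceil(math.sqrt(n)))) if n else 1
    nrows = max(1, int(math.ceil(n / ncols))) if n else 1
    H = (nrows - 1) * pitch + max_tile + 4
    W = (ncols - 1) * pitch + max_tile + 4

    order = list(range(n))
    rng_layout = np.random.default_rng([seed, 0x1A])
    if layout == "random":
        rng_layout.shuffle(order)

    shape = (H, W)
    canvas = {name: np.zeros(shape) for name in CHANNEL_NAMES}
    canvas["phase"] += PHASE_BACKGROUND
    truths: list[GroundTruth] = [None] * n  # type: ignore[list-item]

    noise_model = first.noise_model if n else "none"
    for slot, idx in enumerate(order):
        spec = specs[idx]
        tile_h = tile_w = tile_sizes[idx]
        cell_spec = replace(spec, image_size=(tile_h, tile_w), noise_model="none")
        fields = render_noiseless(cell_spec)
        truth = _ground_truth(cell_spec, fields)

        center_r = (slot // ncols) * pitch + max_tile // 2 + 2
        center_c = (slot % ncols) * pitch + max_tile // 2 + 2
        r0 = min(max(center_r - tile_h // 2, 0), H - tile_h)
        c0 = min(max(center_c - tile_w // 2, 0), W - tile_w)

        s = spec.psf_sigma_px
        rng_cell = np.random.default_rng([seed, 1 + idx])
        for name in CHANNEL_NAMES:
            img = fields[name]
            if name in ("dna", "mukb") and s > 0:
                img = ndimage.gaussian_filter(img, sigma=s, mode="constant")
            if name == "phase":
                sub = canvas["phase"][r0 : r0 + tile_h, c0 : c0 + tile_w]
                # composite: interiors darken by min; halos brighten only
                # untouched background so merged neighbours are not re-split
                halo = img > PHASE_BACKGROUND
                np.minimum(sub, img, out=sub)
                paint = halo & (sub >= PHASE_BACKGROUND)
                sub[paint] = img[paint]
            else:
                if spec.noise_model in ("poisson", "poisson+gaussian"):
                    img = rng_cell.poisson(np.clip(img, 0, None)).astype(float)
                canvas[name][r0 : r0 + tile_h, c0 : c0 + tile_w] += img

        truth.center_px = (truth.center_px[0] + r0, truth.center_px[1] + c0)
        truth.ori_positions_px = [(r + r0, c + c0) for r, c in truth.ori_positions_px]
        truth.ter_positions_px = [(r + r0, c + c0) for r, c in truth.ter_positions_px]
        truths[idx] = truth

    rng_bg = np.random.default_rng([seed, 0xBEEF])
    if n and noise_model != "none":
        for name in ("dna", "mukb", "ori", "ter"):
            canvas[name] += rng_bg.poisson(first.background_photons, shape)
        canvas["phase"] = rng_bg.poisson(np.clip(canvas["phase"], 0, None)).astype(
            float
        )
        if noise_model == "poisson+gaussian" and first.gaussian_sd > 0:
            for name in ("dna", "mukb", "ori", "ter"):
                canvas[name] += rng_bg.normal(0.0, first.gaussian_sd, shape)

    stack = MultiChannelStack(
        channels={k: v[None] for k, v in canvas.items()},
        pixel_size_um=first.pixel_size_um if n else 0.065,
        z_step_um=DEFAULT_CONFIG.z_step_um,
    )
    return stack, truths


# ---------------------------------------------------------------------------
# strain presets — the study conditions


#: Per-strain generative presets. Contour lengths, tube widths, compaction
#: factors, arm biases and the per-cell probability that the MukB domain sits
#: over ter are the population values the analysis is exercised against.
STRAIN_PRESETS: dict[str, dict] = {
    "wildtype": dict(
        contour_length_um=4.5,
        tube_sigma_um=0.187,
        compaction_factor=1.8,
        arm_bias=0.33,
        dna_arm_bias=0.27,
        p_mukb_on_ter=0.04,
    ),
    "delta_matp": dict(
        contour_length_um=3.5,
        tube_sigma_um=0.191,
        compaction_factor=1.75,
        arm_bias=0.49,
        dna_arm_bias=0.32,
        p_mukb_on_ter=0.11,
    ),
    "mukb_eq": dict(
        contour_length_um=3.8,
        tube_sigma_um=0.174,
        compaction_factor=1.2,
        arm_bias=0.26,
        dna_arm_bias=0.25,
        p_mukb_on_ter=0.20,
    ),
}


def strain_spec(
    strain: str,
    seed: int = 0,
    mukb_on_ter: bool | None = None,
    **overrides,
) -> SyntheticSpec:
    """Build a SyntheticSpec from a strain preset.

    ``mukb_on_ter=True`` recentres the MukB arc on the terminus focus (the
    MatP-depleted phenotype); if None it is left on ori.
    """
    if strain not in STRAIN_PRESETS:
        raise ValueError(f"unknown strain {strain!r}; options: {sorted(STRAIN_PRESETS)}")
    p = STRAIN_PRESETS[strain]
    kw = dict(
        ring_radius_um=p["contour_length_um"] / (2.0 * math.pi),
        tube_sigma_um=p["tube_sigma_um"],
        compaction_factor=p["compaction_factor"],
        arm_bias=p["arm_bias"],
        dna_arm_bias=p["dna_arm_bias"],
        seed=seed,
    )
    if mukb_on_ter:
        kw["mukb_arc_center_deg"] = 270.0
    kw.update(overrides)
    return SyntheticSpec(**kw)


def sample_population_specs(
    strain: str, n: int, seed: int = 0, **overrides
) -> list[SyntheticSpec]:
    """Draw n per-cell specs for a strain with realistic cell-to-cell spread.

    Ring radius and ori angle jitter by a few percent; whether the MukB arc
    sits over ter is Bernoulli with the strain's preset probability.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    preset = STRAIN_PRESETS[strain]
    specs = []
    for i in range(n):
        radius = preset["contour_length_um"] / (2 * math.pi)
        radius *= 1.0 + 0.04 * rng.standard_normal()
        ori_angle = rng.uniform(0.0, 360.0)
        on_ter = bool(rng.random() < preset["p_mukb_on_ter"])
        arc_center = (ori_angle + 180.0) % 360.0 if on_ter else ori_angle
        specs.append(
            strain_spec(
                strain,
                seed=int(rng.integers(0, 2**31 - 1)),
                ring_radius_um=radius,
                ori_angles_deg=(ori_angle,),
                ter_angles_deg=((ori_angle + 180.0) % 360.0,),
                mukb_arc_center_deg=arc_center,
                **overrides,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# fixture suite


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write the canonical test fixtures plus ground-truth sidecars.

    Emits a noiseless toroid, a blurred+noisy toroid, a figure-eight dimer,
    a MatP-deletion-like cell (MukB arc over ter), and a >=50-cell wildtype
    population, each as a multi-channel TIFF with a JSON ground-truth
    sidecar, and a manifest listing files, seeds and the fixture SNR.

    Nothing is indexed in the manifest unless its files were fully written.
    """
    from .imaging_io import write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    entries = []

    def _emit(name: str, stack, truths) -> None:
        tiff = outdir / f"{name}.tif"
        side = outdir / f"{name}.truth.json"
        write_stack(stack, tiff)
        if not isinstance(truths, list):
            truths = [truths]
        side.write_text(
            json.dumps([t.to_json_dict() for t in truths], indent=1, sort_keys=True)
        )
        digest = hashlib.sha256(tiff.read_bytes()).hexdigest()
        entries.append(
            {
                "name": name,
                "tiff": tiff.name,
                "truth": side.name,
                "n_cells": len(truths),
                "sha256": digest,
            }
        )

    base = seed
    _emit(
        "toroid_noiseless",
        *render_cell(
            strain_spec("wildtype", seed=base, noise_model="none", psf_sigma_um=0.0)
        ),
    )
    _emit("toroid_noisy", *render_cell(strain_spec("wildtype", seed=base + 1)))
    _emit(
        "figure_eight_dimer",
        *render_cell(
            SyntheticSpec(
                topology="figure_eight",
                ring_radius_um=0.55,
                image_size=(160, 160),
                ori_angles_deg=(180.0, 0.0),
                ter_angles_deg=(300.0, 240.0),
                chromosome_multiplicity=2,
                dna_total_intensity=4.0e5,
                seed=base + 2,
            )
        ),
    )
    _emit(
        "matp_like",
        *render_cell(strain_spec("delta_matp", seed=base + 3, mukb_on_ter=True)),
    )
    pop_specs = sample_population_specs("wildtype", 50, seed=base + 4)
    _emit("population_wildtype", *render_population(pop_specs, seed=base + 4))

    manifest = {
        "seed": seed,
        "pixel_size_um": 0.065,
        "snr_note": (
            "Fluorescence photon budgets: DNA 2e5, MukB 8e4, foci 8e3 per "
            "spot over a 10-photon background; peak pixel SNR ~15-20 "
            "(Poisson-limited)."
        ),
        "fixtures": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
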