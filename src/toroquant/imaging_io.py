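"""Image stacks, results tables, and genomic peak files.

TIFF I/O goes through :mod:`tifffile`; calibration (pixel size, z-step) is
carried in the TIFF ImageDescription as JSON and is required on read —
there is no silent default. The per-cell results table is a pandas
DataFrame with a stable, documented column order written as CSV with a JSON
sidecar holding the analysis configuration. Genomic peak intervals come in
as BED (0-based half-open) on an explicitly circular genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import ImagingConfig, DEFAULT_CONFIG


@dataclass
class MultiChannelStack:
    """One field of view: per-channel z-stacks with physical calibration.

    ``channels`` maps channel name -> float array of shape (z, H, W); all
    channels share one shape. ``z_slices`` of 1 denotes a projection or a
    single-plane acquisition.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float = DEFAULT_CONFIG.z_step_um

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim == 2:
                self.channels[name] = arr[None]
            elif arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2-D or 3-D")

    @property
    def z_slices(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1], arr.shape[2]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def plane(self, name: str, z: int = 0) -> np.ndarray:
        return self.channels[name][z]


def write_stack(stack: MultiChannelStack, path: str | Path) -> Path:
    """Write a multi-channel stack as one TIFF (axes CZYX) with calibration."""
    path = Path(path)
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channel_names": names,
        "axes": "CZYX",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    channel_map: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> MultiChannelStack:
    """Read a multi-channel TIFF written by :func:`write_stack` (or similar).

    ``channel_map`` names the channels in file order; if omitted the names
    embedded in the TIFF description are used. Calibration must come from
    the file metadata or the keyword arguments — a stack without a pixel
    size is an error, never silently defaulted.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]  # C,Y,X -> C,1,Y,X
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape}")

    names = list(channel_map) if channel_map is not None else meta.get("channel_names")
    if names is None:
        raise ValueError(f"{path}: no channel names in metadata and none supplied")
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {len(names)} channel names for {data.shape[0]} channels"
        )

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            f"{path}: pixel size missing from metadata and not supplied; "
            "pass pixel_size_um explicitly"
        )
    zs = z_step_um if z_step_um is not None else meta.get("z_step_um", 0.227)

    channels = {name: data[i].astype(float) for i, name in enumerate(names)}
    return MultiChannelStack(channels=channels, pixel_size_um=float(px), z_step_um=zs)


def max_project(stack: MultiChannelStack) -> MultiChannelStack:
    """Maximum-intensity projection over z; idempotent."""
    return MultiChannelStack(
        channels={n: arr.max(axis=0, keepdims=True) for n, arr in stack.channels.items()},
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
    )


def gaussian_psf(sigma_px: float) -> np.ndarray:
    """Normalized 2-D Gaussian PSF kernel (support 4 sigma)."""
    r = max(1, int(np.ceil(4.0 * sigma_px)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(x**2 + y**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def deconvolve_stack(
    stack: MultiChannelStack,
    config: ImagingConfig | None = None,
    channels: Sequence[str] = ("dna", "mukb", "ori", "ter"),
) -> MultiChannelStack:
    """Richardson-Lucy restoration of fluorescence channels.

    Maximum-likelihood deconvolution under Poisson noise with the known
    Gaussian lateral PSF, applied plane-wise. Phase contrast (and any
    channel not listed) is passed through untouched.
    """
    from skimage.restoration import richardson_lucy

    cfg = config if config is not None else DEFAULT_CONFIG
    sigma_px = cfg.psf_sigma_lateral_um / stack.pixel_size_um
    psf = gaussian_psf(sigma_px)
    out: dict[str, np.ndarray] = {}
    for name, arr in stack.channels.items():
        if name not in channels:
            out[name] = arr.copy()
            continue
        planes = []
        for z in range(arr.shape[0]):
            img = arr[z].astype(float)
            peak = img.max()
            if peak <= 0:
                planes.append(img)
                continue
            restored = richardson_lucy(
                img / peak, psf, num_iter=cfg.rl_iterations, clip=False
            )
            planes.append(np.clip(restored, 0, None) * peak)
        out[name] = np.stack(planes)
    return MultiChannelStack(
        channels=out, pixel_size_um=stack.pixel_size_um, z_step_um=stack.z_step_um
    )


# ---------------------------------------------------------------------------
# results table

#: Stable column order of the per-cell results CSV. Percentages are 0-100,
#: asymmetricity values 0-1, lengths in um, counts non-negative integers.
RESULTS_COLUMNS = [
    "cell_id",
    "strain_label",
    "qc_flag",
    "discarded",
    "dna_threshold",
    "mukb_threshold",
    "dna_in_mukb_percent",
    "mukb_in_dna_percent",
    "ori_overlaps_mukb",
    "ter_overlaps_mukb",
    "compaction_ratio",
    "contour_length_um",
    "width_fwhm_um",
    "feret_diameter_um",
    "dna_cluster_count",
    "mukb_cluster_count",
    "ori_count",
    "ter_count",
    "asymmetricity_dna",
    "asymmetricity_mukb",
    "sum_dna_intensity",
    "normalized_sum",
    "topology",
    "multiplicity_class",
]


def results_table(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Build a CellResultsTable DataFrame with the canonical column order."""
    df = pd.DataFrame(list(rows))
    for col in RESULTS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in RESULTS_COLUMNS]
    df = df[RESULTS_COLUMNS + extra]
    _validate_results(df)
    return df

def _validate_results(df: pd.DataFrame) -> None:
    for col in ("dna_in_mukb_percent", "mukb_in_dna_percent"):
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if len(vals) and ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    for col in ("asymmetricity_dna", "asymmetricity_mukb"):
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if len(vals) and ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    for col in ("ori_count", "ter_count", "dna_cluster_count"):
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if len(vals) and (vals < 0).any():
            raise ValueError(f"{col} negative")


def write_results(
    table: pd.DataFrame, path: str | Path, config: ImagingConfig | None = None
) -> Path:
    """Write the results CSV plus a JSON sidecar with the configuration."""
    path = Path(path)
    _validate_results(table)
    table.to_csv(path, index=False)
    cfg = config if config is not None else DEFAULT_CONFIG
    sidecar = path.with_suffix(path.suffix + ".config.json")
    sidecar.write_text(json.dumps(asdict(cfg), indent=1, sort_keys=True))
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# genomic peaks on a circular genome


@dataclass(frozen=True)
class PeakSet:
    """Intervals on a circular genome, 0-based half-open.

    An interval with end <= start is interpreted as wrapping through the
    origin of coordinates.
    """

    starts: tuple[int, ...]
    ends: tuple[int, ...]
    genome_length_bp: int
    ori_position_bp: int

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")
        if not (0 <= self.ori_position_bp < self.genome_length_bp):
            raise ValueError("ori_position_bp outside the genome")
        for s in self.starts:
            if not (0 <= s < self.genome_length_bp):
                raise ValueError(f"interval start {s} outside the genome")

    def __len__(self) -> int:
        return len(self.starts)

    def midpoints(self) -> np.ndarray:
        """Interval midpoints with circular wrap handling."""
        mids = []
        L = self.genome_length_bp
        for s, e in zip(self.starts, self.ends):
            span = (e - s) % L or L
            mids.append((s + span / 2.0) % L)
        return np.asarray(mids)


def read_peaks(
    path: str | Path, genome_length_bp: int, ori_position_bp: int
) -> PeakSet:
    """Read peak intervals from BED (3+ columns; extra columns ignored).

    Intervals with end <= start are accepted as wrapping the coordinate
    origin of the circular genome; a malformed line raises with its line
    number.
    """
    starts, ends = [], []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if not (0 <= s < genome_length_bp) or not (0 <= e <= genome_length_bp):
                raise ValueError(f"{path}:{lineno}: coordinates outside genome")
            starts.append(s)
            ends.append(e)
    return PeakSet(
        starts=tuple(starts),
        ends=tuple(ends),
        genome_length_bp=genome_length_bp,
        ori_position_bp=ori_position_bp,
    )
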