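"""Synthetic droplet-emulsion generator.

Generates everything the downstream analysis needs without any real
microscope data: droplet placements with Poisson cell loading, ground
truth secreting cells, relocation kinetics from the forward in-droplet
binding model, and rendered two-channel 16-bit time-lapse image stacks.

Forward model
-------------
A secreting cell releases IgG at a constant rate ``s`` molecules/s; all
secreted IgG is captured on the paramagnetic beadline (instantaneous
capture, up to a capacity).  At each frame the captured IgG, expressed
as a molar site concentration ``S(t) = s t / (N_A V)``, equilibrates
independently with the two fluorescent reagents (1:1 binding with
depletion).  The relocation in channel c is::

    R_c(t) = 1 + kappa_c * bound_c(t) / free_c(t)

so R = 1 with no secretion, and rises monotonically with captured IgG.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .binding import bound_complex
from .config import (
    AcquisitionSchedule,
    AssayChemistry,
    CohortSpec,
    EmulsionConfig,
    NoiseModel,
)
from .core import AVOGADRO, DropletSkeleton, GroundTruthCell, RelocationTrace

__all__ = [
    "sample_emulsion",
    "forward_kinetics",
    "sample_cohort",
    "make_secretor_cohort",
    "render_stack",
    "write_dataset",
    "read_stack",
    "PlacementError",
]


class PlacementError(ValueError):
    """Raised when the chamber cannot hold the requested droplets."""


def _grid_layout(n: int, radius_px: int, chamber_shape=None):
    """Non-overlapping jittered square-grid placement.

    Returns (H, W, spacing, margin, n_cols, n_rows).  Raises
    PlacementError when an explicit chamber is too small.
    """
    # margin leaves room for placement jitter (±2 px) plus the 3 px
    # movement-artifact shift without leaving the chamber
    spacing = 2 * radius_px + 6
    margin = radius_px + 8
    if chamber_shape is None:
        n_cols = max(1, math.ceil(math.sqrt(n)))
        n_rows = math.ceil(n / n_cols)
        height = 2 * margin + (n_rows - 1) * spacing + 1
        width = 2 * margin + (n_cols - 1) * spacing + 1
        return height, width, spacing, margin, n_cols, n_rows
    height, width = chamber_shape
    n_cols = (width - 2 * margin) // spacing + 1 if width >= 2 * margin else 0
    n_rows = (height - 2 * margin) // spacing + 1 if height >= 2 * margin else 0
    if n_cols * n_rows < n:
        raise PlacementError(
            f"chamber {chamber_shape} holds at most {n_cols * n_rows} droplets "
            f"of radius {radius_px} px without overlap; {n} requested"
        )
    return height, width, spacing, margin, n_cols, n_rows


def sample_emulsion(config: EmulsionConfig, rng: np.random.Generator):
    """Place droplets in the chamber and draw Poisson cell counts.

    Cell counts are independent Poisson(mean_occupancy).  Returns
    (droplets, cells): droplet skeletons with geometry and occupancy,
    and one GroundTruthCell per encapsulated cell (all non-secretors at
    this stage; see :func:`sample_cohort`).
    """
    r = config.droplet_radius_px
    height, width, spacing, margin, n_cols, _ = _grid_layout(
        config.n_droplets, r, config.chamber_shape
    )
    counts = rng.poisson(config.mean_occupancy, size=config.n_droplets)
    droplets = []
    cells = []
    for i in range(config.n_droplets):
        row, col = divmod(i, n_cols)
        jx, jy = rng.integers(-2, 3, size=2)
        cx = margin + col * spacing + int(jx)
        cy = margin + row * spacing + int(jy)
        droplets.append(
            DropletSkeleton(
                droplet_id=i, cx=cx, cy=cy, radius_px=r, n_cells=int(counts[i])
            )
        )
        for _ in range(int(counts[i])):
            cells.append(
                GroundTruthCell(droplet_id=i, n_cells_in_droplet=int(counts[i]))
            )
    return droplets, cells


def forward_kinetics(
    cell: GroundTruthCell,
    chem: AssayChemistry,
    sched: AcquisitionSchedule,
    volume_l: float,
) -> RelocationTrace:
    """Relocation trace predicted by the forward binding model.

    Captured IgG accumulates linearly, N(t) = s*t (capped at the
    beadline capacity); the red channel sees the detector bound to any
    captured IgG (K_D = chem.kd_detector), the green channel sees the
    antigen bound with the cell's own K_D.
    """
    if volume_l <= 0:
        raise ValueError("volume_l must be > 0")
    times = sched.times_min()
    t_s = times * 60.0
    n_captured = np.minimum(cell.secretion_rate * t_s, chem.capture_capacity)
    sites = n_captured / (AVOGADRO * volume_l)  # molar

    b_red = bound_complex(sites, chem.detector_total, chem.kd_detector)
    free_red = chem.detector_total - b_red
    r_red = 1.0 + chem.kappa_red * b_red / free_red

    b_green = bound_complex(sites, chem.gpi_total, cell.kd)
    free_green = chem.gpi_total - b_green
    r_green = 1.0 + chem.kappa_green * b_green / free_green

    return RelocationTrace(
        times_min=times,
        r_red=np.asarray(r_red, dtype=float),
        r_green=np.asarray(r_green, dtype=float),
        bg_red_frac=np.asarray(free_red / chem.detector_total, dtype=float),
        bg_green_frac=np.asarray(free_green / chem.gpi_total, dtype=float),
    )


def _truncated_lognormal(rng, log_mean, log_sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(log_mean, log_sd, size=size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _draw_kd(rng, spec: CohortSpec, size):
    cls = rng.choice(len(spec.kd_class_weights), size=size, p=spec.kd_class_weights)
    lo = np.array([b[0] for b in spec.kd_class_bounds_nm])[cls]
    hi = np.array([b[1] for b in spec.kd_class_bounds_nm])[cls]
    return rng.uniform(lo, hi) * 1e-9


def sample_cohort(
    config: EmulsionConfig,
    spec: CohortSpec,
    chem: AssayChemistry,
    sched: AcquisitionSchedule,
    rng: np.random.Generator,
):
    """Emulsion plus secretor assignment and forward kinetics.

    Each occupied droplet hosts at most one IgG-secreting cell (the
    probability that any of its n cells secretes is 1-(1-p)^n); the
    secretor draws a truncated log-normal rate, and is antigen-specific
    with probability ``gpi_specific_fraction`` (K_D from the class
    mixture) or secretes irrelevant IgG otherwise.

    Returns (droplets, cells, traces) where traces maps droplet_id ->
    RelocationTrace for secretor droplets.
    """
    droplets, cells = sample_emulsion(config, rng)
    by_droplet: dict[int, list[GroundTruthCell]] = {}
    for c in cells:
        by_droplet.setdefault(c.droplet_id, []).append(c)

    traces: dict[int, RelocationTrace] = {}
    p = spec.secretor_fraction
    for did, dcells in by_droplet.items():
        n = len(dcells)
        if rng.random() >= 1.0 - (1.0 - p) ** n:
            continue
        cell = dcells[0]
        cell.is_igg_secretor = True
        cell.secretion_rate = float(
            _truncated_lognormal(
                rng, spec.rate_log_mean, spec.rate_log_sd, spec.rate_min, spec.rate_max, 1
            )[0]
        )
        if rng.random() < spec.gpi_specific_fraction:
            cell.is_gpi_specific = True
            cell.kd = float(_draw_kd(rng, spec, 1)[0])
        else:
            cell.is_gpi_specific = False
            cell.kd = spec.kd_nonspecific
        traces[did] = forward_kinetics(cell, chem, sched, config.droplet_volume_l)
    return droplets, cells, traces


def make_secretor_cohort(
    rates,
    kds,
    chem: AssayChemistry,
    sched: AcquisitionSchedule,
    volume_l: float = 1.0e-11,
    pixel_size_um: float = 1.5,
):
    """Deterministic cohort with exactly one secreting cell per droplet.

    Used for parameter-recovery experiments: `rates` (molecules/s) and
    `kds` (molar) are given per droplet instead of being sampled.
    """
    rates = np.asarray(rates, dtype=float)
    kds = np.broadcast_to(np.asarray(kds, dtype=float), rates.shape)
    n = len(rates)
    config = EmulsionConfig(
        n_droplets=n, mean_occupancy=0.0, droplet_volume_l=volume_l,
        pixel_size_um=pixel_size_um,
    )
    rng = np.random.default_rng(0)  # only jitters placement
    droplets, _ = sample_emulsion(config, rng)
    cells = []
    traces = {}
    for d, s, kd in zip(droplets, rates, kds):
        d.n_cells = 1
        cell = GroundTruthCell(
            droplet_id=d.droplet_id,
            secretion_rate=float(s),
            kd=float(kd),
            is_igg_secretor=True,
            is_gpi_specific=bool(kd < 100e-9),
            n_cells_in_droplet=1,
        )
        cells.append(cell)
        traces[d.droplet_id] = forward_kinetics(cell, chem, sched, volume_l)
    return config, droplets, cells, traces


def beadline_extent(radius_px: int) -> int:
    """Half-length (px) of the beadline bar: 0.6 of the droplet diameter."""
    return max(1, round(0.6 * radius_px))


def _disk_offsets(r: int):
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    m = dy * dy + dx * dx <= r * r
    return dy[m], dx[m]


def _small_disk_offsets(r: int):
    return _disk_offsets(r)


def render_stack(
    droplets,
    traces,
    noise: NoiseModel,
    sched: AcquisitionSchedule,
    chamber_shape,
    rng: np.random.Generator,
    base_intensity=(2000.0, 2000.0),
    cell_radius_px: int = 1,
    cell_contrast: float = 0.3,
    speck_gain: float = 3.0,
):
    """Rasterize the emulsion into two 16-bit time-lapse stacks.

    Each droplet is a disk of background fluorescence proportional to
    the free fluorophore fraction; a horizontal 3-px-high beadline bar
    through the center carries background x R_c(t).  Cells appear as
    dark disks in the red channel.  A `movement_fraction` subset of
    droplets shifts by 3 px on odd frames; an `artifact_fraction`
    subset carries a bright 2x2 speck off the beadline.

    Returns (red_stack, green_stack, info) with uint16 stacks of shape
    (n_frames, H, W) and an `info` DataFrame carrying the rendered
    per-droplet truth (center, radius, cells, secretor parameters via
    caller merge, moved/artifact flags).
    """
    height, width = chamber_shape
    n_frames = sched.n_frames
    n = len(droplets)

    moved = rng.random(n) < noise.movement_fraction
    speck = rng.random(n) < noise.artifact_fraction

    # Per-droplet static geometry: cell and speck positions stay fixed.
    cell_pos: list[list[tuple[int, int]]] = []
    speck_pos: list[tuple[int, int] | None] = []
    for i, d in enumerate(droplets):
        r = d.radius_px
        pts = []
        min_sep = 2 * cell_radius_px + 3  # leaves >=1 px of background between cells
        for _ in range(d.n_cells):
            # keep cells clear of the beadline rows, the rim, and each other
            best = None
            for _try in range(200):
                dy = int(
                    rng.integers(
                        cell_radius_px + 2,
                        max(cell_radius_px + 3, r - cell_radius_px - 2),
                    )
                )
                if rng.random() < 0.5:
                    dy = -dy
                max_dx = int(math.sqrt(max((r - cell_radius_px - 2) ** 2 - dy * dy, 0)))
                dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx > 0 else 0
                if abs(dy) <= cell_radius_px + 1:
                    continue
                best = (dy, dx)
                if all(
                    math.hypot(dy - py, dx - px) >= min_sep for py, px in pts
                ):
                    break
            if best is not None:
                pts.append(best)
        cell_pos.append(pts)
        if speck[i]:
            dy = int(rng.integers(3, max(4, d.radius_px - 2)))
            if rng.random() < 0.5:
                dy = -dy
            speck_pos.append((dy, 0))
        else:
            speck_pos.append(None)

    disk_cache: dict[int, tuple] = {}
    cell_cache: dict[int, tuple] = {}

    red = np.zeros((n_frames, height, width), dtype=np.uint16)
    green = np.zeros((n_frames, height, width), dtype=np.uint16)
    overflow = False

    for t in range(n_frames):
        frame_r = np.zeros((height, width), dtype=np.float64)
        frame_g = np.zeros((height, width), dtype=np.float64)
        for i, d in enumerate(droplets):
            r = d.radius_px
            if r not in disk_cache:
                disk_cache[r] = _disk_offsets(r)
            dy, dx = disk_cache[r]
            cx, cy = d.cx, d.cy
            if moved[i] and t % 2 == 1:
                cx, cy = cx + 3, cy
            trace = traces.get(d.droplet_id)
            if trace is None:
                rr = rg = 1.0
                fr = fg = 1.0
            else:
                rr, rg = trace.r_red[t], trace.r_green[t]
                fr = 1.0 if trace.bg_red_frac is None else trace.bg_red_frac[t]
                fg = 1.0 if trace.bg_green_frac is None else trace.bg_green_frac[t]
            bg_r = base_intensity[0] * fr
            bg_g = base_intensity[1] * fg
            ys, xs = cy + dy, cx + dx
            frame_r[ys, xs] = bg_r
            frame_g[ys, xs] = bg_g
            # beadline bar: 3 rows x (2*extent+1) columns through the center
            ext = beadline_extent(r)
            frame_r[cy - 1 : cy + 2, cx - ext : cx + ext + 1] = bg_r * rr
            frame_g[cy - 1 : cy + 2, cx - ext : cx + ext + 1] = bg_g * rg
            # cells: dark disks in the red channel
            if cell_pos[i]:
                if cell_radius_px not in cell_cache:
                    cell_cache[cell_radius_px] = _small_disk_offsets(cell_radius_px)
                cdy, cdx = cell_cache[cell_radius_px]
                for pdy, pdx in cell_pos[i]:
                    frame_r[cy + pdy + cdy, cx + pdx + cdx] = bg_r * cell_contrast
            if speck_pos[i] is not None:
                pdy, pdx = speck_pos[i]
                frame_r[cy + pdy : cy + pdy + 2, cx + pdx : cx + pdx + 2] = bg_r * speck_gain
                frame_g[cy + pdy : cy + pdy + 2, cx + pdx : cx + pdx + 2] = bg_g * speck_gain
        if noise.shot_noise:
            frame_r = rng.poisson(np.maximum(frame_r, 0)).astype(np.float64)
            frame_g = rng.poisson(np.maximum(frame_g, 0)).astype(np.float64)
        if noise.read_noise_sd > 0:
            frame_r = frame_r + rng.normal(0, noise.read_noise_sd, frame_r.shape)
            frame_g = frame_g + rng.normal(0, noise.read_noise_sd, frame_g.shape)
        if frame_r.max() > 65535 or frame_g.max() > 65535:
            overflow = True
        red[t] = np.clip(np.rint(frame_r), 0, 65535).astype(np.uint16)
        green[t] = np.clip(np.rint(frame_g), 0, 65535).astype(np.uint16)

    if overflow:
        warnings.warn("pixel intensities exceeded the 16-bit range and were clipped")

    info = pd.DataFrame(
        {
            "droplet_id": [d.droplet_id for d in droplets],
            "cx": [d.cx for d in droplets],
            "cy": [d.cy for d in droplets],
            "radius_px": [d.radius_px for d in droplets],
            "n_cells": [d.n_cells for d in droplets],
            "moved": moved,
            "artifact": speck,
        }
    )
    return red, green, info


def chamber_shape_for(config: EmulsionConfig):
    """Chamber (H, W) in pixels: explicit, or the auto grid layout."""
    h, w, *_ = _grid_layout(
        config.n_droplets, config.droplet_radius_px, config.chamber_shape
    )
    return h, w


def ground_truth_table(info: pd.DataFrame, cells) -> pd.DataFrame:
    """Merge rendered geometry with secretor ground truth (one row/droplet)."""
    sec = {}
    for c in cells:
        if c.is_igg_secretor:
            sec[c.droplet_id] = c
    rows = []
    for _, row in info.iterrows():
        c = sec.get(row.droplet_id)
        rows.append(
            {
                "droplet_id": int(row.droplet_id),
                "cx": int(row.cx),
                "cy": int(row.cy),
                "radius_px": int(row.radius_px),
                "n_cells": int(row.n_cells),
                "moved": bool(row.moved),
                "artifact": bool(row.artifact),
                "is_igg_secretor": c is not None,
                "secretion_rate": c.secretion_rate if c else 0.0,
                "kd": c.kd if c else float("nan"),
                "is_gpi_specific": bool(c.is_gpi_specific) if c else False,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(out_dir, red, green, truth: pd.DataFrame, config=None):
    """Write the standard dataset layout: two multi-page TIFFs + TSV (+ JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "red.tif", red)
    tifffile.imwrite(out / "green.tif", green)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if config is not None:
        with open(out / "config.json", "w") as fh:
            fh.write(json.dumps(asdict(config), indent=2) + "\n")
    return out


def read_stack(path):
    """Read a multi-page TIFF stack as (n_frames, H, W) uint16.

    Raises ValueError naming the file when it cannot be decoded.
    """
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise ValueError(f"failed to read TIFF stack {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"TIFF stack {path!s} has unexpected shape {arr.shape}")
    return arr
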