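"""Droplet and beadline segmentation, intensity extraction, QC.

The chamber images are two-channel time-lapse stacks.  Droplets are
bright disks on a dark oil background; inside each droplet the
paramagnetic beads align into a horizontal bar (beadline) under the
magnetic field.  For every droplet and frame we extract the mean
beadline intensity and the mean background intensity (droplet pixels
excluding the beadline, detected cells and bright specks) per channel,
and form the relocation ratio beadline/background.

Droplet detection uses global thresholding plus connected components
with a circularity filter; the emulsion is monodisperse so this is
simpler and fully deterministic compared to a Hough transform.  Cells
are detected as dark disks in the red channel of the first frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .config import AcquisitionSchedule
from .core import (
    FLAG_ARTIFACT,
    FLAG_BG_INVALID,
    FLAG_EDGE,
    FLAG_MOVED,
    FLAG_MULTI_CELL,
    RelocationTrace,
)
from .synth import beadline_extent

__all__ = [
    "DropletRegion",
    "DropletObservation",
    "segment_droplets",
    "locate_beadline",
    "compute_relocation",
    "qc_droplet",
    "analyze_stack",
    "observations_to_tables",
]


@dataclass
class DropletRegion:
    """One segmented droplet in a single frame."""

    cy: float
    cx: float
    radius: float
    area: int
    circularity: float
    touches_edge: bool
    mask_slice: tuple | None = None
    mask: np.ndarray | None = None


@dataclass
class DropletObservation:
    """Per-droplet geometry, QC flags, and per-frame/channel intensities."""

    droplet_id: int
    cx: float
    cy: float
    radius: float
    n_cells_detected: int = 0
    qc_flags: set = field(default_factory=set)
    beadline_mean: dict = field(default_factory=dict)  # channel -> (T,)
    background_mean: dict = field(default_factory=dict)

    @property
    def passes_qc(self) -> bool:
        return not (
            self.qc_flags
            & {FLAG_EDGE, FLAG_MOVED, FLAG_ARTIFACT, FLAG_MULTI_CELL, FLAG_BG_INVALID}
        )


def segment_droplets(
    frame, min_area: int = 20, min_circularity: float = 0.8, warn: bool = True
):
    """Segment droplets in one grayscale frame.

    Returns a list of :class:`DropletRegion`.  Border-touching regions
    are kept but flagged ``touches_edge`` so downstream QC can exclude
    them.  A blank frame yields an empty list with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("segment_droplets expects a 2D grayscale image")
    if float(frame.max()) - float(frame.min()) < 1e-9:
        if warn:
            warnings.warn("no droplets found: blank image")
        return []
    thr = threshold_otsu(frame)
    # refine to the midpoint of the two class means: on oil-dominated
    # chamber images Otsu can settle inside the dark-noise peak, letting
    # rare noise pixels bridge adjacent droplets
    lo, hi = frame[frame <= thr], frame[frame > thr]
    if len(lo) and len(hi):
        thr = 0.5 * (float(lo.mean()) + float(hi.mean()))
    mask = frame > thr
    mask = ndi.binary_fill_holes(mask)
    lbl = label(mask)
    regions = []
    h, w = frame.shape
    for p in regionprops(lbl):
        if p.area < min_area:
            continue
        minr, minc, maxr, maxc = p.bbox
        edge = minr == 0 or minc == 0 or maxr == h or maxc == w
        circ = 4.0 * math.pi * p.area / p.perimeter**2 if p.perimeter > 0 else 0.0
        # border-cut droplets lose their circular outline; keep them so
        # they can be flagged EDGE and excluded downstream
        if circ < min_circularity and not edge:
            continue
        regions.append(
            DropletRegion(
                cy=p.centroid[0],
                cx=p.centroid[1],
                radius=math.sqrt(p.area / math.pi),
                area=int(p.area),
                circularity=circ,
                touches_edge=edge,
                mask_slice=p.slice,
                mask=p.image,
            )
        )
    if not regions and warn:
        warnings.warn("no droplets found")
    return regions


def locate_beadline(region: DropletRegion, frame=None):
    """Beadline pixel mask for a segmented droplet.

    The magnetic field axis is horizontal and the beadline runs through
    the droplet center, so the mask is the axis-centered bar: 3 px high,
    0.6 droplet diameters long, intersected with the droplet pixels.
    When the image carries no beadline contrast (pre-secretion frames)
    this geometric bar is exactly the stated fallback; when a frame is
    supplied, off-axis bright contrast is reported (it indicates an
    artifact, never a displaced beadline).

    Returns (rows, cols) index arrays in full-image coordinates, plus a
    bool ``suspicious`` when off-axis contrast beats the axis bar.
    """
    cy, cx = int(round(region.cy)), int(round(region.cx))
    r = int(round(region.radius))
    ext = beadline_extent(r)
    rows = np.arange(cy - 1, cy + 2)
    cols = np.arange(cx - ext, cx + ext + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    inside = (rr - region.cy) ** 2 + (cc - region.cx) ** 2 <= region.radius**2 * 1.05
    rr, cc = rr[inside], cc[inside]
    suspicious = False
    if frame is not None and len(rr):
        frame = np.asarray(frame, dtype=float)
        bar_mean = frame[rr, cc].mean()
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        dmask = dy * dy + dx * dx <= (r - 1) ** 2
        off = dmask & (np.abs(dy) > 2)
        ys, xs = cy + dy[off], cx + dx[off]
        keep = (ys >= 0) & (ys < frame.shape[0]) & (xs >= 0) & (xs < frame.shape[1])
        if keep.any():
            off_max = frame[ys[keep], xs[keep]].max()
            suspicious = bool(off_max > 1.5 * bar_mean)
    return rr, cc, suspicious


def compute_relocation(
    obs: DropletObservation, times_min
) -> RelocationTrace | None:
    """Relocation trace r_c[k] = beadline_mean / background_mean.

    Returns None (and flags the observation BG_INVALID) when any
    background mean is non-positive.
    """
    bg_r = np.asarray(obs.background_mean["red"], dtype=float)
    bg_g = np.asarray(obs.background_mean["green"], dtype=float)
    if np.any(bg_r <= 0) or np.any(bg_g <= 0):
        obs.qc_flags.add(FLAG_BG_INVALID)
        return None
    return RelocationTrace(
        times_min=np.asarray(times_min, dtype=float),
        r_red=np.asarray(obs.beadline_mean["red"], dtype=float) / bg_r,
        r_green=np.asarray(obs.beadline_mean["green"], dtype=float) / bg_g,
    )


def qc_droplet(
    positions: np.ndarray,
    n_cells: int,
    has_artifact: bool,
    touches_edge: bool,
    movement_tol_px: float = 2.0,
) -> set:
    """Assemble the QC flag set for one droplet.

    positions : (T, 2) per-frame centers (NaN rows where unmatched);
    MOVED when any consecutive displacement exceeds the tolerance.
    Flags are additive.
    """
    flags = set()
    if touches_edge:
        flags.add(FLAG_EDGE)
    if n_cells > 2:
        flags.add(FLAG_MULTI_CELL)
    if has_artifact:
        flags.add(FLAG_ARTIFACT)
    pos = np.asarray(positions, dtype=float)
    for k in range(1, len(pos)):
        a, b = pos[k - 1], pos[k]
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            continue
        if np.hypot(*(b - a)) > movement_tol_px:
            flags.add(FLAG_MOVED)
            break
    return flags


def _detect_cells_and_specks(red0, disk_rows, disk_cols, bead_rows, bead_cols):
    """Dark-disk cell count and bright-speck mask inside one droplet.

    Works on the first red frame (no relocation yet): cells are dark
    disks well below the background level; specks are isolated pixels
    well above it.  Returns (n_cells, cell_index, speck_index) where the
    index arrays address full-image coordinates.
    """
    vals = red0[disk_rows, disk_cols]
    med = float(np.median(vals))
    if med <= 0:
        return 0, (np.array([], int), np.array([], int)), (np.array([], int), np.array([], int))
    bead_set = set(zip(bead_rows.tolist(), bead_cols.tolist()))
    in_bead = np.fromiter(
        ((y, x) in bead_set for y, x in zip(disk_rows.tolist(), disk_cols.tolist())),
        dtype=bool,
        count=len(disk_rows),
    )
    dark = vals < 0.6 * med
    bright = (vals > 1.8 * med) & ~in_bead

    # connected components on the local grid
    y0, x0 = disk_rows.min(), disk_cols.min()
    hh = disk_rows.max() - y0 + 1
    ww = disk_cols.max() - x0 + 1
    grid = np.zeros((hh, ww), dtype=bool)
    grid[disk_rows - y0, disk_cols - x0] = dark
    lbl, n_lbl = ndi.label(grid)
    n_cells = 0
    for i in range(1, n_lbl + 1):
        if (lbl == i).sum() >= 3:
            n_cells += 1
    cell_idx = np.nonzero(grid)
    cell_idx = (cell_idx[0] + y0, cell_idx[1] + x0)

    gridb = np.zeros((hh, ww), dtype=bool)
    gridb[disk_rows - y0, disk_cols - x0] = bright
    lblb, n_lblb = ndi.label(gridb)
    speck = np.zeros_like(gridb)
    for i in range(1, n_lblb + 1):
        comp = lblb == i
        if comp.sum() >= 2:
            speck |= comp
    sp_idx = np.nonzero(speck)
    sp_idx = (sp_idx[0] + y0, sp_idx[1] + x0)
    return n_cells, cell_idx, sp_idx


def analyze_stack(
    red: np.ndarray,
    green: np.ndarray,
    sched: AcquisitionSchedule,
    movement_tol_px: float = 2.0,
):
    """Full per-stack extraction: geometry, QC, per-frame intensities.

    Geometry is taken from the first frame of the summed channels;
    subsequent frames are re-segmented only to track droplet centers
    for the movement QC.  Returns a list of DropletObservation ordered
    by (cy, cx), with droplet_id assigned in that order.
    """
    red = np.asarray(red)
    green = np.asarray(green)
    if red.shape != green.shape:
        raise ValueError("red and green stacks must have identical shapes")
    n_frames = red.shape[0]
    if n_frames != sched.n_frames:
        raise ValueError(
            f"stack has {n_frames} frames but the schedule expects {sched.n_frames}"
        )

    comb0 = red[0].astype(np.float64) + green[0].astype(np.float64)
    regions = segment_droplets(comb0)
    regions.sort(key=lambda g: (round(g.cy), round(g.cx)))

    # Per-frame droplet centers for movement tracking.  Strong secretors
    # relocate most of the fluorophore onto the beadline in late frames,
    # so the permissive settings (no circularity filter, small min area)
    # keep the beadline-only remnant, whose centroid is still the
    # droplet center.
    frame_centers = []
    for t in range(1, n_frames):
        comb = red[t].astype(np.float64) + green[t].astype(np.float64)
        regs = segment_droplets(comb, min_area=8, min_circularity=0.0, warn=False)
        frame_centers.append(
            np.array([[g.cy, g.cx] for g in regs]) if regs else np.empty((0, 2))
        )

    observations = []
    for did, g in enumerate(regions):
        cy, cx = int(round(g.cy)), int(round(g.cx))
        r = int(round(g.radius))
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        inside = dy * dy + dx * dx <= r * r
        ys, xs = cy + dy[inside], cx + dx[inside]
        keep = (ys >= 0) & (ys < red.shape[1]) & (xs >= 0) & (xs < red.shape[2])
        ys, xs = ys[keep], xs[keep]

        bead_rows, bead_cols, _ = locate_beadline(g)
        n_cells, cell_idx, speck_idx = _detect_cells_and_specks(
            red[0].astype(np.float64), ys, xs, bead_rows, bead_cols
        )

        # background = droplet minus beadline minus cells minus specks
        excl = set(zip(bead_rows.tolist(), bead_cols.tolist()))
        excl |= set(zip(cell_idx[0].tolist(), cell_idx[1].tolist()))
        excl |= set(zip(speck_idx[0].tolist(), speck_idx[1].tolist()))
        bg_keep = np.fromiter(
            ((y, x) not in excl for y, x in zip(ys.tolist(), xs.tolist())),
            dtype=bool,
            count=len(ys),
        )
        bg_rows, bg_cols = ys[bg_keep], xs[bg_keep]

        bead_mean = {"red": np.zeros(n_frames), "green": np.zeros(n_frames)}
        bg_mean = {"red": np.zeros(n_frames), "green": np.zeros(n_frames)}
        for t in range(n_frames):
            for ch, stack in (("red", red), ("green", green)):
                fr = stack[t]
                bead_mean[ch][t] = (
                    fr[bead_rows, bead_cols].mean() if len(bead_rows) else 0.0
                )
                bg_mean[ch][t] = fr[bg_rows, bg_cols].mean() if len(bg_rows) else 0.0

        # movement: nearest segmented center in each later frame
        positions = np.full((n_frames, 2), np.nan)
        positions[0] = (g.cy, g.cx)
        for t in range(1, n_frames):
            centers = frame_centers[t - 1]
            if len(centers) == 0:
                continue
            tree = cKDTree(centers)
            dist, idx = tree.query([g.cy, g.cx])
            if dist <= g.radius:
                positions[t] = centers[idx]

        has_artifact = len(speck_idx[0]) > 0
        flags = qc_droplet(
            positions, n_cells, has_artifact, g.touches_edge, movement_tol_px
        )
        obs = DropletObservation(
            droplet_id=did,
            cx=g.cx,
            cy=g.cy,
            radius=g.radius,
            n_cells_detected=n_cells,
            qc_flags=flags,
            beadline_mean=bead_mean,
            background_mean=bg_mean,
        )
        observations.append(obs)
    return observations


def observations_to_tables(observations, sched: AcquisitionSchedule):
    """Flatten observations into intensity and relocation DataFrames."""
    times = sched.times_min()
    int_rows = []
    reloc_rows = []
    for obs in observations:
        trace = compute_relocation(obs, times)
        for t in range(sched.n_frames):
            for ch in ("red", "green"):
                int_rows.append(
                    {
                        "droplet_id": obs.droplet_id,
                        "frame": t,
                        "time_min": times[t],
                        "channel": ch,
                        "beadline_mean": obs.beadline_mean[ch][t],
                        "background_mean": obs.background_mean[ch][t],
                        "relocation": (
                            obs.beadline_mean[ch][t] / obs.background_mean[ch][t]
                            if obs.background_mean[ch][t] > 0
                            else np.nan
                        ),
                    }
                )
        if trace is not None:
            for t in range(sched.n_frames):
                reloc_rows.append(
                    {
                        "droplet_id": obs.droplet_id,
                        "frame": t,
                        "time_min": times[t],
                        "r_red": trace.r_red[t],
                        "r_green": trace.r_green[t],
                    }
                )
    return pd.DataFrame(int_rows), pd.DataFrame(reloc_rows)
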