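"""Shared containers and physical constants.

The assay measures, per droplet, the dimensionless "relocation" ratio:
mean fluorescence on the magnetic beadline divided by mean fluorescence
of the rest of the droplet, in two channels (red = anti-IgG detector,
green = fluorescent antigen).  These containers are shared between the
synthetic generator and the image-analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23  # molecules / mol

#: QC flag vocabulary used throughout the pipeline.
FLAG_EDGE = "EDGE"
FLAG_MOVED = "MOVED"
FLAG_ARTIFACT = "ARTIFACT"
FLAG_MULTI_CELL = "MULTI_CELL"
FLAG_BG_INVALID = "BG_INVALID"


@dataclass
class RelocationTrace:
    """Per-droplet relocation time series in both channels.

    Attributes
    ----------
    times_min : array of acquisition times in minutes (first frame at 0).
    r_red, r_green : relocation (beadline / background) per frame,
        dimensionless, 1.0 meaning no relocation.
    bg_red_frac, bg_green_frac : fraction of fluorophore remaining free
        in solution per frame (generator bookkeeping used only for
        rendering the background intensity; 1.0 when unknown).
    """

    times_min: np.ndarray
    r_red: np.ndarray
    r_green: np.ndarray
    bg_red_frac: np.ndarray | None = None
    bg_green_frac: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.r_red = np.asarray(self.r_red, dtype=float)
        self.r_green = np.asarray(self.r_green, dtype=float)
        if not (len(self.times_min) == len(self.r_red) == len(self.r_green)):
            raise ValueError("trace arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.times_min)


@dataclass
class GroundTruthCell:
    """Ground truth for one encapsulated cell in the synthetic emulsion."""

    droplet_id: int
    secretion_rate: float = 0.0  # molecules / s
    kd: float = 1.0e-5  # molar; nonsecretors carry a placeholder
    is_igg_secretor: bool = False
    is_gpi_specific: bool = False
    n_cells_in_droplet: int = 1

    def __post_init__(self) -> None:
        if self.secretion_rate < 0:
            raise ValueError("secretion_rate must be >= 0")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.is_igg_secretor and self.n_cells_in_droplet < 1:
            raise ValueError("a secretor must sit in a droplet with >= 1 cell")


@dataclass
class DropletSkeleton:
    """Geometry and occupancy of one droplet before rendering."""

    droplet_id: int
    cx: int
    cy: int
    radius_px: int
    n_cells: int
    flags: set = field(default_factory=set)
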