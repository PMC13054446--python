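"""Configuration dataclasses for every pipeline stage.

All configs are plain, fully serializable dataclasses validated at
construction; a run is reproducible from its config plus one integer
seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Time-lapse schedule: n_frames images every frame_interval minutes.

    Defaults follow the assay protocol: six frames every 7.5 minutes,
    spanning 37.5 minutes.
    """

    frame_interval_min: float = 7.5
    n_frames: int = 6

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def total_time_min(self) -> float:
        return self.frame_interval_min * (self.n_frames - 1)

    def times_min(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass(frozen=True)
class AssayChemistry:
    """In-droplet reagent concentrations and optical gains.

    gpi_total : fluorescent antigen concentration, molar (30 nM).
    detector_total : fluorescent anti-IgG detector, molar (75 nM).
    kd_detector : detector/IgG dissociation constant, molar.  Near-
        saturating (1 nM) so the red channel tracks total captured IgG.
    capture_capacity : beadline capture capacity, molecules; effectively
        unlimited by default.
    kappa_red, kappa_green : channel gains converting the bound:free
        fluorophore ratio into relocation excess (R - 1).
    """

    gpi_total: float = 30e-9
    detector_total: float = 75e-9
    kd_detector: float = 1e-9
    capture_capacity: float = 1e7
    kappa_red: float = 15.0
    kappa_green: float = 15.0

    def __post_init__(self) -> None:
        for name in ("gpi_total", "detector_total", "kd_detector"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa_red <= 0 or self.kappa_green <= 0:
            raise ValueError("channel gains must be > 0")
        if self.capture_capacity <= 0:
            raise ValueError("capture_capacity must be > 0")


@dataclass(frozen=True)
class EmulsionConfig:
    """Droplet emulsion geometry and occupancy.

    The 10 pL droplet volume is fixed by the cell suspension density of
    30e6 cells/mL and the mean occupancy of 0.3 cells/droplet
    (0.3 / 3e7 mL^-1 = 1e-11 L).
    """

    n_droplets: int = 2000
    mean_occupancy: float = 0.3
    droplet_volume_l: float = 1.0e-11
    pixel_size_um: float = 1.5
    chamber_shape: Optional[Tuple[int, int]] = None  # (H, W) px; auto if None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.mean_occupancy < 0:
            raise ValueError("mean_occupancy must be >= 0")
        if self.droplet_volume_l <= 0:
            raise ValueError("droplet_volume_l must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def droplet_radius_um(self) -> float:
        # sphere of volume V: r = (3V / 4 pi)^(1/3); 1 L = 1e15 um^3
        v_um3 = self.droplet_volume_l * 1e15
        return (3.0 * v_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def droplet_radius_px(self) -> int:
        return max(3, round(self.droplet_radius_um / self.pixel_size_um))


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise and QC-failure artifact classes.

    movement_fraction of droplets jitter their center by >2 px between
    frames (a QC exclusion class); artifact_fraction carry a spurious
    bright speck.
    """

    read_noise_sd: float = 2.0
    shot_noise: bool = False
    movement_fraction: float = 0.0
    artifact_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        for name in ("movement_fraction", "artifact_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def noiseless(self) -> bool:
        return (
            self.read_noise_sd == 0
            and not self.shot_noise
            and self.movement_fraction == 0
            and self.artifact_fraction == 0
        )


@dataclass(frozen=True)
class SecretorCallConfig:
    """Positivity filters applied to the red-channel relocation trace.

    A droplet is called IgG-secreting when the trace exceeds 1.2 at its
    maximum, rises by more than 0.025 between first and last frame, and
    has a least-squares slope of at least 0.004 relocation units per
    frame interval.
    """

    min_relocation_threshold: float = 1.2
    net_difference_threshold: float = 0.025
    slope_threshold: float = 0.004

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic splenocyte-like cohort.

    secretor_fraction : probability that an encapsulated cell is an
        IgG-secreting cell (plasmablast/plasma cell).  The default
        emulates an ASC-rich acquisition so a few-thousand-droplet run
        yields a statistically useful number of positives.
    gpi_specific_fraction : fraction of IgG-secretors whose IgG binds
        the antigen within the assay window; the rest secrete IgG of
        irrelevant specificity (kd_nonspecific, far above 100 nM).
    rate_log_mean, rate_log_sd : natural-log parameters of the
        log-normal secretion-rate distribution (mean ~33 molecules/s),
        truncated to [rate_min, rate_max].
    kd_class_weights / kd_class_bounds_nm : mixture over low / medium /
        high affinity classes, uniform within each range (nM).
    """

    secretor_fraction: float = 0.25
    gpi_specific_fraction: float = 0.40
    rate_log_mean: float = 3.317
    rate_log_sd: float = 0.6
    rate_min: float = 4.0
    rate_max: float = 800.0
    kd_class_weights: Tuple[float, float, float] = (0.90, 0.08, 0.02)
    kd_class_bounds_nm: Tuple[Tuple[float, float], ...] = (
        (10.0, 100.0),
        (1.0, 10.0),
        (0.2, 1.0),
    )
    kd_nonspecific: float = 1.0e-5

    def __post_init__(self) -> None:
        if not 0 <= self.secretor_fraction <= 1:
            raise ValueError("secretor_fraction must be in [0, 1]")
        if not 0 <= self.gpi_specific_fraction <= 1:
            raise ValueError("gpi_specific_fraction must be in [0, 1]")
        if abs(sum(self.kd_class_weights) - 1.0) > 1e-9:
            raise ValueError("kd_class_weights must sum to 1")
        if self.rate_min <= 0 or self.rate_max <= self.rate_min:
            raise ValueError("need 0 < rate_min < rate_max")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; serializable to/from JSON."""

    seed: int = 0
    emulsion: EmulsionConfig = field(default_factory=EmulsionConfig)
    chemistry: AssayChemistry = field(default_factory=AssayChemistry)
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    calling: SecretorCallConfig = field(default_factory=SecretorCallConfig)
    organ: str = "spleen"
    age_weeks: float = 8.0
    mouse_id: str = "synthetic-01"

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def tup(x):
            return tuple(tuple(e) if isinstance(e, list) else e for e in x)

        kwargs = dict(data)
        if "emulsion" in kwargs:
            emu = dict(kwargs["emulsion"])
            if emu.get("chamber_shape") is not None:
                emu["chamber_shape"] = tuple(emu["chamber_shape"])
            kwargs["emulsion"] = EmulsionConfig(**emu)
        if "chemistry" in kwargs:
            kwargs["chemistry"] = AssayChemistry(**kwargs["chemistry"])
        if "schedule" in kwargs:
            kwargs["schedule"] = AcquisitionSchedule(**kwargs["schedule"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseModel(**kwargs["noise"])
        if "cohort" in kwargs:
            coh = dict(kwargs["cohort"])
            if "kd_class_weights" in coh:
                coh["kd_class_weights"] = tuple(coh["kd_class_weights"])
            if "kd_class_bounds_nm" in coh:
                coh["kd_class_bounds_nm"] = tup(coh["kd_class_bounds_nm"])
            kwargs["cohort"] = CohortSpec(**coh)
        if "calling" in kwargs:
            kwargs["calling"] = SecretorCallConfig(**kwargs["calling"])
        return cls(**kwargs)
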