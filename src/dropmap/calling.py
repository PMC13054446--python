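"""IgG-secretor positivity calling on relocation traces.

A droplet is called positive for IgG secretion from its red-channel
(anti-IgG) trace when all three filters hold:

* maximum relocation over the trace > 1.2 — the achieved relocation
  must clear a floor (traces start at 1.0 by construction, so the floor
  applies to the maximum, not the literal minimum);
* net difference r[last] - r[first] > 0.025;
* least-squares slope of r versus frame index >= 0.004 relocation
  units per frame interval.

The green (antigen) channel is deliberately not used for calling; it is
reserved for the specificity/affinity measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SecretorCallConfig
from .core import RelocationTrace

__all__ = ["CallResult", "call_igg_secretor", "call_table"]


@dataclass(frozen=True)
class CallResult:
    is_positive: bool
    max_relocation: float
    net_difference: float
    slope: float
    failed_criteria: tuple

    def as_dict(self) -> dict:
        return {
            "is_positive": self.is_positive,
            "max_relocation": self.max_relocation,
            "net_difference": self.net_difference,
            "slope": self.slope,
            "failed_criteria": ";".join(self.failed_criteria),
        }


def call_igg_secretor(
    trace: RelocationTrace, cfg: SecretorCallConfig | None = None
) -> CallResult:
    """Apply the three positivity filters to one trace."""
    if cfg is None:
        cfg = SecretorCallConfig()
    r = np.asarray(trace.r_red, dtype=float)
    if len(r) < 2:
        raise ValueError("a trace needs at least 2 frames to be called")
    max_reloc = float(r.max())
    net = float(r[-1] - r[0])
    slope = float(np.polyfit(np.arange(len(r)), r, 1)[0])
    failed = []
    if not max_reloc > cfg.min_relocation_threshold:
        failed.append("min_relocation")
    if not net > cfg.net_difference_threshold:
        failed.append("net_difference")
    if not slope >= cfg.slope_threshold:
        failed.append("slope")
    return CallResult(
        is_positive=not failed,
        max_relocation=max_reloc,
        net_difference=net,
        slope=slope,
        failed_criteria=tuple(failed),
    )


def call_table(traces: dict, cfg: SecretorCallConfig | None = None) -> pd.DataFrame:
    """Call a mapping droplet_id -> trace and return the call table."""
    rows = []
    for did, trace in traces.items():
        res = call_igg_secretor(trace, cfg)
        rows.append({"droplet_id": did, **res.as_dict()})
    return pd.DataFrame(rows)
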