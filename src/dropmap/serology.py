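"""Serum-level computations: SPR steady-state affinity, anti-antigen
percentage, and censored ELISA ED50.

SPR: equilibrium responses at a handful of analyte concentrations are
fitted with the 1:1 steady-state model R_eq(C) = Rmax C / (K_D + C).
The percentage of antigen-specific IgG follows the instrument formula
verbatim:  % = Rmax / capture_level * (M_antigen / M_IgG) * 100.

ELISA: optical density versus serum dilution is fitted with a
four-parameter logistic; the ED50 (dilution at half-maximal OD) is
censored to <300 / >218,700 when it falls outside the measured
three-fold dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = [
    "SPR_CONCENTRATIONS_NM",
    "ELISA_DILUTIONS",
    "SteadyStateFit",
    "Ed50Fit",
    "steady_state_response",
    "fit_steady_state",
    "percent_anti_gpi",
    "four_param_logistic",
    "fit_ed50",
    "M_GPI_DEFAULT",
    "M_IGG_DEFAULT",
]

#: analyte concentration series used for the serum affinity measurements (nM)
SPR_CONCENTRATIONS_NM = (2000.0, 667.0, 222.0, 74.0, 25.0)

#: three-fold serum dilution series 300 * 3^k, k = 0..6
ELISA_DILUTIONS = tuple(300 * 3**k for k in range(7))

ED50_IN_RANGE = "IN_RANGE"
ED50_LT_LOW = "LT_300"
ED50_GT_HIGH = "GT_218700"

M_GPI_DEFAULT = 63_000.0  # g/mol, antigen monomer
M_IGG_DEFAULT = 150_000.0  # g/mol


def steady_state_response(conc, kd, rmax):
    """1:1 steady-state binding: R_eq = Rmax * C / (K_D + C)."""
    c = np.asarray(conc, dtype=float)
    return rmax * c / (kd + c)


@dataclass(frozen=True)
class SteadyStateFit:
    kd: float  # molar units of the input concentrations
    rmax: float  # response units
    kd_se: float
    rmax_se: float
    extrapolated: bool  # True when max concentration < fitted K_D


def fit_steady_state(concentrations, responses) -> SteadyStateFit:
    """Least-squares 1:1 steady-state affinity fit.

    Concentrations may be in any consistent unit; the fitted K_D comes
    back in the same unit.  The fit is flagged ``extrapolated`` when the
    largest injected concentration is below the fitted K_D — the
    saturation plateau was never approached and Rmax/K_D are only
    jointly constrained.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) != len(r):
        raise ValueError("concentrations and responses must have equal length")
    if len(c) < 3:
        raise ValueError("need >= 3 concentrations for a steady-state fit")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if len(np.unique(c)) != len(c):
        raise ValueError("concentrations must be distinct")
    if np.all(r <= 0):
        raise ValueError("no positive responses: nothing to fit")

    p0 = (float(np.median(c)), float(r.max()) * 1.2)
    popt, pcov = curve_fit(
        lambda cc, kd, rmax: steady_state_response(cc, kd, rmax),
        c,
        r,
        p0=p0,
        bounds=([1e-30, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    kd, rmax = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return SteadyStateFit(
        kd=kd,
        rmax=rmax,
        kd_se=float(se[0]),
        rmax_se=float(se[1]),
        extrapolated=bool(c.max() < kd),
    )


def percent_anti_gpi(
    rmax: float,
    capture_level: float,
    m_gpi: float = M_GPI_DEFAULT,
    m_igg: float = M_IGG_DEFAULT,
) -> float:
    """Antigen-specific percentage of captured IgG from SPR quantities.

    % = Rmax / capture_level * (M_antigen / M_IgG) * 100.  Linear in
    Rmax, inversely linear in the capture level.  A warning-worthy
    value above 100 is returned as computed.
    """
    if capture_level <= 0:
        raise ValueError("capture_level must be > 0")
    if m_gpi <= 0 or m_igg <= 0:
        raise ValueError("molar masses must be > 0")
    if rmax < 0:
        raise ValueError("rmax must be >= 0")
    return rmax / capture_level * (m_gpi / m_igg) * 100.0


def four_param_logistic(x, top, bottom, ed50, hill):
    """Descending 4PL in the dilution variable: OD(x) =
    bottom + (top - bottom) / (1 + (x / ed50)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ed50) ** hill)


@dataclass(frozen=True)
class Ed50Fit:
    ed50: float  # reciprocal dilution; NaN when censored without a fit
    flag: str
    params: tuple = field(default=())  # (top, bottom, ed50, hill) when fitted


def fit_ed50(
    dilutions: Sequence[float],
    od: Sequence[float],
    dilution_range: tuple = (300.0, 218_700.0),
    baseline_od: float = 0.2,
) -> Ed50Fit:
    """Censored ED50 from a serum dilution series.

    Fits a descending four-parameter logistic of OD against reciprocal
    dilution and reports the dilution at half-maximal OD, censored to
    the measured range.  A flat series cannot be fitted: it is censored
    LT_300 when the ODs sit at baseline (no detectable titer) and
    GT_218700 when they sit on a saturated plateau.
    """
    x = np.asarray(dilutions, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(x) != len(y):
        raise ValueError("dilutions and od must have equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 dilution points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("dilutions must be strictly increasing")
    lo, hi = dilution_range

    span = float(y.max() - y.min())
    if span < 0.05 * max(float(y.max()), 1e-12) or span < 1e-12:
        # flat series: side on the OD level
        if float(np.mean(y)) <= baseline_od:
            return Ed50Fit(ed50=float("nan"), flag=ED50_LT_LOW)
        return Ed50Fit(ed50=float("nan"), flag=ED50_GT_HIGH)

    rho = spearmanr(x, y).statistic
    if rho > 0:
        raise ValueError(
            "OD increases with dilution: series orientation check failed"
        )

    p0 = (float(y.max()), float(y.min()), float(np.sqrt(x[0] * x[-1])), 1.0)
    popt, _ = curve_fit(
        four_param_logistic,
        x,
        y,
        p0=p0,
        bounds=([0, 0, 1e-6, 0.1], [np.inf, np.inf, np.inf, 20.0]),
        maxfev=20000,
    )
    ed50 = float(popt[2])
    if ed50 < lo:
        return Ed50Fit(ed50=ed50, flag=ED50_LT_LOW, params=tuple(popt))
    if ed50 > hi:
        return Ed50Fit(ed50=ed50, flag=ED50_GT_HIGH, params=tuple(popt))
    return Ed50Fit(ed50=ed50, flag=ED50_IN_RANGE, params=tuple(popt))
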