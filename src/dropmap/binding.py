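"""Equilibrium 1:1 binding chemistry.

Both fluorescent reagents in the droplet assay (the antigen and the
anti-IgG detector) bind captured IgG on the beadline in a simple 1:1
reversible reaction.  With total binding sites ``S`` (captured IgG, in
molar), total ligand ``L`` and dissociation constant ``K_D``, the bound
complex ``B`` satisfies the conservation quadratic::

    B^2 - (S + L + K_D) B + S L = 0

whose physically meaningful root is the smaller one.  We evaluate it in
the numerically stable product form ``B = 2 S L / (b + sqrt(b^2 - 4SL))``
with ``b = S + L + K_D``, which avoids catastrophic cancellation when
``S`` is tiny (early frames, slow secretors).
"""

from __future__ import annotations

import numpy as np


def bound_complex(sites, ligand, kd):
    """Equilibrium bound concentration for 1:1 binding with depletion.

    Parameters
    ----------
    sites, ligand : total site and ligand concentrations (molar).
    kd : dissociation constant (molar), > 0.

    Returns
    -------
    Bound complex concentration (molar), same shape as the broadcast
    inputs.  Always in ``[0, min(sites, ligand))``.
    """
    s = np.asarray(sites, dtype=float)
    l = np.asarray(ligand, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(k <= 0):
        raise ValueError("kd must be > 0")
    b = s + l + k
    disc = b * b - 4.0 * s * l
    root = np.sqrt(np.maximum(disc, 0.0))
    denom = b + root
    out = np.where(denom > 0, 2.0 * s * l / np.where(denom > 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def free_ligand(sites, ligand, kd):
    """Free ligand remaining in solution at equilibrium (molar)."""
    return np.asarray(ligand, dtype=float) - bound_complex(sites, ligand, kd)


def occupancy(free_lig, kd):
    """Langmuir fractional site occupancy theta = L_free / (L_free + K_D)."""
    f = np.asarray(free_lig, dtype=float)
    return f / (f + kd)


def kd_from_occupancy(theta, free_lig):
    """Invert the isotherm: K_D = L_free (1 - theta) / theta."""
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0) or np.any(th >= 1):
        raise ValueError("occupancy must be strictly inside (0, 1)")
    out = np.asarray(free_lig, dtype=float) * (1.0 - th) / th
    if out.ndim == 0:
        return float(out)
    return out
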