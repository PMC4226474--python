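"""FRET-based readout of the tether-to-surface distance.

In the experiment the ligand carries the donor dye and the surface-bound
streptavidin the acceptor.  The donor-acceptor distance is modelled as the
Flory radius of the tether plus the ligand radius, and transfer efficiency
follows the standard Förster form

    E(r) = 1 / (1 + (r / R_0)^6),

with Förster distance ``R_0 = 5`` nm for the DyLight 549/649 pair.  Measured
efficiencies come from acceptor photobleaching: the donor brightens once the
acceptor is destroyed, and ``E = 1 - I_before / I_after``.  Series are
compared after normalising to a reference linker (the shortest one present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .polymer import PolymerSpec, flory_radius

__all__ = [
    "FretModelParams",
    "FretRecord",
    "predicted_distance",
    "theoretical_fret",
    "fret_from_photobleach",
    "normalize_series",
]


@dataclass(frozen=True)
class FretModelParams:
    """Geometry of the donor-acceptor pair.

    forster_distance: R_0 in nm (50% transfer distance).
    ligand_radius: radius of the tethered ligand in nm, added to the coil
        radius to give the dye-to-surface distance.
    """

    forster_distance: float = 5.0
    ligand_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.forster_distance <= 0:
            raise ValueError("forster_distance must be positive")
        if self.ligand_radius < 0:
            raise ValueError("ligand_radius must be non-negative")


@dataclass(frozen=True)
class FretRecord:
    """One acceptor-photobleaching measurement."""

    linker_name: str
    donor_before: float
    donor_after: float
    efficiency: float
    clamped: bool = False


def predicted_distance(spec: PolymerSpec, params: FretModelParams | None = None) -> float:
    """Expected donor-acceptor distance: Flory radius plus ligand radius (nm)."""
    params = params or FretModelParams()
    return flory_radius(spec) + params.ligand_radius


def theoretical_fret(r: float, params: FretModelParams | None = None) -> float:
    """Förster transfer efficiency at donor-acceptor distance ``r`` (nm).

    Strictly decreasing in ``r``; equals 1 at contact and 1/2 at ``R_0``.
    """
    if r < 0:
        raise ValueError(f"distance must be non-negative, got {r}")
    params = params or FretModelParams()
    return 1.0 / (1.0 + (r / params.forster_distance) ** 6)


def fret_from_photobleach(donor_before: float, donor_after: float) -> tuple[float, bool]:
    """Acceptor-photobleaching efficiency estimate ``1 - I_before / I_after``.

    Returns ``(efficiency, clamped)``.  Photobleaching noise can leave the
    donor dimmer after bleaching than before; such negative estimates are
    clamped to 0 and flagged (with a warning) rather than propagated.
    """
    if donor_after <= 0:
        raise ValueError(
            f"post-bleach donor intensity must be positive, got {donor_after}"
        )
    if donor_before < 0:
        raise ValueError(
            f"pre-bleach donor intensity must be non-negative, got {donor_before}"
        )
    eff = 1.0 - donor_before / donor_after
    if eff < 0:
        warnings.warn(
            "donor brighter before photobleaching than after; clamping "
            "estimated FRET efficiency to 0",
            stacklevel=2,
        )
        return 0.0, True
    return eff, False


def normalize_series(
    values: Sequence[float], reference_index: int = 0
) -> np.ndarray:
    """Divide a series by its reference element, which maps to exactly 1.

    Missing values (NaN) pass through as NaN.  The conventional reference is
    the shortest linker of the series.
    """
    arr = np.asarray(values, dtype=float)
    if not -len(arr) <= reference_index < len(arr):
        raise IndexError(f"reference index {reference_index} out of range")
    ref = arr[reference_index]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"reference value must be positive and finite, got {ref}")
    return arr / ref
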