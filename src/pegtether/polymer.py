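"""Closed-form descriptors of poly(ethylene glycol) (PEG) tethers.

A PEG linker of molecular weight ``mw`` is treated as a freely jointed chain
of ethylene-oxide (PEO) repeat units of mass 44 Da and length 0.28 nm (the
monomer projection in water).  From these two constants everything else
follows:

* contour length  ``L_c = n a``           (fully extended chain),
* Flory radius    ``R_F = a n^{3/5}``     (equilibrium coil size of a
  self-avoiding chain in good solvent),
* Gaussian entropic spring force ``f = 3 kT x / (n a^2)`` for a chain held
  at end-to-end extension ``x``,
* Rouse longest-relaxation-time estimate used to size simulations.

All lengths are in nm, energies in pN·nm (kT = 4.11 pN·nm at 300 K), forces
in pN.  Derived chain sizes use the *unrounded* unit count ``mw / 44``; the
integer unit count is a display quantity only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KT_300K",
    "PolymerSpec",
    "ChainGeometry",
    "peo_unit_count",
    "contour_length",
    "flory_radius",
    "entropic_extension_force",
    "rouse_time_estimate",
]

#: Thermal energy at 300 K in pN·nm.
KT_300K: float = 4.11

#: Mass of one ethylene-oxide repeat unit, Da.
PEO_MONOMER_MASS: float = 44.0

#: Projected length of one PEO unit in water, nm.
PEO_UNIT_LENGTH: float = 0.28

#: Flory exponent for a self-avoiding chain in good solvent.
FLORY_EXPONENT: float = 3.0 / 5.0


@dataclass(frozen=True)
class PolymerSpec:
    """A PEG linker identified by its molecular weight.

    Parameters
    ----------
    mw:
        Molecular weight in Da; must be positive.
    unit_length:
        PEO unit length ``a`` in nm.
    monomer_mass:
        Mass of one repeat unit in Da.
    """

    mw: float
    unit_length: float = PEO_UNIT_LENGTH
    monomer_mass: float = PEO_MONOMER_MASS

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")
        if self.unit_length <= 0:
            raise ValueError(f"unit length must be positive, got {self.unit_length}")
        if self.monomer_mass <= 0:
            raise ValueError(f"monomer mass must be positive, got {self.monomer_mass}")

    @property
    def n_units_exact(self) -> float:
        """Real-valued repeat-unit count ``mw / monomer_mass``."""
        return self.mw / self.monomer_mass

    @property
    def n_units(self) -> int:
        """Integer repeat-unit count (nearest integer, ties round half up)."""
        return int(math.floor(self.n_units_exact + 0.5))

    def geometry(self) -> "ChainGeometry":
        return ChainGeometry(
            contour_length=contour_length(self),
            flory_radius=flory_radius(self),
        )


@dataclass(frozen=True)
class ChainGeometry:
    """Derived chain dimensions in nm."""

    contour_length: float
    flory_radius: float


def peo_unit_count(mw: float, monomer_mass: float = PEO_MONOMER_MASS) -> int:
    """Number of PEO repeat units in a PEG of molecular weight ``mw`` (Da).

    Returns the nearest integer of ``mw / monomer_mass``; ties round half up.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return int(math.floor(mw / monomer_mass + 0.5))


def contour_length(spec: PolymerSpec) -> float:
    """Fully extended chain length ``L_c = n a`` in nm (unrounded ``n``)."""
    return spec.n_units_exact * spec.unit_length


def flory_radius(spec: PolymerSpec) -> float:
    """Equilibrium coil radius ``R_F = a n^{3/5}`` in nm (unrounded ``n``).

    The 3/5 exponent is the Flory estimate for a self-avoiding chain in good
    solvent; for a single unit ``R_F = a``.
    """
    return spec.unit_length * spec.n_units_exact**FLORY_EXPONENT


def entropic_extension_force(
    spec: PolymerSpec, extension: float, kT: float = KT_300K
) -> float:
    """Gaussian-chain restoring force at a given end-to-end extension.

    ``f = 3 kT x / (n a^2)`` in pN for ``extension`` x in nm and ``kT`` in
    pN·nm.  The force is inversely proportional to the chain length, which is
    why longer tethers pull less hard on a surface-held end.  Valid only well
    below full extension; requesting ``extension >= contour_length`` raises,
    as the Gaussian approximation has no meaning there.

    This closed form is an order-of-magnitude cross-check for the slope of
    the simulated tether potential of mean force.
    """
    if extension < 0:
        raise ValueError(f"extension must be non-negative, got {extension}")
    if extension >= contour_length(spec):
        raise ValueError(
            f"extension {extension} nm is at or beyond the contour length "
            f"{contour_length(spec):.3g} nm; Gaussian chain force is undefined"
        )
    return 3.0 * kT * extension / (spec.n_units_exact * spec.unit_length**2)


def rouse_time_estimate(
    n_beads: int, segment_length: float, bead_diffusion: float
) -> float:
    """Longest Rouse relaxation time of a free bead-spring chain.

    ``tau_1 ~ b^2 N^2 / (3 pi^2 D)`` with ``b`` the segment length, ``N``
    the bead count and ``D`` the single-bead diffusion coefficient.  Used to
    size equilibration and sampling intervals; it is an estimate, not a
    measured autocorrelation time.
    """
    if n_beads < 2:
        raise ValueError(f"a chain needs at least 2 beads, got {n_beads}")
    if segment_length <= 0 or bead_diffusion <= 0:
        raise ValueError("segment_length and bead_diffusion must be positive")
    return segment_length**2 * n_beads**2 / (3.0 * math.pi**2 * bead_diffusion)
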