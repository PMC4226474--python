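"""Brownian dynamics of a bead-spring tether above a sticky plane.

The model is a desk-scale analogue of the coarse-grained system used to
study how tether length controls binding kinetics: a flexible bead-spring
chain has one end fixed at height ``h`` above a planar surface, and the
*terminal* bead feels a weak, short-range attractive well at the plane that
stands in for the receptor-ligand bond (the plane replaces an explicit lipid
bilayer, and protein geometry is ignored).  Binding is a purely geometric
event: the terminal bead dwelling within a cutoff distance of the plane.

Interactions (energies in units of kT, lengths in nm):

* harmonic bonds of rest length ``b`` (the segment length) and stiffness
  ``k_bond``;
* a bounded soft-core repulsion ``U = eps (1 - r/sigma)^2`` for ``r < sigma``
  between all non-bonded bead pairs; at the default 25 kT overlap penalty
  chains are effectively self-avoiding while the pair force stays finite,
  so the explicit Euler-Maruyama step cannot blow up at close contact;
* a soft half-harmonic wall at ``z = 0`` acting on every bead;
* for the terminal bead only, a Gaussian attractive well of depth
  ``binding_depth`` (kT) and width set by ``binding_range``.

Dynamics are overdamped (position) Langevin:
``dx = (D/kT) F dt + sqrt(2 D dt) N(0,1)`` with ``kT = 1`` internally, so the
bead diffusion coefficient ``D`` sets the clock.  Time is reported in reduced
units ``tau = nm^2 / D``; no attempt is made to calibrate it to seconds.
Replicas run independently from per-replica seeds spawned off one master
seed, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from numba import njit

from .kinetics import EventTrace
from .polymer import PolymerSpec, rouse_time_estimate

__all__ = [
    "SimulationConfig",
    "ChainSystem",
    "HeightSeries",
    "BrownianResult",
    "build_chain",
    "run_brownian",
    "detect_events",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, potentials and integrator settings for one tethered chain.

    Lengths in nm, energies in kT, time in reduced units (``nm^2 / D``).
    ``temperature_kT`` (pN·nm) is used only to convert free-energy slopes to
    forces in pN at analysis time.
    """

    n_beads: int = 30
    segment_length: float = 0.84  # 3 PEO units x 0.28 nm
    tether_height: float = 9.0
    bond_stiffness: float = 100.0  # kT / nm^2
    excluded_volume_sigma: float = 0.84
    excluded_volume_strength: float = 25.0  # kT at full overlap
    wall_stiffness: float = 200.0  # kT / nm^2, half-harmonic below z=0
    binding_depth: float = 0.0  # kT; 0 disables the well
    binding_range: float = 1.0  # nm; Gaussian well sigma = range / 2
    temperature_kT: float = 4.11  # pN·nm at 300 K
    bead_diffusion: float = 1.0  # nm^2 per reduced time unit
    timestep: float = 0.003
    n_steps: int = 200_000
    n_replicas: int = 20
    seed: int = 0
    sample_every: int = 10
    equilibration_steps: int | None = None  # default: 10 x Rouse estimate
    tethered: bool = True
    wall: bool = True

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError(f"need at least 2 beads, got {self.n_beads}")
        if self.tether_height <= 0:
            raise ValueError("tether_height must be positive")
        if self.segment_length <= 0 or self.bead_diffusion <= 0:
            raise ValueError("segment_length and bead_diffusion must be positive")
        if self.timestep <= 0 or self.n_steps < 1 or self.n_replicas < 1:
            raise ValueError("timestep, n_steps and n_replicas must be positive")
        if self.binding_range <= 0:
            raise ValueError("binding_range must be positive")
        # The integrator must resolve the binding well: a single diffusive
        # step has to be small against the well range or events are missed.
        rms_step = math.sqrt(2.0 * self.bead_diffusion * self.timestep)
        if rms_step >= 0.1 * self.binding_range:
            raise ValueError(
                f"per-step RMS displacement {rms_step:.3g} nm must stay below "
                f"0.1 x binding_range = {0.1 * self.binding_range:.3g} nm; "
                "reduce the timestep"
            )

    @property
    def rouse_time(self) -> float:
        return rouse_time_estimate(
            self.n_beads, self.segment_length, self.bead_diffusion
        )

    @property
    def default_equilibration_steps(self) -> int:
        if self.equilibration_steps is not None:
            return int(self.equilibration_steps)
        return int(round(10.0 * self.rouse_time / self.timestep))

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        """Load a config from YAML; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ChainSystem:
    """Initial state of one tethered (or free) chain."""

    positions: np.ndarray  # (n_beads, 3), bead 0 is the tether point
    config: SimulationConfig
    spec: PolymerSpec | None = None

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def chain_contour(self) -> float:
        return (self.n_beads - 1) * self.config.segment_length


@dataclass
class HeightSeries:
    """Terminal-bead height above the plane for one replica."""

    times: np.ndarray
    heights: np.ndarray
    replica_id: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.heights):
            raise ValueError("times and heights must have equal length")

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class BrownianResult:
    """Output of a multi-replica Brownian-dynamics run."""

    height_series: list[HeightSeries]
    end_to_end_sq: list[np.ndarray]  # squared end-to-end distance per sample
    trajectories: list[np.ndarray] | None
    config: SimulationConfig
    seeds: list[int]

    def pooled_heights(self) -> np.ndarray:
        return np.concatenate([hs.heights for hs in self.height_series])


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    pos,
    n_steps,
    sample_every,
    dt,
    D,
    b,
    k_bond,
    sigma,
    eps_ev,
    k_wall,
    eps_bind,
    s_bind,
    tethered,
    wall,
    seed,
    heights,
    ree2,
    traj,
    traj_every,
    blowup_limit,
):  # pragma: no cover - exercised through run_brownian
    np.random.seed(seed)
    n = pos.shape[0]
    start = 1 if tethered else 0
    forces = np.zeros((n, 3))
    rc2 = sigma * sigma  # soft-core cutoff squared
    inv_s2 = 1.0 / (s_bind * s_bind)
    sqrt_2Ddt = math.sqrt(2.0 * D * dt)
    mob_dt = D * dt  # mobility * dt with kT = 1
    si = 0
    ti = 0
    for step in range(n_steps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        # harmonic bonds
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                fmag = -k_bond * (r - b) / r
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                forces[i + 1, 0] += fx
                forces[i + 1, 1] += fy
                forces[i + 1, 2] += fz
                forces[i, 0] -= fx
                forces[i, 1] -= fy
                forces[i, 2] -= fz
        # soft-core excluded volume between non-bonded pairs:
        # U = eps (1 - r/sigma)^2, bounded force 2 eps / sigma at overlap
        if eps_ev > 0.0:
            for i in range(n - 2):
                for j in range(i + 2, n):
                    dx = pos[j, 0] - pos[i, 0]
                    dy = pos[j, 1] - pos[i, 1]
                    dz = pos[j, 2] - pos[i, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rc2 and r2 > 1e-12:
                        r = math.sqrt(r2)
                        fmag = 2.0 * eps_ev * (1.0 / sigma - r / (sigma * sigma)) / r
                        fx = fmag * dx
                        fy = fmag * dy
                        fz = fmag * dz
                        forces[j, 0] += fx
                        forces[j, 1] += fy
                        forces[j, 2] += fz
                        forces[i, 0] -= fx
                        forces[i, 1] -= fy
                        forces[i, 2] -= fz
        # soft wall at z = 0
        if wall:
            for i in range(start, n):
                z = pos[i, 2]
                if z < 0.0:
                    forces[i, 2] -= k_wall * z
        # Gaussian binding well on the terminal bead
        if eps_bind > 0.0:
            z = pos[n - 1, 2]
            forces[n - 1, 2] -= eps_bind * z * inv_s2 * math.exp(
                -0.5 * z * z * inv_s2
            )
        # Euler-Maruyama update of mobile beads
        for i in range(start, n):
            for k in range(3):
                pos[i, k] += mob_dt * forces[i, k] + sqrt_2Ddt * np.random.normal()
        if (step + 1) % sample_every == 0:
            hz = pos[n - 1, 2]
            heights[si] = hz
            dx = pos[n - 1, 0] - pos[0, 0]
            dy = pos[n - 1, 1] - pos[0, 1]
            dz = pos[n - 1, 2] - pos[0, 2]
            ree2[si] = dx * dx + dy * dy + dz * dz
            if traj_every > 0 and si % traj_every == 0 and ti < traj.shape[0]:
                for i in range(n):
                    for k in range(3):
                        traj[ti, i, k] = pos[i, k]
                ti += 1
            si += 1
            if abs(hz) > blowup_limit or abs(dx) > blowup_limit or abs(dy) > blowup_limit:
                return 1
    return 0


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------


def beads_for_spec(spec: PolymerSpec, units_per_bead: int = 3) -> int:
    """Bead count (including the fixed tether bead) for a PEG spec.

    One bead lumps ``units_per_bead`` PEO units; the mobile bead count is the
    nearest integer of ``n_units_exact / units_per_bead`` and the fixed
    tether point adds one.
    """
    if units_per_bead < 1:
        raise ValueError("units_per_bead must be >= 1")
    return int(math.floor(spec.n_units_exact / units_per_bead + 0.5)) + 1


def build_chain(
    spec: PolymerSpec | None = None,
    config: SimulationConfig | None = None,
    units_per_bead: int = 3,
) -> ChainSystem:
    """Initialise a tethered chain, mapping a PEG spec onto beads if given.

    With a spec, ``n_beads`` and ``segment_length`` are derived from the
    coarse-graining (``units_per_bead`` PEO units per bead, so the segment
    length is ``units_per_bead x 0.28`` nm); otherwise the config values are
    used as-is.  Bead 0 sits fixed at the tether height; the rest are grown
    as a random walk of bond-length steps, rejecting overlaps and (for a
    walled system) placements below the plane.  The same seed always gives
    the same initial coordinates.
    """
    config = config or SimulationConfig()
    if spec is not None:
        config = config.replace(
            n_beads=beads_for_spec(spec, units_per_bead),
            segment_length=units_per_bead * spec.unit_length,
        )
    chain_contour = (config.n_beads - 1) * config.segment_length
    if config.tethered and chain_contour < config.tether_height - config.binding_range:
        warnings.warn(
            f"chain contour {chain_contour:.2f} nm cannot reach the binding "
            f"plane from tether height {config.tether_height} nm; binding "
            "will be impossible or vanishingly rare",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    pos = _grow_chain(config, rng)
    return ChainSystem(positions=pos, config=config, spec=spec)


def _grow_chain(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_beads
    b = config.segment_length
    sigma = config.excluded_volume_sigma
    origin_z = config.tether_height if config.tethered else max(
        config.tether_height, 0.5 * n * b
    )
    pos = np.zeros((n, 3))
    pos[0] = (0.0, 0.0, origin_z)
    for i in range(1, n):
        for _attempt in range(2000):
            v = rng.normal(size=3)
            v *= b / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if config.wall and cand[2] < 0.05:
                continue
            if i >= 2:
                d = np.linalg.norm(pos[: i - 1] - cand, axis=1)
                if np.any(d < 0.9 * sigma):
                    continue
            pos[i] = cand
            break
        else:
            raise RuntimeError(
                f"could not place bead {i} without overlap after 2000 attempts"
            )
    return pos


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def run_brownian(
    system: ChainSystem,
    record_trajectory: bool = False,
    trajectory_every: int = 100,
) -> BrownianResult:
    """Run overdamped Langevin dynamics for every replica of a system.

    Each replica re-grows its own initial conformation and integrates with
    an independent seed spawned from the master seed.  The first
    ``equilibration_steps`` (default ten Rouse times) are discarded before
    any sample is recorded.  Returns per-replica terminal-height series,
    squared end-to-end distances, and (optionally) thinned trajectories.
    """
    cfg = system.config
    equil = cfg.default_equilibration_steps
    total_steps = equil + cfg.n_steps
    n_samples_total = total_steps // cfg.sample_every
    n_equil_samples = equil // cfg.sample_every
    master = np.random.SeedSequence(cfg.seed)
    # keep seeds below 2^31 for the kernel RNG
    seeds = [int(s) for s in (master.generate_state(cfg.n_replicas) >> 1)]
    blowup_limit = 10.0 * max(system.chain_contour, cfg.tether_height)

    height_series: list[HeightSeries] = []
    ree2_list: list[np.ndarray] = []
    traj_list: list[np.ndarray] | None = [] if record_trajectory else None
    sample_dt = cfg.sample_every * cfg.timestep
    times = (1.0 + np.arange(n_samples_total - n_equil_samples)) * sample_dt

    for rep, rep_seed in enumerate(seeds):
        init_rng = np.random.default_rng(rep_seed)
        pos = _grow_chain(cfg, init_rng)
        heights = np.empty(n_samples_total)
        ree2 = np.empty(n_samples_total)
        if record_trajectory:
            n_frames = n_samples_total // trajectory_every + 1
            traj = np.empty((n_frames, cfg.n_beads, 3))
        else:
            traj = np.empty((0, cfg.n_beads, 3))
        flag = _run_kernel(
            pos,
            total_steps,
            cfg.sample_every,
            cfg.timestep,
            cfg.bead_diffusion,
            cfg.segment_length,
            cfg.bond_stiffness,
            cfg.excluded_volume_sigma,
            cfg.excluded_volume_strength,
            cfg.wall_stiffness,
            cfg.binding_depth,
            0.5 * cfg.binding_range,
            cfg.tethered,
            cfg.wall,
            rep_seed,
            heights,
            ree2,
            traj,
            trajectory_every if record_trajectory else 0,
            blowup_limit,
        )
        if flag != 0:
            raise RuntimeError(
                f"replica {rep} (seed {rep_seed}) diverged: a coordinate "
                f"exceeded {blowup_limit:.1f} nm; reduce the timestep or "
                "bond stiffness"
            )
        height_series.append(
            HeightSeries(
                times=times.copy(),
                heights=heights[n_equil_samples:],
                replica_id=rep,
                seed=rep_seed,
            )
        )
        ree2_list.append(ree2[n_equil_samples:])
        if record_trajectory:
            traj_list.append(traj)
    return BrownianResult(
        height_series=height_series,
        end_to_end_sq=ree2_list,
        trajectories=traj_list,
        config=cfg,
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def detect_events(
    series: HeightSeries,
    bind_cutoff: float = 1.0,
    unbind_cutoff: float | None = 1.5,
) -> EventTrace:
    """Classify a height series into alternating bound/unbound dwells.

    A binding event starts when the terminal height drops below
    ``bind_cutoff`` and ends when it rises above ``unbind_cutoff``.  The
    hysteresis (dual cutoff) suppresses rapid recrossing chatter at the
    threshold; setting ``unbind_cutoff = bind_cutoff`` (or ``None``) recovers
    the single-cutoff definition of a binding event.  The first and last
    dwells are flagged as censored: their true start/end lie outside the
    observation window.
    """
    if unbind_cutoff is None:
        unbind_cutoff = bind_cutoff
    if unbind_cutoff < bind_cutoff:
        raise ValueError("unbind_cutoff must be >= bind_cutoff")
    h = np.asarray(series.heights)
    if h.size == 0:
        raise ValueError("empty height series")
    dt = series.sample_dt if len(h) > 1 else 1.0

    states = []  # 1 = bound, 0 = unbound
    counts = []
    state = 1 if h[0] < bind_cutoff else 0
    count = 1
    for z in h[1:]:
        if state == 0 and z < bind_cutoff:
            states.append(0)
            counts.append(count)
            state, count = 1, 1
        elif state == 1 and z > unbind_cutoff:
            states.append(1)
            counts.append(count)
            state, count = 0, 1
        else:
            count += 1
    states.append(state)
    counts.append(count)

    durations = np.asarray(counts, dtype=float) * dt
    states_arr = np.asarray(states, dtype=int)
    return EventTrace(
        states=states_arr,
        durations=durations,
        total_time=float(len(h) * dt),
        first_censored=True,
        last_censored=True,
    )
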