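"""Ground-truth generators and the packaged linker table.

Every stage of the analysis pipeline can be exercised end-to-end without
any external data: a two-state telegraph process stands in for bound/unbound
dynamics of the tethered ligand, noisy donor-intensity pairs emulate the
acceptor-photobleaching FRET readout, and linear-in-time IL2 curves emulate
the stimulation time course.  Each generator is deterministic under a fixed
seed and returns its ground truth alongside the synthetic record, so
estimators can be tested closed-loop.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .kinetics import EventTrace
from .simulate import HeightSeries

__all__ = [
    "TelegraphParams",
    "gen_telegraph",
    "gen_fret_intensities",
    "gen_response_curves",
    "table1_fixture",
]


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state Markov surrogate for bound/unbound switching.

    ``k_on`` is the unbound->bound rate (so mean unbound dwell is 1/k_on)
    and ``k_off`` the bound->unbound rate.  Dwells are exponential.
    """

    k_on: float
    k_off: float
    duration: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


# Surrogate height levels: far from both detection cutoffs (1.0 / 1.5 nm)
# so single- and dual-cutoff modes classify identically.
_BOUND_LEVEL = 0.5
_UNBOUND_LEVEL = 3.0
_JITTER_SD = 0.05


def gen_telegraph(
    params: TelegraphParams,
    sample_dt: float = 0.01,
    emit_heights: bool = True,
) -> tuple[EventTrace, HeightSeries | None]:
    """Draw a telegraph trace and a surrogate height series.

    Alternating exponential dwells are drawn until ``duration`` is filled
    (the final dwell is truncated and marked censored).  The surrogate
    height series renders each dwell as ``max(1, round(d / sample_dt))``
    samples at 0.5 nm (bound) or 3 nm (unbound) plus small Gaussian jitter,
    so threshold event detection recovers the generator's own dwell counts
    exactly.  Pass ``emit_heights=False`` to skip the (potentially large)
    surrogate series when only the dwell trace is needed.
    """
    if params.duration < 10.0 / min(params.k_on, params.k_off):
        warnings.warn(
            "duration is short relative to the slowest rate; expect very "
            "few events",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    states, durations = [], []
    t, state = 0.0, 0  # start unbound
    last_censored = False
    while t < params.duration:
        rate = params.k_on if state == 0 else params.k_off
        d = rng.exponential(1.0 / rate)
        if t + d > params.duration:
            d = params.duration - t
            last_censored = True
        states.append(state)
        durations.append(d)
        t += d
        state = 1 - state
    trace = EventTrace(
        states=np.array(states),
        durations=np.array(durations),
        total_time=params.duration,
        first_censored=False,
        last_censored=last_censored,
    )
    if not emit_heights:
        return trace, None
    heights, times = [], []
    t_acc = 0.0
    for s, d in zip(states, durations):
        n = max(1, int(round(d / sample_dt)))
        level = _BOUND_LEVEL if s == 1 else _UNBOUND_LEVEL
        heights.append(level + _JITTER_SD * rng.standard_normal(n))
        times.append(t_acc + sample_dt * (1.0 + np.arange(n)))
        t_acc += n * sample_dt
    surrogate = HeightSeries(
        times=np.concatenate(times),
        heights=np.concatenate(heights),
        replica_id=0,
        seed=params.seed,
    )
    return trace, surrogate


def gen_fret_intensities(
    true_efficiency: float,
    noise_sd: float = 0.05,
    n: int = 100,
    seed: int = 0,
    base_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Donor intensity pairs around a known transfer efficiency.

    ``donor_after`` (post-bleach, unquenched) is drawn around a base level;
    ``donor_before = donor_after * (1 - E)`` with multiplicative Gaussian
    noise of relative sd ``noise_sd``.  Columns: donor_before, donor_after,
    true_efficiency.
    """
    if not 0 <= true_efficiency < 1:
        raise ValueError("true_efficiency must be in [0, 1)")
    rng = np.random.default_rng(seed)
    after = base_intensity * (1.0 + 0.1 * rng.standard_normal(n))
    after = np.abs(after)
    before = after * (1.0 - true_efficiency) * (
        1.0 + noise_sd * rng.standard_normal(n)
    )
    before = np.clip(before, 0.0, None)
    return pd.DataFrame(
        {
            "donor_before": before,
            "donor_after": after,
            "true_efficiency": true_efficiency,
        }
    )


def gen_response_curves(
    slope_per_linker: dict[str, float],
    noise_sd: float = 0.02,
    timepoints=(1, 2, 3, 4, 5, 6),
    n_experiments: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-in-time normalized response curves with additive noise.

    Emulates an hourly stimulation time course (default six hourly
    timepoints, three independent experiments).  Responses are
    ``slope * t`` plus Gaussian noise, clipped to [0, 1]; the defaults keep
    slopes <= 1/6 per hour so clipping is negligible.  Columns: linker,
    experiment_id, time_h, percent_il2 (on the 0-1 normalized scale),
    true_slope.
    """
    if any(s < 0 for s in slope_per_linker.values()):
        raise ValueError("slopes must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    rows = []
    for linker, slope in slope_per_linker.items():
        for exp in range(n_experiments):
            y = np.clip(slope * t + noise_sd * rng.standard_normal(len(t)), 0.0, 1.0)
            for ti, yi in zip(t, y):
                rows.append(
                    {
                        "linker": linker,
                        "experiment_id": f"exp{exp + 1}",
                        "time_h": ti,
                        "percent_il2": yi,
                        "true_slope": slope,
                    }
                )
    return pd.DataFrame(rows)


def table1_fixture() -> pd.DataFrame:
    """The nine PEG linkers with their printed properties.

    Columns: name, mw_da, n_units, contour_length_nm, flory_radius_nm,
    fret_efficiency_pct (NaN where transfer was below detection).
    """
    ref = importlib.resources.files("pegtether.data") / "peg_linker_table.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
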