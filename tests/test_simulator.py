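"""Tethered-chain Brownian dynamics: construction, sampling, event detection."""

import numpy as np
import pytest

from pegtether import (
    HeightSeries,
    PolymerSpec,
    SimulationConfig,
    build_chain,
    detect_events,
    run_brownian,
)
from pegtether.simulate import beads_for_spec


def _quick_config(**kwargs):
    defaults = dict(
        n_beads=6,
        n_steps=20_000,
        n_replicas=2,
        equilibration_steps=5_000,
        seed=42,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_too_coarse_timestep_rejected(self):
        # RMS step must resolve the binding well
        with pytest.raises(ValueError, match="RMS displacement"):
            SimulationConfig(timestep=0.05, binding_range=1.0)

    def test_yaml_roundtrip_rejects_unknown_keys(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_beads: 10\ntether_height: 5.0\n")
        cfg = SimulationConfig.from_yaml(str(path))
        assert cfg.n_beads == 10 and cfg.tether_height == 5.0
        path.write_text("n_beads: 10\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            SimulationConfig.from_yaml(str(path))


class TestBuildChain:
    def test_peg4000_maps_to_31_beads_at_three_units_per_bead(self):
        # round(90.9 / 3) mobile beads plus the fixed tether bead
        spec = PolymerSpec(4000)
        assert beads_for_spec(spec, units_per_bead=3) == 31
        system = build_chain(spec, _quick_config())
        assert system.n_beads == 31
        assert system.config.segment_length == pytest.approx(0.84)

    def test_dumbbell(self):
        system = build_chain(config=_quick_config(n_beads=2))
        assert system.positions.shape == (2, 3)
        assert system.positions[0, 2] == system.config.tether_height

    def test_identical_seeds_give_identical_coordinates(self):
        a = build_chain(config=_quick_config(seed=7))
        b = build_chain(config=_quick_config(seed=7))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_short_chain_warns_when_plane_unreachable(self):
        with pytest.warns(UserWarning, match="cannot reach"):
            build_chain(config=_quick_config(n_beads=4, tether_height=9.0))

    def test_bond_lengths_and_no_overlaps_below_tether(self):
        system = build_chain(config=_quick_config(n_beads=20, tether_height=12.0))
        bonds = np.linalg.norm(np.diff(system.positions, axis=0), axis=1)
        assert np.allclose(bonds, system.config.segment_length)
        assert system.positions[1:, 2].min() > 0


class TestRunBrownian:
    def test_same_seed_bit_identical(self):
        cfg = _quick_config(tether_height=4.0)
        r1 = run_brownian(build_chain(config=cfg))
        r2 = run_brownian(build_chain(config=cfg))
        for a, b in zip(r1.height_series, r2.height_series):
            np.testing.assert_array_equal(a.heights, b.heights)
        assert r1.seeds == r2.seeds

    def test_distinct_replicas_distinct_paths(self):
        res = run_brownian(build_chain(config=_quick_config(tether_height=4.0)))
        assert not np.array_equal(
            res.height_series[0].heights, res.height_series[1].heights
        )

    def test_no_attraction_means_no_bound_dwells(self):
        # repulsive tethered chain at h = 9 never dwells below the 1 nm cutoff
        cfg = _quick_config(n_beads=10, binding_depth=0.0, n_steps=60_000)
        res = run_brownian(build_chain(config=cfg))
        heights = res.pooled_heights()
        assert heights.mean() > 4.0
        for hs in res.height_series:
            trace = detect_events(hs)
            assert len(trace.bound_dwells(complete_only=False)) == 0

    def test_heights_never_significantly_below_plane(self):
        # soft wall tolerance: penetration limited to ~sqrt(kT / k_wall)
        cfg = _quick_config(
            n_beads=4, tether_height=1.5, binding_depth=7.0, n_steps=80_000
        )
        res = run_brownian(build_chain(config=cfg))
        assert res.pooled_heights().min() > -0.4

    def test_trajectory_recording_shape(self):
        cfg = _quick_config(n_steps=10_000, equilibration_steps=1_000)
        res = run_brownian(build_chain(config=cfg), record_trajectory=True)
        assert res.trajectories is not None
        traj = res.trajectories[0]
        assert traj.ndim == 3 and traj.shape[1] == cfg.n_beads


class TestEquilibriumStatistics:
    """Boltzmann-consistency checks on the terminal-height distribution."""

    @staticmethod
    def _heights_at_depth(eps, seed=9):
        cfg = SimulationConfig(
            n_beads=3,
            tether_height=1.2,
            binding_depth=eps,
            n_steps=400_000,
            sample_every=5,
            n_replicas=2,
            equilibration_steps=20_000,
            seed=seed,
        )
        return run_brownian(build_chain(config=cfg)).pooled_heights()

    def test_bound_fraction_increases_with_well_depth(self):
        fracs = [np.mean(self._heights_at_depth(eps) < 1.0) for eps in (0.0, 2.0, 4.0)]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_reweighted_flat_run_predicts_attractive_run(self):
        # detailed balance: P_eps(z) must equal P_0(z) e^{-U_bind(z)} up to
        # normalisation; compare the predicted and measured bound fractions
        h0 = self._heights_at_depth(0.0)
        h4 = self._heights_at_depth(4.0)
        eps, s = 4.0, 0.5
        w = np.exp(eps * np.exp(-0.5 * (h0 / s) ** 2))
        predicted = np.sum(w[h0 < 1.0]) / np.sum(w)
        measured = np.mean(h4 < 1.0)
        assert measured == pytest.approx(predicted, rel=0.2)


class TestDetectEvents:
    def _series(self, heights, dt=1.0):
        h = np.asarray(heights, dtype=float)
        return HeightSeries(
            times=dt * (1 + np.arange(len(h))), heights=h, replica_id=0, seed=0
        )

    def test_single_bound_dwell_with_hysteresis(self):
        trace = detect_events(
            self._series([3, 0.8, 0.9, 2.0, 3]), bind_cutoff=1.0, unbind_cutoff=1.5
        )
        bound = trace.bound_dwells(complete_only=False)
        assert len(bound) == 1
        assert bound[0] == pytest.approx(2.0)  # two samples at dt = 1

    def test_intermediate_heights_do_not_unbind_below_upper_cutoff(self):
        # 1.2 nm is above the bind cutoff but below the unbind cutoff:
        # hysteresis keeps the bound state alive
        trace = detect_events(
            self._series([3, 0.8, 1.2, 0.9, 2.0]), bind_cutoff=1.0, unbind_cutoff=1.5
        )
        assert len(trace.bound_dwells(complete_only=False)) == 1
        assert trace.bound_dwells(complete_only=False)[0] == pytest.approx(3.0)

    def test_single_cutoff_fidelity_mode(self):
        trace = detect_events(
            self._series([3, 0.8, 1.2, 0.9, 2.0]), bind_cutoff=1.0, unbind_cutoff=1.0
        )
        assert len(trace.bound_dwells(complete_only=False)) == 2

    def test_all_heights_above_cutoff_yields_no_events(self):
        trace = detect_events(self._series([2, 3, 4, 5]))
        assert trace.n_binding_events == 0
        assert len(trace.bound_dwells(complete_only=False)) == 0

    def test_first_and_last_dwells_censored(self):
        trace = detect_events(self._series([3, 0.5, 3, 0.5, 3]))
        assert trace.first_censored and trace.last_censored
        # three unbound dwells, two censored away
        assert len(trace.unbound_dwells(complete_only=False)) == 3
        assert len(trace.unbound_dwells()) == 1

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            detect_events(self._series([1, 2]), bind_cutoff=1.0, unbind_cutoff=0.5)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_events(self._series([]))
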