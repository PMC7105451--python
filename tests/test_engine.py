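"""Time-stepping engine: stability, step updates, therapy, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from tislet import (EcmAnnulus, SimulationConfig, apply_therapy_schedule,
                    make_scenario, max_stable_dt, run_simulation,
                    step_epithelial_cancer, step_tcells)
from tislet.fields import Species

from conftest import tiny_config


class TestMaxStableDt:
    def test_reference_value(self):
        assert max_stable_dt(8.0, [[40.0, 0.0]]) == pytest.approx(0.1)

    def test_zero_velocity_capped(self):
        assert max_stable_dt(8.0, np.zeros((3, 2)), cap=0.01) == 0.01

    def test_halves_with_speed(self):
        a = max_stable_dt(8.0, [[40.0, 0.0]])
        assert max_stable_dt(8.0, [[80.0, 0.0]]) == pytest.approx(a / 2)


class TestEpithelialCancerStep:
    def test_single_cell_does_not_drift(self):
        cfg = tiny_config()
        out = step_epithelial_cancer(np.array([[0.0, 0.0]]), [8.0], cfg, 0.01)
        assert np.allclose(out, [[0.0, 0.0]])

    def test_two_cell_hand_oracle(self):
        """First step of the two-cell toy state, computed by hand.

        Each cell drifts away from its neighbour by Δt·α·M with
        α = βR³/(μF) = 5120 and M = M⁰(1 + e^{-λd/R}).
        """
        cfg = make_scenario("toy_two_cell").config
        m0 = 30.0 ** 2 / (2 * math.pi ** 2 * 5.0 * 8.0 ** 4)
        m = m0 * (1 + math.exp(-10.0 * 20.0 / 8.0))
        expected_shift = 0.01 * 5120.0 * m
        traj = run_simulation(cfg)
        xs = np.sort(traj.final_cells["x_um"].to_numpy())
        assert xs == pytest.approx([-10.0 - expected_shift,
                                    10.0 + expected_shift], rel=1e-9)

    def test_reference_step_matches_kernel(self):
        """Compiled kernel and numpy reference agree at η = 0."""
        pos0 = np.array([[0.0, 0.0], [14.0, 2.0], [-9.0, 6.0], [40.0, -35.0],
                         [3.0, -12.0], [60.0, 60.0]])
        cfg = tiny_config(initial_positions=pos0.tolist())
        expected = step_epithelial_cancer(pos0, np.full(6, 8.0), cfg, 0.01)
        traj = run_simulation(cfg)
        got = traj.final_cells.sort_values("cell_id")[["x_um", "y_um"]]
        assert got.to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_overlapping_cells_separate(self):
        pos0 = np.array([[0.0, 0.0], [6.0, 0.0]])      # 10 μm overlap
        cfg = tiny_config(initial_positions=pos0.tolist(), t_end=0.5)
        traj = run_simulation(cfg)
        xs = np.sort(traj.final_cells["x_um"].to_numpy())
        assert xs[1] - xs[0] > 6.0


class TestTcellStep:
    def test_no_cancer_no_motion(self):
        cfg = tiny_config()
        ann = cfg.annulus()
        out = step_tcells(np.array([[250.0, 0.0]]), np.zeros((0, 2)),
                          [], [], ann, cfg, 0.01)
        assert np.allclose(out, [[250.0, 0.0]])

    def test_fresh_annulus_attenuates_radial_motion(self):
        """Inside anisotropic stroma the radial response is suppressed by
        e^{-ks}·λ1/λ2 relative to the tangential response."""
        cfg = tiny_config(eta=2.0)
        ann = cfg.annulus()
        p = np.array([[160.0, 0.0]])      # radial = x, tangential = y
        noise = np.array([[1.0, 1.0]])
        out = step_tcells(p, np.zeros((0, 2)), [], [], ann, cfg, 0.01,
                          noise=noise)
        # noise enters scaled by η√dt then by μ_j Ψ
        base = cfg.eta * math.sqrt(0.01)
        s = 200.0 - 160.0
        expect_rad = cfg.chemotactic_mobility * math.exp(-0.3 * s) * base
        expect_tan = cfg.chemotactic_mobility * 10.0 * base
        d = out[0] - p[0]
        assert d[0] == pytest.approx(expect_rad, rel=1e-9)
        assert d[1] == pytest.approx(expect_tan, rel=1e-9)
        assert abs(d[0]) < 1e-3 * abs(d[1])

    def test_degraded_annulus_is_isotropic(self):
        cfg = tiny_config(eta=2.0)
        ann = EcmAnnulus(lambda1=1.0, lambda2_init=1.0, k_init=0.0, v0=1.0)
        p = np.array([[160.0, 0.0]])
        noise = np.array([[1.0, -0.5]])
        out = step_tcells(p, np.zeros((0, 2)), [], [], ann, cfg, 0.01,
                          noise=noise)
        d = out[0] - p[0]
        base = cfg.eta * math.sqrt(0.01) * cfg.chemotactic_mobility
        assert d == pytest.approx(base * noise[0], rel=1e-9)

    def test_drift_points_up_gradient(self):
        cfg = tiny_config()
        ann = cfg.annulus()
        out = step_tcells(np.array([[250.0, 0.0]]), np.array([[0.0, 0.0]]),
                          [], [], ann, cfg, 0.01)
        assert out[0][0] < 250.0      # toward the cancer cell at the origin


class TestTherapySchedule:
    def test_no_crossing_no_events(self):
        cfg = SimulationConfig(scenario="combo")
        times = np.arange(0, 10, 0.01)
        events, marks = apply_therapy_schedule(times, np.full_like(times, 0.1),
                                               cfg)
        assert events == [] and marks["t0"] is None

    def test_untreated_scenario_never_injects(self):
        cfg = SimulationConfig(scenario="none")
        times = np.arange(0, 10, 0.01)
        events, _ = apply_therapy_schedule(times, np.linspace(0, 1, 1000), cfg)
        assert events == []

    def test_timeline_marks(self):
        cfg = SimulationConfig(scenario="combo", trigger_fraction=0.35)
        times = np.arange(0, 100, 0.01)
        f = np.minimum(times / 100.0, 1.0)          # crosses 0.35 at t=35+
        events, marks = apply_therapy_schedule(times, f, cfg)
        assert marks["t0"] == pytest.approx(35.01, abs=0.02)
        assert marks["t1"] == pytest.approx(marks["t0"] + 1.0)
        assert marks["t2"] == pytest.approx(marks["t0"] + 10.0)
        assert marks["t3"] == pytest.approx(marks["t2"] + 1.0)
        assert [e.species for e in events] == [Species.ENZYME, Species.DRUG]

    def test_kernel_trigger_matches_timeline(self):
        cfg = SimulationConfig(seed=3, scenario="combo", t_end=80.0)
        traj = run_simulation(cfg)
        s = traj.summary
        assert s["t0_h"] > 0
        assert s["t1_h"] == pytest.approx(s["t0_h"] + 1.0)
        assert s["t2_h"] == pytest.approx(s["t0_h"] + 10.0)
        assert s["t3_h"] == pytest.approx(s["t2_h"] + 1.0)
        ts = traj.timeseries
        idx = int(round(s["t0_h"] / cfg.dt))
        assert ts.f.iloc[idx] > 0.35
        assert np.all(ts.f.iloc[: idx - 1].to_numpy() <= 0.35)


@pytest.fixture(scope="module")
def short_run():
    cfg = SimulationConfig(seed=5, scenario="none", t_end=20.0,
                           store_cells=True, snapshot_every=2.0)
    return cfg, run_simulation(cfg)


class TestRunInvariants:
    def test_times_strictly_increasing_f_bounded(self, short_run):
        _, traj = short_run
        ts = traj.timeseries
        assert np.all(np.diff(ts.time_h) > 0)
        assert ts.f.between(0, 1).all()

    def test_all_cells_inside_domain(self, short_run):
        cfg, traj = short_run
        r = np.hypot(traj.final_cells.x_um, traj.final_cells.y_um)
        assert np.all(r <= cfg.domain_radius)

    def test_confinement_keeps_islet_cells_inside_r1(self, short_run):
        cfg, traj = short_run
        wc = traj.final_cells[traj.final_cells.phenotype != "tlymphocyte"]
        assert np.all(np.hypot(wc.x_um, wc.y_um)
                      <= cfg.islet_inner_radius - cfg.cell_radius + 1e-9)

    def test_no_deep_overlap_between_islet_cells(self, short_run):
        """Hertz repulsion keeps overlap below one radius."""
        cfg, traj = short_run
        wc = traj.final_cells[traj.final_cells.phenotype != "tlymphocyte"]
        p = wc[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > cfg.cell_radius

    def test_tcells_spawn_on_first_mutation(self, short_run):
        cfg, traj = short_run
        ts = traj.timeseries
        t_mut = traj.summary["t_first_mutation_h"]
        assert t_mut >= 0
        i = int(round(t_mut / cfg.dt))
        assert ts.n_tcell.iloc[i] == cfg.n_tcells
        assert ts.n_tcell.iloc[max(i - 1, 0)] in (0, cfg.n_tcells)

    def test_snapshot_cadence(self, short_run):
        cfg, traj = short_run
        times = traj.snapshots.time_h.unique()
        assert times == pytest.approx(np.arange(0, 21, 2.0))


class TestTcellTrappingAndInfiltration:
    def test_untreated_tcells_stay_out_of_the_islet(self):
        traj = run_simulation(SimulationConfig(seed=2, scenario="none",
                                               t_end=60.0))
        tc = traj.final_cells.query("phenotype == 'tlymphocyte'")
        r = np.hypot(tc.x_um, tc.y_um)
        assert np.all(r > 120.0 - 13.0)     # never deep inside the islet
        lam2 = traj.summary["lambda2_final"]
        assert lam2 == pytest.approx(np.full(10, 10.0))

    def test_enzyme_degrades_anisotropy_and_lets_tcells_in(self):
        traj = run_simulation(SimulationConfig(seed=2, scenario="pegph20",
                                               t_end=100.0))
        lam2 = np.asarray(traj.summary["lambda2_final"])
        assert np.all(lam2 < 2.0)
        kk = np.asarray(traj.summary["k_final"])
        assert np.all(kk < 0.05)
        tc = traj.final_cells.query("phenotype == 'tlymphocyte'")
        assert np.any(np.hypot(tc.x_um, tc.y_um) < 120.0)
        assert (traj.events.event == "kill").sum() > 0
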