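"""Cell mechanics, motility statistics, immigration and departures."""

import numpy as np
import pytest
from scipy import stats

from thymosim.geometry import Domain, build_niche
from thymosim.mechanics import (
    active_displacement,
    death_mask,
    exit_mask,
    outward_heading,
    spawn_is_blocked,
    spawn_position,
    step_forces,
    update_headings,
)
from thymosim.params import SimulationParams
from thymosim import run_simulation


@pytest.fixture
def params():
    return SimulationParams(seed=0)


@pytest.fixture
def domain(params):
    return Domain(params.domain_radius, params.domain_depth)


def pair_disp(positions, radii, params, domain):
    eb = np.zeros(len(radii), dtype=bool)
    disp, _ = step_forces(
        np.asarray(positions, dtype=float), np.asarray(radii, dtype=float),
        eb, None, domain, params,
    )
    return disp


class TestForces:
    def test_contact_pair_has_zero_net_force(self, params, domain):
        pos = [[0.0, -20.0, 2.5], [5.0, -20.0, 2.5]]  # distance = r_i + r_j
        disp = pair_disp(pos, [2.5, 2.5], params, domain)
        np.testing.assert_allclose(disp, 0.0, atol=1e-12)

    def test_overlapping_pair_forces_equal_and_opposite(self, params, domain):
        pos = [[0.0, -20.0, 2.5], [4.0, -20.0, 2.5]]
        disp = pair_disp(pos, [2.5, 2.5], params, domain)
        np.testing.assert_allclose(disp[0], -disp[1])
        assert disp[0][0] < 0  # pushed apart along the centre line
        assert disp[1][0] > 0

    def test_adhesive_shell_pulls_back_together(self, params, domain):
        pos = [[0.0, -20.0, 2.5], [5.5, -20.0, 2.5]]  # in the adhesion shell
        disp = pair_disp(pos, [2.5, 2.5], params, domain)
        assert disp[0][0] > 0
        assert disp[1][0] < 0

    def test_isolated_cell_does_not_move(self, params, domain):
        disp = pair_disp([[0.0, -20.0, 2.5]], [2.5], params, domain)
        np.testing.assert_allclose(disp, 0.0, atol=1e-12)

    def test_tec_spheres_exert_force_but_never_move(self, params, domain):
        niche = build_niche(params, np.random.default_rng(0))
        before = niche.sphere_centers.copy()
        tec = niche.tecs[0]
        pos = np.array([tec.body_center + np.array([2.0, 0.0, 0.0])])
        eb = np.zeros(1, dtype=bool)
        disp, contact = step_forces(
            pos, np.array([2.5]), eb, niche, domain, params
        )
        assert np.linalg.norm(disp[0]) > 0
        assert contact[0]
        np.testing.assert_array_equal(niche.sphere_centers, before)


class TestRelaxation:
    def test_pair_potential_non_increasing_without_motility(self, params,
                                                            domain):
        from thymosim._kernels import pair_energy

        rng = np.random.default_rng(0)
        pos = np.column_stack([
            rng.uniform(-10, 10, 25), rng.uniform(-30, -10, 25),
            np.full(25, 2.5),
        ])
        rad = np.full(25, 2.5)
        eb = np.zeros(25, dtype=bool)
        # small relaxation keeps the overdamped update in the gradient-descent
        # regime (no overshoot), where the pair potential must be monotone
        gentle = params.replace(relaxation_per_step=0.05)
        args = (gentle.relaxation_per_step, gentle.adhesion_ratio,
                gentle.adhesion_range)
        first = prev = pair_energy(pos, rad, *args)
        # the potential is only C0 at the adhesion cutoff; an explicit step
        # can raise the energy by the kink depth per pair crossing it
        kink = 3 * 0.5 * args[0] * args[1] * ((args[2] - 1) * 5.0) ** 2
        for _ in range(200):
            disp, _ = step_forces(pos, rad, eb, None, domain, gentle)
            pos = pos + disp
            e = pair_energy(pos, rad, *args)
            assert e <= prev + kink
            prev = e
        assert prev < first

    def test_runaway_overlap_truncated_with_warning(self, params, domain):
        pos = np.array([[0.0, -20.0, 2.5], [0.1, -20.0, 2.5]])
        huge = params.replace(relaxation_per_step=5.0)
        with pytest.warns(UserWarning, match="truncated"):
            disp, _ = step_forces(
                pos, np.array([2.5, 2.5]), np.zeros(2, dtype=bool),
                None, domain, huge,
            )
        assert np.linalg.norm(disp, axis=1).max() <= 2.5 + 1e-9


class TestMotility:
    def test_speed_scale_halves_time_averaged_speed(self):
        rng = np.random.default_rng(0)
        dt = 15.0
        for scale, expect in ((1.0, 4.0), (0.5, 2.0)):
            phi = np.zeros(200)
            total = 0.0
            for _ in range(240):  # 1 hr of steps
                phi = update_headings(phi, np.full(200, 0.6), dt, rng)
                disp = active_displacement(phi, np.full(200, 4.0 * scale), dt)
                total += np.linalg.norm(disp[:, :2], axis=1).mean()
            speed = total / 240 / (dt / 60.0)
            assert speed == pytest.approx(expect, rel=0.05)

    def test_directionality_vanishes_without_persistence(self):
        # enormous turning noise -> pure diffusion -> net/total path -> 0
        rng = np.random.default_rng(1)
        dt = 15.0
        n = 300
        phi = rng.uniform(-np.pi, np.pi, n)
        start = np.zeros((n, 3))
        pos = start.copy()
        total = np.zeros(n)
        for _ in range(960):  # 4 hr
            phi = update_headings(phi, np.full(n, 50.0), dt, rng)
            d = active_displacement(phi, np.full(n, 4.0), dt)
            pos += d
            total += np.linalg.norm(d[:, :2], axis=1)
        ratio = np.linalg.norm(pos[:, :2], axis=1) / total
        assert ratio.mean() < 0.1

    def test_persistent_walker_mean_speed_within_5_percent(self):
        # track-statistics oracle: ensemble of 1-hr tracks
        rng = np.random.default_rng(2)
        dt = 15.0
        n = 150
        phi = rng.uniform(-np.pi, np.pi, n)
        path = np.zeros(n)
        for _ in range(240):
            phi = update_headings(phi, np.full(n, 0.6), dt, rng)
            d = active_displacement(phi, np.full(n, 4.0), dt)
            path += np.linalg.norm(d[:, :2], axis=1)
        measured = path / (240 * dt / 60.0)
        assert measured.mean() == pytest.approx(4.0, rel=0.05)

    def test_outward_heading_points_radially(self):
        pos = np.array([[0.0, -10.0, 2.5], [10.0, 0.0, 2.5]])
        h = outward_heading(pos)
        assert h[0] == pytest.approx(-np.pi / 2)
        assert h[1] == pytest.approx(0.0)


class TestImmigration:
    def test_spawn_positions_on_ventral_arc(self, domain):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = spawn_position(domain, 2.5, rng)
            rr = np.hypot(p[0], p[1])
            assert rr == pytest.approx(domain.radius - 2.5)
            assert p[1] <= 0.0

    def test_blocked_spawn_detection(self, domain):
        rng = np.random.default_rng(0)
        cand = spawn_position(domain, 2.5, rng)
        occupied = cand[None, :].copy()
        assert spawn_is_blocked(cand, 2.5, occupied, np.array([2.5]))
        far = occupied + np.array([[20.0, 0.0, 0.0]])
        assert not spawn_is_blocked(cand, 2.5, far, np.array([2.5]))

    def test_il7r_levels_uniform_on_unit_interval(self):
        # distributional oracle over a long immigration stream
        res = run_simulation(
            SimulationParams(seed=11, n_steps=30_000, homing_interval=0.2,
                             p_select=1.0),
            record_clone_series=False, occupancy_stride=0,
        )
        levels = res.forest.founders.il7r_level.values
        assert len(levels) > 300
        assert (levels >= 0).all() and (levels <= 1).all()
        ks = stats.kstest(levels, "uniform")
        assert ks.pvalue > 0.01

    def test_lesioned_founder_unique_and_after_entry_time(self):
        from thymosim.params import LesionSpec

        params = SimulationParams(
            seed=4, n_steps=18_000,
            lesion=LesionSpec(kinds=frozenset({"IL7R_WT"})),
            lesion_entry_time=30.0,
        )
        res = run_simulation(params, record_clone_series=False,
                             occupancy_stride=0)
        lesioned = res.forest.founders[res.forest.founders.lesioned]
        assert len(lesioned) == 1
        assert lesioned.homing_hr.iloc[0] >= 30.0

    def test_reference_run_never_spawns_lesioned(self):
        res = run_simulation(
            SimulationParams(seed=4, n_steps=8000),
            record_clone_series=False, occupancy_stride=0,
        )
        assert not res.forest.founders.lesioned.any()


class TestDepartures:
    def test_exit_requires_exit_bound_and_boundary(self, domain):
        pos = np.array([[0.0, -(domain.radius + 0.1), 2.5],
                        [0.0, -10.0, 2.5]])
        eb = np.array([True, True])
        mask = exit_mask(pos, eb, domain)
        assert mask[0] and not mask[1]
        eb = np.array([False, False])
        assert not exit_mask(pos, eb, domain).any()

    def test_death_below_radius_floor(self):
        radii = np.array([0.9, 1.5])
        apop = np.array([True, True])
        mask = death_mask(radii, apop, 1.0)
        assert mask[0] and not mask[1]
        assert not death_mask(radii, np.array([False, False]), 1.0).any()

    def test_population_balance_over_homeostatic_window(self):
        res = run_simulation(SimulationParams(seed=9, n_steps=30_000),
                             record_clone_series=False, occupancy_stride=0)
        ev = res.events
        window = ev[ev.time_hr >= 60.0]
        arrivals = (window.event == "spawn").sum() + (
            window.event == "divide"
        ).sum()
        departures = (window.event == "exit").sum() + (
            window.event == "die"
        ).sum()
        assert departures == pytest.approx(arrivals, rel=0.35)
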