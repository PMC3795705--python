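"""Phantom generator: blood kinetics, diffusion solver, rendering, cohorts."""

import numpy as np
import pytest
from dataclasses import replace

from discdiff.phantom import (DEFAULT_TIME_POINTS, DiscSpec, KineticsParams,
                              PhantomConfig, blood_peak_time, generate_cohort,
                              render_series, simulate_blood_curve,
                              solve_disc_diffusion)

from oracles import slab_series


class TestBloodCurve:
    def test_zero_amplitude_gives_zeros(self):
        p = KineticsParams(blood_amplitude=0.0)
        assert np.all(simulate_blood_curve(p, [0, 1, 5, 360]) == 0.0)

    def test_zero_at_injection(self):
        p = KineticsParams(blood_amplitude=3.0, uptake_time=2.0,
                           decay_time=90.0)
        assert simulate_blood_curve(p, [0.0])[0] == 0.0

    def test_sampled_peak_matches_closed_form(self):
        p = KineticsParams()
        grid = np.arange(0.0, 30.0, 0.1)
        sampled = grid[np.argmax(simulate_blood_curve(p, grid))]
        assert abs(sampled - blood_peak_time(p)) < 0.1

    def test_default_peak_before_first_acquisition_and_near_zero_at_end(self):
        p = KineticsParams()
        assert blood_peak_time(p) < 5.0
        c = simulate_blood_curve(p, DEFAULT_TIME_POINTS)
        assert 0.0 < c[-1] < 0.1 * c.max()
        # strictly decreasing over the five post-contrast samples
        assert np.all(np.diff(c[1:]) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            KineticsParams(uptake_time=10.0, decay_time=5.0)
        with pytest.raises(ValueError):
            simulate_blood_curve(KineticsParams(), [-1.0])


class TestDiffusionSolver:
    def test_sealed_boundaries_stay_empty(self):
        p = KineticsParams(endplate_permeability=0.0, perfusion_rate=0.0)
        sol = solve_disc_diffusion(10.0, p, DEFAULT_TIME_POINTS)
        assert np.all(sol.c == 0.0)

    def test_perfusion_equilibrium_reaches_boundary_value(self):
        # strong perfusion with a constant driving concentration
        p = KineticsParams(endplate_permeability=0.0, perfusion_rate=0.5)
        sol = solve_disc_diffusion(
            10.0, p, [0, 60, 240], boundary_concentration=lambda t: 2.0)
        assert np.allclose(sol.c[-1], 2.0, atol=1e-6)

    def test_dirichlet_matches_analytic_slab_series(self):
        D, h, c0 = 0.03, 10.0, 5.0
        p = KineticsParams(diffusivity=D, perfusion_rate=0.0)
        sol = solve_disc_diffusion(
            h, p, [0, 30, 120, 300], n_nodes=201, dt=0.05,
            boundary="dirichlet", boundary_concentration=lambda t: c0)
        for k, t in enumerate([30.0, 120.0, 300.0], start=1):
            exact = slab_series(sol.x, t, h, D, c0, n_terms=80)
            assert np.max(np.abs(sol.c[k] - exact)) < 1e-3 * c0

    def test_symmetry_about_midplane(self):
        p = KineticsParams()
        sol = solve_disc_diffusion(8.0, p, DEFAULT_TIME_POINTS, n_nodes=81)
        assert np.max(np.abs(sol.c - sol.c[:, ::-1])) < 1e-10

    @pytest.mark.parametrize("draw", range(8))
    def test_maximum_principle_on_random_parameters(self, draw):
        rng = np.random.default_rng(100 + draw)
        p = KineticsParams(
            blood_amplitude=rng.uniform(0.5, 3.0),
            diffusivity=rng.uniform(0.005, 0.08),
            endplate_permeability=rng.uniform(0.0, 0.1),
            perfusion_rate=rng.uniform(0.0, 0.02),
        )
        h = rng.uniform(4.0, 14.0)
        sol = solve_disc_diffusion(h, p, DEFAULT_TIME_POINTS)
        cb = simulate_blood_curve(p, np.arange(0, 361.0, 0.5))
        assert sol.c.min() >= -1e-9
        assert sol.c.max() <= cb.max() + 1e-9

    def test_central_band_near_zero_at_early_time_points(self):
        sol = solve_disc_diffusion(10.0, KineticsParams(), DEFAULT_TIME_POINTS)
        late = sol.band_mean(0.4, 0.6, 5)
        for k in (1, 2):  # 5 and 10 minutes
            assert sol.band_mean(0.4, 0.6, k) < 0.02 * late

    def test_grid_refinement_convergence(self):
        p = KineticsParams()
        coarse = solve_disc_diffusion(10.0, p, [0, 120, 360], n_nodes=101)
        fine = solve_disc_diffusion(10.0, p, [0, 120, 360], n_nodes=201)
        ref = np.interp(coarse.x, fine.x, fine.c[-1])
        rel = np.max(np.abs(coarse.c[-1] - ref)) / fine.c[-1].max()
        assert rel < 1e-3

    def test_explicit_scheme_rejects_unstable_step(self):
        p = KineticsParams(diffusivity=0.05)
        with pytest.raises(ValueError, match="unstable"):
            solve_disc_diffusion(5.0, p, [0, 60], n_nodes=201, dt=0.5,
                                 scheme="explicit")

    def test_explicit_and_crank_nicolson_agree(self):
        p = KineticsParams()
        cn = solve_disc_diffusion(10.0, p, [0, 120], n_nodes=41, dt=0.5)
        ex = solve_disc_diffusion(10.0, p, [0, 120], n_nodes=41, dt=0.05,
                                  scheme="explicit")
        assert np.max(np.abs(cn.c[-1] - ex.c[-1])) < 1e-3 * max(
            ex.c[-1].max(), 1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            solve_disc_diffusion(-1.0, KineticsParams(), [0, 5])
        with pytest.raises(ValueError):
            solve_disc_diffusion(10.0, KineticsParams(), [0, 5], n_nodes=2)


class TestRendering:
    def _render_default(self, config):
        spec = DiscSpec()
        params = config.kinetics
        field = solve_disc_diffusion(spec, params, config.time_points,
                                     n_nodes=config.n_nodes, dt=config.dt)
        cfg = replace(config, discs=(spec,))
        series, truth = render_series(cfg, {"d0": field}, params)
        return series["d0"], truth["d0"]

    def test_no_agent_no_noise_post_equals_pre(self, quiet_config):
        cfg = replace(quiet_config,
                      kinetics=KineticsParams(blood_amplitude=0.0))
        series, _ = self._render_default(cfg)
        for label, img in series.images.items():
            np.testing.assert_array_equal(img, series.images["PRE"])

    def test_scb_region_tracks_blood_curve(self, quiet_config):
        series, truth = self._render_default(quiet_config)
        cb = simulate_blood_curve(truth.params, quiet_config.time_points)
        scb = truth.masks["SCB_upper"] | truth.masks["SCB_lower"]
        pre = series.images["PRE"]
        for k, label in enumerate(series.labels):
            diff = (series.images[label] - pre)[scb].mean()
            assert diff == pytest.approx(truth.params.signal_gain * cb[k],
                                         abs=1e-6)

    def test_t2_brightness_monotone_in_hydration(self, quiet_config):
        out = {}
        for w in (0.3, 1.0):
            spec = DiscSpec(hydration=w)
            field = solve_disc_diffusion(spec, quiet_config.kinetics,
                                         quiet_config.time_points)
            cfg = replace(quiet_config, discs=(spec,))
            series, truth = render_series(cfg, {"d0": field},
                                          quiet_config.kinetics)
            disc = np.zeros_like(truth["d0"].masks["Central"])
            for lab in ("Central", "Peripheral_upper", "Peripheral_lower"):
                disc |= truth["d0"].masks[lab]
            out[w] = series["d0"].t2[disc].mean()
        assert out[1.0] > out[0.3]


class TestCohortGeneration:
    def test_same_seed_is_bit_identical(self):
        cfg = PhantomConfig()
        a = generate_cohort(cfg, 5, seed=42)
        b = generate_cohort(cfg, 5, seed=42)
        assert a.metadata.equals(b.metadata)
        for d in a.disc_ids:
            for label in a.series[d].images:
                np.testing.assert_array_equal(a.series[d].images[label],
                                              b.series[d].images[label])
            np.testing.assert_array_equal(a.landmarks[d].upper,
                                          b.landmarks[d].upper)

    def test_reference_grade_frequencies_exact(self):
        cfg = PhantomConfig()
        cohort = generate_cohort(cfg, 214, seed=0,
                                 grade_counts=(50, 43, 58, 48, 15))
        hist = cohort.metadata["pfirrmann"].value_counts().sort_index()
        assert hist.tolist() == [50, 43, 58, 48, 15]

    def test_uniform_height_support(self):
        cfg = PhantomConfig()
        cohort = generate_cohort(cfg, 60, seed=3,
                                 height_distribution="uniform",
                                 height_range=(5.0, 14.0))
        h = cohort.metadata["height_mm"]
        assert h.min() >= 5.0 and h.max() <= 14.0

    def test_metadata_has_grouping_variables(self, fixture_cohort):
        cols = set(fixture_cohort.metadata.columns)
        assert {"pfirrmann", "mc_upper", "mc_lower", "defect_upper",
                "defect_lower", "irregular", "age", "height_mm",
                "spondylolisthesis"} <= cols

    def test_fixture_mc_disc_has_perfusion(self, fixture_cohort):
        meta = fixture_cohort.metadata
        mc = meta[(meta["mc_upper"] != "0") | (meta["mc_lower"] != "0")]
        assert len(mc) == 1
        assert (mc["true_perfusion"] > 0).all()
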