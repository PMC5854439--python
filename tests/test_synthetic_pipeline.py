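"""Generator contracts and pipeline plumbing (config validation, CLI)."""

import json

import numpy as np
import pytest

from basketmap.basket import basket_with_density, place_basket
from basketmap.phase_mapping import PhaseMovie
from basketmap.pipeline import basket_placements, ground_truth, \
    map_with_basket, validate_config
from basketmap.ps_detection import detect_ps, wrap_angle
from basketmap.synthetic_data import analytic_vortex_movie, \
    limit_cycle_states, make_aliasing_fixture, make_farfield_masks


class TestVortexGenerator:
    def test_single_positive_charge_every_frame(self):
        vx = analytic_vortex_movie(centers=((10.4, 10.3),),
                                   duration_ms=100.0, grid_mm=(20.0, 20.0))
        det = detect_ps(vx.movie, vx.elements, vx.node_xy)
        assert (det.charge == 1).all()
        counts = np.bincount(det.frame_idx,
                             minlength=len(vx.movie.frame_times))
        assert (counts == 1).all()

    def test_omega_sign_flips_nothing_spatial(self):
        a = analytic_vortex_movie(omega=2 * np.pi * 8, duration_ms=5.0,
                                  grid_mm=(20.0, 20.0),
                                  centers=((10.0, 10.0),))
        b = analytic_vortex_movie(omega=-2 * np.pi * 8, duration_ms=5.0,
                                  grid_mm=(20.0, 20.0),
                                  centers=((10.0, 10.0),))
        assert np.allclose(a.movie.phase[0], b.movie.phase[0])

    def test_opposite_pair_nets_zero(self):
        vx = analytic_vortex_movie(centers=((6.3, 10.2), (14.4, 10.3)),
                                   charges=(1, -1), duration_ms=3.0,
                                   grid_mm=(20.0, 20.0))
        det = detect_ps(vx.movie, vx.elements, vx.node_xy)
        per_frame = np.zeros(len(vx.movie.frame_times), dtype=int)
        np.add.at(per_frame, det.frame_idx, det.charge)
        assert (per_frame == 0).all()
        assert len(det.frame_idx) == 2 * len(vx.movie.frame_times)

    def test_zero_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            analytic_vortex_movie(omega=0.0)


class TestAliasingFixture:
    def test_deterministic(self):
        geo = basket_with_density(8, 8)
        a = make_aliasing_fixture(geo)
        b = make_aliasing_fixture(geo)
        assert np.array_equal(a.traces, b.traces)

    def test_underlying_field_has_no_ps(self):
        # the continuous wave sampled densely: a smooth traveling wave with
        # no amplitude zeros, hence no winding anywhere
        geo = basket_with_density(16, 16)
        n = 80
        lon = np.linspace(0, 2 * np.pi, n, endpoint=False)
        lat = np.linspace(-16.8, 16.8, n)
        gl, gt_ = np.meshgrid(lon, lat, indexing="ij")
        k0 = 2 * np.pi / 9.6
        phi = k0 * gt_.ravel() * (1 + 0.4 * np.cos(gl.ravel()))
        t = np.arange(300.0)
        theta = wrap_angle(2 * np.pi * 8.5 * t[:, None] / 1000.0
                           - phi[None, :])
        iy, ix = np.mgrid[0:n - 1, 0:n - 1]
        p00 = iy * n + ix
        els = np.stack([p00, p00 + 1, p00 + n + 1, p00 + n],
                       axis=-1).reshape(-1, 4)
        movie = PhaseMovie(frame_times=t, phase=theta)
        xy = np.column_stack([gl.ravel(), gt_.ravel()])
        det = detect_ps(movie, els, xy)
        assert len(det.frame_idx) == 0


class TestScenarioGenerators:
    def test_mini_scenario_deterministic(self):
        from basketmap.tissue_sim import build_domain, run_scenario
        from basketmap.synthetic_data import _pinwheel_states
        runs = []
        for _ in range(2):
            d = build_domain("annulus", (12.0, 12.0), dx=0.6,
                             condition="cAF", diffusivity=0.1,
                             holes=[(6.0, 6.0, 2.0)])
            states = _pinwheel_states(d, (6.0, 6.0), "RA_PM", "cAF")
            movie, _ = run_scenario(d, [], duration=60.0, dt=0.02,
                                    states=states)
            runs.append(movie.frames)
        assert np.array_equal(runs[0], runs[1])

    def test_limit_cycle_covers_action_potential(self):
        cyc = limit_cycle_states("RA_PM", "cAF")
        vm = cyc[:, 0]
        assert vm.max() > 0.0 and vm.min() < -75.0

    def test_masks_nested_and_identity(self, standard_scenario,
                                       scenario_sources):
        masks = make_farfield_masks(standard_scenario)
        assert set(masks) == {"all", "rotor_and_reentry", "rotor_core"}
        assert np.all(np.isin(masks["rotor_core"],
                              masks["rotor_and_reentry"]))
        same = scenario_sources.masked(masks["all"])
        assert np.array_equal(same.values, scenario_sources.values)

    def test_rotor_only_mask_silences_distant_electrodes(
            self, standard_scenario, scenario_sources):
        from basketmap.forward_egm import egm_at_points
        masks = make_farfield_masks(standard_scenario)
        core = scenario_sources.masked(masks["rotor_core"])
        # near-contact electrode over the (now silenced) pacing corner
        pts = np.array([[46.0, 4.0, 1.0]])
        full = egm_at_points(scenario_sources, pts).v_rms()[0]
        masked = egm_at_points(core, pts).v_rms()[0]
        assert full > 10.0 * masked

    def test_pacing_only_has_no_sustained_ps(self, pacing_only_scenario):
        gt = ground_truth(pacing_only_scenario)
        assert gt.rotor_tracks == []


class TestPipelinePlumbing:
    def test_missing_sections_rejected_before_compute(self):
        with pytest.raises(ValueError, match="basket"):
            validate_config({"scenario": {"name": "standard"}})
        with pytest.raises(ValueError, match="scenario"):
            validate_config({"basket": {"densities": [[8, 8]]}})
        with pytest.raises(ValueError, match="densities"):
            validate_config({"scenario": {"name": "standard"},
                             "basket": {"densities": []}})
        with pytest.raises(ValueError, match="unknown scenario"):
            validate_config({"scenario": {"name": "torso"},
                             "basket": {"densities": [[8, 8]]}})

    def test_defaults_filled(self):
        cfg = validate_config({"scenario": {"name": "standard"},
                               "basket": {"densities": [[8, 8]]}})
        assert cfg["trim_ms"] == 500.0
        assert tuple(cfg["grid_points"]) == (240, 240)

    def test_pacing_only_mapping_yields_no_true_rotor(
            self, pacing_only_scenario):
        gt = ground_truth(pacing_only_scenario)
        pls = basket_placements(pacing_only_scenario)
        geo = basket_with_density(8, 8)
        geo = place_basket(geo, pls["near"]["center"],
                           pls["near"]["orientation"])
        res = map_with_basket(pacing_only_scenario, geo, gt=gt)
        assert res.report.label_percent["TRUE_ROTOR"] == 0.0
        assert all(c.label in ("IMPS", "FIPS") for c in res.classified)


class TestCli:
    def test_generate_writes_bundle(self, tmp_path):
        import h5py
        from click.testing import CliRunner
        from basketmap.cli import main
        out = tmp_path / "bundle.h5"
        result = CliRunner().invoke(
            main, ["generate", "--scenario", "pacing_only",
                   "--duration-ms", "80", "--out", str(out)])
        assert result.exit_code == 0, result.output
        with h5py.File(out) as fh:
            assert "vm_movie/frames" in fh
            assert "scenario_yaml" in fh.attrs

    def test_run_rejects_bad_config(self, tmp_path):
        from click.testing import CliRunner
        from basketmap.cli import main
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("scenario:\n  name: standard\n")
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg), "--out", str(tmp_path)])
        assert result.exit_code != 0

    def test_compare_merges_reports(self, tmp_path):
        from click.testing import CliRunner
        from basketmap.cli import main
        for name, pct in (("a", 50.0), ("b", 25.0)):
            (tmp_path / f"report_{name}.json").write_text(json.dumps(
                {"label_percent": {"TRUE_ROTOR": pct, "IMPS": 0.0,
                                   "FIPS": 0.0}}))
        out = tmp_path / "table.csv"
        result = CliRunner().invoke(
            main, ["compare", str(tmp_path / "report_a.json"),
                   str(tmp_path / "report_b.json"), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert "50.0" in out.read_text()
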