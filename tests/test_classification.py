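"""Classification tests: circular-monotonicity scoring, labelling,
percentages, coverage, trajectory distances."""

import itertools

import numpy as np
import pytest

from basketmap.basket import build_basket, place_basket, distance_map
from basketmap.classification_metrics import _circularly_sequential, \
    _project_to_plane, activation_sequence_score, classify_tracks, \
    coverage_metrics, detection_percentages, trajectory_distance, \
    ClassifiedTrack
from basketmap.forward_egm import EgmSet
from basketmap.ps_detection import PsTrack


def _track(xy, times=None, charge=1, rotations=5.0):
    xy = np.atleast_2d(xy)
    if len(xy) == 1:
        xy = np.repeat(xy, 100, axis=0)
    if times is None:
        times = np.arange(float(len(xy)))
    return PsTrack(frame_idx=np.arange(len(xy)), times=np.asarray(times),
                   xy=xy, charge=charge,
                   element_ids=np.zeros(len(xy)), rotations=rotations)


def _rotating_egms(geometry, cycle_ms=125.0, n_ms=2000, phase_fn=None,
                   center_chart=(0.0, 0.0)):
    """EGMs whose activation sweeps circularly around a chart point."""
    r = geometry.radius
    lon = np.repeat(geometry.longitudes(), geometry.electrodes_per_spline)
    lat = np.tile(geometry.arc_latitudes(), geometry.n_splines)
    dx = r * np.angle(np.exp(1j * (lon - center_chart[0] / r)))
    ang = np.arctan2(lat - center_chart[1], dx)
    t = np.arange(float(n_ms))
    offsets = phase_fn(ang) if phase_fn else ang
    traces = np.cos(2 * np.pi * t[:, None] / cycle_ms - offsets[None, :])
    return EgmSet(electrode_ids=geometry.electrode_ids,
                  electrode_coords=geometry.coords_flat,
                  traces=traces, frame_times=t)


class TestCircularSequence:
    QUAD_ANGLES = np.deg2rad([45.0, 135.0, -135.0, -45.0])

    def test_exact_null_fraction_for_four_electrodes(self):
        # brute-force all 24 orderings: exactly 8 (4 rotations x 2
        # directions) are circularly monotone -> chance level 1/3
        good = sum(_circularly_sequential(self.QUAD_ANGLES,
                                          np.array(perm, dtype=float))
                   for perm in itertools.permutations(range(4)))
        assert good == 8

    def test_random_orderings_score_near_chance(self, rng):
        hits = sum(_circularly_sequential(
            self.QUAD_ANGLES, rng.permutation(4).astype(float))
            for _ in range(600))
        assert 0.25 < hits / 600 < 0.42

    def test_undefined_below_three_finite_times(self):
        t = np.array([0.0, 1.0, np.nan, np.nan])
        assert not _circularly_sequential(self.QUAD_ANGLES, t)

    def test_perfect_rotation_scores_one(self):
        geo = build_basket(4, 2, 31.0, 4.8)
        ps = np.array([geo.radius * np.pi / 4.0, 0.0])  # mid-cell point
        egm = _rotating_egms(geo, center_chart=ps)
        score, ids, undefined = activation_sequence_score(
            ps, geo, egm, cycle_length=125.0, t_start=200.0, t_end=1800.0)
        assert not undefined
        assert score == 1.0
        assert len(ids) == 4

    def test_scrambled_activation_scores_low(self, rng):
        geo = build_basket(4, 2, 31.0, 4.8)
        ps = np.array([geo.radius * np.pi / 4.0, 0.0])
        # half-cycle offsets on diagonally opposite electrodes make the
        # activation order alternate around the ring: never monotone
        egm = _rotating_egms(geo, center_chart=ps,
                             phase_fn=lambda a: np.pi *
                             ((np.cos(a) * np.sin(a)) > 0))
        score, _, undefined = activation_sequence_score(
            ps, geo, egm, cycle_length=125.0, t_start=200.0, t_end=1800.0)
        assert undefined or score < 0.5


class TestClassifyTracks:
    def _near_geometry(self):
        geo = build_basket(8, 8, 31.0, 4.8)
        return place_basket(geo, (20.0, 28.0, 16.0), (1, 0, 0))

    def _chart_point_over(self, geo, target):
        # chart point whose center-ray projection lands nearest the target
        # (only rays that actually reach the tissue plane qualify)
        xs = np.linspace(0, 2 * np.pi * geo.radius, 200, endpoint=False)
        ys = np.linspace(geo.arc_latitudes()[0], geo.arc_latitudes()[-1], 50)
        gx, gy = np.meshgrid(xs, ys)
        world = geo.chart_to_world(gx.ravel(), gy.ravel())
        proj = _project_to_plane(world, geo.center)
        d = np.linalg.norm(proj[:, :2] - np.asarray(target), axis=1)
        d[proj[:, 2] != 0.0] = np.inf
        k = int(np.argmin(d))
        return np.array([gx.ravel()[k], gy.ravel()[k]])

    def test_track_over_tissue_ps_is_true_rotor(self, rng):
        geo = self._near_geometry()
        gt = _track((20.0, 28.0))
        chart = self._chart_point_over(geo, (20.0, 28.0))
        basket_track = _track(chart)
        egm = _rotating_egms(geo)
        (ct,) = classify_tracks([basket_track], [gt], geo, egm)
        assert ct.label == "TRUE_ROTOR"
        assert ct.match_distance < 10.0

    def test_unmatched_sequential_track_is_imps(self):
        geo = self._near_geometry()
        gt = _track((20.0, 28.0))
        chart = self._chart_point_over(geo, (20.0, 28.0))
        far_chart = chart + np.array([geo.radius * np.pi, 0.0])
        egm = _rotating_egms(geo, cycle_ms=125.0)
        tr = _track(far_chart, times=np.arange(500.0, 2000.0))
        tr.frame_idx = np.arange(500, 2000)
        (ct,) = classify_tracks([tr], [gt], geo, egm, default_cycle_ms=125.0)
        assert ct.label in ("IMPS", "FIPS")
        assert ct.match_distance > 10.0

    def test_empty_ground_truth_never_true(self, rng):
        geo = self._near_geometry()
        egm = _rotating_egms(geo)
        tr = _track(self._chart_point_over(geo, (20.0, 28.0)))
        (ct,) = classify_tracks([tr], [], geo, egm)
        assert ct.label in ("IMPS", "FIPS")

    def test_true_rotor_fraction_monotone_in_match_threshold(self):
        geo = self._near_geometry()
        gt = _track((20.0, 28.0))
        egm = _rotating_egms(geo)
        offsets = (0.0, 3.0, 8.0, 15.0)
        tracks = [_track(self._chart_point_over(geo, (20.0 + o, 28.0)))
                  for o in offsets]
        counts = []
        for thr in (20.0, 10.0, 5.0, 1.0):
            cls = classify_tracks(tracks, [gt], geo, egm,
                                  match_threshold=thr)
            counts.append(sum(c.label == "TRUE_ROTOR" for c in cls))
        assert counts == sorted(counts, reverse=True)

    def test_labels_exhaustive_and_exclusive(self):
        geo = self._near_geometry()
        egm = _rotating_egms(geo)
        tracks = [_track(self._chart_point_over(geo, (20.0 + o, 28.0 - o)))
                  for o in (0.0, 6.0, 14.0)]
        cls = classify_tracks(tracks, [_track((20.0, 28.0))], geo, egm)
        assert len(cls) == len(tracks)
        assert all(c.label in ("TRUE_ROTOR", "IMPS", "FIPS") for c in cls)


class TestReportMetrics:
    def test_full_window_track_is_100_percent(self):
        times = np.arange(100.0)
        ct = ClassifiedTrack(track=_track((0.0, 0.0)), label="TRUE_ROTOR")
        pct = detection_percentages([ct], times)
        assert pct["TRUE_ROTOR"] == 100.0
        assert pct["FIPS"] == 0.0

    def test_no_tracks_zero_percent(self):
        pct = detection_percentages([], np.arange(50.0))
        assert set(pct.values()) == {0.0}

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detection_percentages([], np.arange(50.0), window=(90.0, 95.0))

    def test_coverage_matches_brute_force(self, rng):
        geo = build_basket(8, 8)
        tissue = rng.uniform(-25, 25, size=(800, 3))
        dm = distance_map(geo, tissue)
        cov = coverage_metrics(dm, tissue[:, :2], None)
        d = np.min(np.linalg.norm(
            geo.coords_flat[None, :, :] - tissue[:, None, :], axis=2),
            axis=1)
        assert cov["tissue_near_pct"] == pytest.approx(
            100.0 * np.mean(d <= 5.0))
        assert cov["tissue_mid_pct"] == pytest.approx(
            100.0 * np.mean((d > 5.0) & (d <= 10.0)))

    def test_coverage_all_near_and_none(self):
        geo = build_basket(8, 8)
        shell = geo.coords_flat * (19.0 / 15.5)  # 3.5 mm outside
        cov = coverage_metrics(distance_map(geo, shell), shell[:, :2], None)
        assert cov["tissue_near_pct"] == 100.0
        far = geo.coords_flat * 4.0   # > 10 mm away everywhere
        cov2 = coverage_metrics(distance_map(geo, far), far[:, :2], None)
        assert cov2["tissue_near_pct"] == 0.0
        assert cov2["tissue_mid_pct"] == 0.0

    def test_trajectory_distance_identical_zero(self):
        a = _track(np.column_stack([np.linspace(0, 5, 50),
                                    np.linspace(2, 7, 50)]))
        st = trajectory_distance(a, a)
        assert st["min_mm"] == st["median_mm"] == st["max_mm"] == 0.0

    def test_trajectory_distance_constant_offset(self):
        xy = np.column_stack([np.linspace(0, 5, 50), np.zeros(50)])
        a = _track(xy)
        b = _track(xy + np.array([3.0, 4.0]))
        st = trajectory_distance(a, b)
        assert st["median_mm"] == pytest.approx(5.0)

    def test_export_tables_roundtrip(self, tmp_path):
        import csv
        from basketmap.classification_metrics import classification_to_csv
        from basketmap.ps_detection import tracks_to_csv
        tracks = [_track((1.0, 2.0)), _track((5.0, 6.0), charge=-1)]
        cls = [ClassifiedTrack(track=tracks[0], label="TRUE_ROTOR",
                               match_distance=1.5, sequential_score=0.9),
               ClassifiedTrack(track=tracks[1], label="FIPS",
                               sequential_score=0.1)]
        cpath = tmp_path / "cls.csv"
        classification_to_csv(cls, cpath)
        rows = list(csv.DictReader(open(cpath)))
        assert [r["label"] for r in rows] == ["TRUE_ROTOR", "FIPS"]
        tpath = tmp_path / "trk.csv"
        tracks_to_csv(tracks, tpath)
        rows = list(csv.DictReader(open(tpath)))
        assert len(rows) == sum(len(t.times) for t in tracks)
        assert {r["track_id"] for r in rows} == {"0", "1"}

    def test_no_overlap_rejected(self):
        a = _track((0.0, 0.0), times=np.arange(0.0, 50.0))
        b = _track((0.0, 0.0), times=np.arange(100.0, 150.0))
        b.frame_idx = np.arange(100, 150)
        with pytest.raises(ValueError, match="overlap"):
            trajectory_distance(a, b)
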