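"""PS detection/tracking tests against analytic vortex oracles and the
discrete index-sum theorem."""

import numpy as np
import pytest

from basketmap.phase_mapping import PhaseMovie
from basketmap.ps_detection import PsTrack, anatomical_reentry_track, \
    count_rotations, detect_ps, filter_rotors, topological_charge, \
    track_ps, wrap_angle
from basketmap.synthetic_data import analytic_vortex_movie


def _boundary_winding(phase_grid):
    """Brute-force winding number along the outer boundary (CCW)."""
    top, bottom = phase_grid[-1, :], phase_grid[0, :]
    left, right = phase_grid[:, 0], phase_grid[:, -1]
    loop = np.concatenate([bottom, right[1:], top[::-1][1:], left[::-1][1:]])
    return int(np.round(wrap_angle(np.diff(loop)).sum() / (2 * np.pi)))


class TestTopologicalCharge:
    def test_ideal_vortex_center_element(self):
        vx = analytic_vortex_movie(centers=((10.4, 10.3),), charges=(1,),
                                   duration_ms=1.0, grid_mm=(20.0, 20.0))
        frame = vx.movie.phase[0]
        charges = np.array([topological_charge(frame, el)
                            for el in vx.elements])
        assert charges.sum() == 1
        hit = vx.elements[charges == 1][0]
        assert np.allclose(vx.node_xy[hit].mean(axis=0), (10.4, 10.3),
                           atol=vx.dx)

    def test_mirrored_vortex_flips_chirality(self):
        vx = analytic_vortex_movie(centers=((10.4, 10.3),), charges=(-1,),
                                   duration_ms=1.0, grid_mm=(20.0, 20.0))
        frame = vx.movie.phase[0]
        charges = [topological_charge(frame, el) for el in vx.elements]
        assert min(charges) == -1 and max(charges) == 0

    def test_small_element_rejected(self):
        with pytest.raises(ValueError):
            topological_charge(np.zeros(10), np.array([1, 2]))

    def test_nonfinite_node_skips_element(self):
        frame = np.array([0.0, np.nan, 1.0, 2.0])
        assert topological_charge(frame, np.array([0, 1, 2, 3])) == 0

    def test_index_sum_equals_boundary_winding_random_fields(self, rng):
        # 100 uniformly random phase fields: sum of interior element
        # charges must equal the boundary winding number exactly
        n = 12
        iy, ix = np.mgrid[0:n - 1, 0:n - 1]
        p00 = iy * n + ix
        elements = np.stack([p00, p00 + 1, p00 + n + 1, p00 + n],
                            axis=-1).reshape(-1, 4)
        for _ in range(100):
            field = rng.uniform(-np.pi, np.pi, (n, n))
            total = sum(topological_charge(field.ravel(), el)
                        for el in elements)
            assert total == _boundary_winding(field)

    def test_global_phase_offset_invariance(self):
        vx = analytic_vortex_movie(duration_ms=1.0, grid_mm=(20.0, 20.0),
                                   centers=((9.0, 11.0),))
        frame = vx.movie.phase[0]
        shifted = wrap_angle(frame + 1.2345)
        for el in vx.elements[::7]:
            assert topological_charge(frame, el) == \
                topological_charge(shifted, el)


class TestDetectAndTrack:
    def test_plane_wave_has_no_interior_ps(self):
        n = 21
        iy, ix = np.mgrid[0:n, 0:n]
        t = np.arange(50.0)
        theta = wrap_angle(2 * np.pi * 9 * t[:, None] / 1000.0
                           - 0.5 * ix.ravel()[None, :])
        movie = PhaseMovie(frame_times=t, phase=theta)
        iy2, ix2 = np.mgrid[0:n - 1, 0:n - 1]
        p00 = iy2 * n + ix2
        els = np.stack([p00, p00 + 1, p00 + n + 1, p00 + n],
                       axis=-1).reshape(-1, 4)
        xy = np.column_stack([ix.ravel(), iy.ravel()]).astype(float)
        det = detect_ps(movie, els, xy)
        assert len(det.frame_idx) == 0

    def test_stationary_vortex_single_full_track(self):
        vx = analytic_vortex_movie(centers=((10.4, 10.3),),
                                   duration_ms=500.0, grid_mm=(20.0, 20.0))
        det = detect_ps(vx.movie, vx.elements, vx.node_xy)
        tracks = track_ps(det, link_radius=2.0)
        assert len(tracks) == 1
        assert len(tracks[0].times) == len(vx.movie.frame_times)
        # location error below one element everywhere
        err = np.abs(tracks[0].xy - np.array([10.4, 10.3])).max()
        assert err < vx.dx

    def test_rotation_count_matches_omega(self):
        omega = 2 * np.pi * 8.0
        vx = analytic_vortex_movie(centers=((10.4, 10.3),), omega=omega,
                                   duration_ms=1000.0, grid_mm=(20.0, 20.0))
        det = detect_ps(vx.movie, vx.elements, vx.node_xy)
        (track,) = track_ps(det, link_radius=2.0)
        rot = count_rotations(track, vx.movie, vx.node_xy, probe_radius=3.0)
        assert rot == pytest.approx(8.0, abs=0.5)

    def test_two_distant_vortices_never_merge(self):
        vx = analytic_vortex_movie(centers=((8.3, 15.2), (31.6, 14.7)),
                                   charges=(1, -1), duration_ms=300.0,
                                   grid_mm=(40.0, 30.0))
        det = detect_ps(vx.movie, vx.elements, vx.node_xy)
        tracks = track_ps(det, link_radius=3.0)
        assert len(tracks) == 2
        assert {t.charge for t in tracks} == {1, -1}
        for t in tracks:
            assert np.ptp(t.xy[:, 0]) < 3.0

    def test_meandering_vortex_bbox(self):
        # center orbits a 5 mm circle: bbox must be ~10x10 mm (+-20%)
        t = np.arange(0.0, 800.0)
        cx = 15.2 + 5.0 * np.cos(2 * np.pi * t / 400.0)
        cy = 15.3 + 5.0 * np.sin(2 * np.pi * t / 400.0)
        n = 31
        iy, ix = np.mgrid[0:n, 0:n]
        x = ix.ravel().astype(float)
        y = iy.ravel().astype(float)
        theta = np.empty((len(t), n * n))
        for k in range(len(t)):
            theta[k] = np.arctan2(y - cy[k], x - cx[k]) \
                - 2 * np.pi * 8 * t[k] / 1000.0
        movie = PhaseMovie(frame_times=t, phase=wrap_angle(theta))
        iy2, ix2 = np.mgrid[0:n - 1, 0:n - 1]
        p00 = iy2 * n + ix2
        els = np.stack([p00, p00 + 1, p00 + n + 1, p00 + n],
                       axis=-1).reshape(-1, 4)
        det = detect_ps(movie, els, np.column_stack([x, y]))
        tracks = track_ps(det, link_radius=3.0, max_gap_frames=5)
        track = max(tracks, key=lambda tr: tr.duration)
        assert track.duration > 0.9 * (t[-1] - t[0])
        x0, x1, y0, y1 = track.meander_bbox
        assert (x1 - x0) == pytest.approx(10.0, rel=0.2)
        assert (y1 - y0) == pytest.approx(10.0, rel=0.2)

    def test_filter_rotors(self):
        short = PsTrack(frame_idx=np.arange(3), times=np.arange(3.0),
                        xy=np.zeros((3, 2)), charge=1,
                        element_ids=np.zeros(3), rotations=0.4)
        long = PsTrack(frame_idx=np.arange(900), times=np.arange(900.0),
                       xy=np.zeros((900, 2)), charge=1,
                       element_ids=np.zeros(900), rotations=8.2)
        assert filter_rotors([short, long]) == [long]
        assert filter_rotors([]) == []


class TestAnatomicalReentry:
    def test_ring_winding_recovers_hidden_charge(self):
        vx = analytic_vortex_movie(centers=((10.0, 10.0),),
                                   omega=2 * np.pi * 8.0,
                                   duration_ms=500.0, grid_mm=(20.0, 20.0))
        track = anatomical_reentry_track(vx.movie, vx.node_xy,
                                         (10.0, 10.0), ring_radius=4.0)
        assert track is not None
        assert track.charge == 1
        assert len(track.times) == len(vx.movie.frame_times)
        assert track.rotations == pytest.approx(4.0, abs=0.5)  # 8 Hz, 0.5 s

    def test_no_circulation_returns_none(self):
        t = np.arange(100.0)
        theta = wrap_angle(np.zeros((100, 121))
                           + 2 * np.pi * 8 * t[:, None] / 1000.0)
        movie = PhaseMovie(frame_times=t, phase=theta)
        iy, ix = np.mgrid[0:11, 0:11]
        xy = np.column_stack([ix.ravel(), iy.ravel()]).astype(float) * 2.0
        assert anatomical_reentry_track(movie, xy, (10.0, 10.0), 4.0) is None
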