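"""Phase-singularity detection and tracking.

A phase singularity (PS) is located by the discrete topological charge of
each mesh element: the sum of phase differences along the oriented element
boundary, each difference wrapped to (-pi, pi], is an exact multiple of
2*pi; elements with winding +-2*pi host a PS of that chirality.  Detections
are linked over time into trajectories by greedy same-charge
nearest-neighbor matching, and each trajectory's rotation count is taken
from the unwrapped phase of probe channels on a small ring around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phase_mapping import PhaseMovie

__all__ = ["PsDetections", "PsTrack", "topological_charge", "detect_ps",
           "track_ps", "count_rotations", "filter_rotors", "wrap_angle",
           "tracks_to_csv", "anatomical_reentry_track"]

TWO_PI = 2.0 * np.pi


def wrap_angle(d):
    """Wrap angle differences to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(d), TWO_PI)


def topological_charge(phase_frame: np.ndarray, element: np.ndarray) -> int:
    """Charge of one element: sign of the boundary winding, or 0.

    ``element`` lists node indices in boundary order (>= 3 nodes).
    Elements with non-finite phase on any node return 0 (skipped).
    """
    element = np.asarray(element)
    if element.size < 3:
        raise ValueError("element needs at least 3 nodes")
    theta = np.asarray(phase_frame)[element]
    if not np.all(np.isfinite(theta)):
        return 0
    d = wrap_angle(np.diff(np.append(theta, theta[0])))
    k = int(np.round(d.sum() / TWO_PI))
    return int(np.clip(k, -1, 1))


@dataclass
class PsDetections:
    """Flat table of per-frame PS detections on one mesh."""

    frame_idx: np.ndarray        # index into frame_times
    frame_times: np.ndarray      # ms, full movie time base
    element_id: np.ndarray
    xy: np.ndarray               # (k, 2) chart coordinates, mm
    charge: np.ndarray           # +-1
    n_skipped_elements: int = 0

    def in_frame(self, fi: int) -> np.ndarray:
        return np.nonzero(self.frame_idx == fi)[0]


@dataclass
class PsTrack:
    """A linked PS trajectory."""

    frame_idx: np.ndarray
    times: np.ndarray            # ms
    xy: np.ndarray               # (k, 2) mm
    charge: int
    element_ids: np.ndarray
    rotations: float = np.nan

    @property
    def birth(self) -> float:
        return float(self.times[0])

    @property
    def death(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.death - self.birth

    @property
    def mean_cycle_length(self) -> float:
        if not np.isfinite(self.rotations) or self.rotations <= 0:
            return np.nan
        return self.duration / self.rotations

    @property
    def meander_bbox(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the trajectory, mm."""
        return (float(self.xy[:, 0].min()), float(self.xy[:, 0].max()),
                float(self.xy[:, 1].min()), float(self.xy[:, 1].max()))

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)


def detect_ps(movie: PhaseMovie, elements: np.ndarray,
              node_xy: np.ndarray,
              centroids: np.ndarray | None = None) -> PsDetections:
    """All nonzero-charge elements in every frame.

    ``elements`` is (M, nv) node indices in boundary order (triangles or
    quads); ``node_xy`` gives the chart coordinates of each phase channel.
    ``centroids`` overrides the arithmetic element centroids (needed on
    periodic charts whose seam elements straddle the coordinate jump).
    """
    phase = movie.phase
    elements = np.asarray(elements)
    node_xy = np.asarray(node_xy)
    if centroids is None:
        centroids = node_xy[elements].mean(axis=1)

    fi_out, el_out, ch_out = [], [], []
    skipped = 0
    el_next = np.roll(elements, -1, axis=1)
    for fi in range(phase.shape[0]):
        theta = phase[fi]
        d = wrap_angle(theta[el_next] - theta[elements])
        s = d.sum(axis=1)
        finite = np.all(np.isfinite(theta[elements]), axis=1)
        skipped += int((~finite).sum())
        k = np.zeros(len(elements))
        k[finite] = np.round(s[finite] / TWO_PI)
        hit = np.nonzero(k != 0)[0]
        if len(hit):
            fi_out.append(np.full(len(hit), fi))
            el_out.append(hit)
            ch_out.append(np.clip(k[hit], -1, 1).astype(int))
    if fi_out:
        fi_arr = np.concatenate(fi_out)
        el_arr = np.concatenate(el_out)
        ch_arr = np.concatenate(ch_out)
    else:
        fi_arr = np.empty(0, dtype=int)
        el_arr = np.empty(0, dtype=int)
        ch_arr = np.empty(0, dtype=int)
    return PsDetections(frame_idx=fi_arr, frame_times=movie.frame_times,
                        element_id=el_arr, xy=centroids[el_arr],
                        charge=ch_arr, n_skipped_elements=skipped)


def track_ps(detections: PsDetections, link_radius: float,
             max_gap_frames: int = 2) -> list[PsTrack]:
    """Greedy same-charge nearest-neighbor linking into trajectories.

    In each frame, open tracks and new detections are matched in order of
    increasing distance; matches beyond ``link_radius`` (mm) are rejected
    and tracks unseen for more than ``max_gap_frames`` frames are closed.
    """
    tracks_done: list[dict] = []
    open_tracks: list[dict] = []
    n_frames = len(detections.frame_times)
    for fi in range(n_frames):
        idx = detections.in_frame(fi)
        cand = []
        for ti, tr in enumerate(open_tracks):
            for di in idx:
                if detections.charge[di] != tr["charge"]:
                    continue
                dist = np.hypot(*(detections.xy[di] - tr["xy"][-1]))
                if dist <= link_radius:
                    cand.append((dist, ti, di))
        cand.sort(key=lambda c: c[0])
        used_t, used_d = set(), set()
        for dist, ti, di in cand:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            tr["frame_idx"].append(fi)
            tr["xy"].append(detections.xy[di])
            tr["element_ids"].append(detections.element_id[di])
        for di in idx:
            if di not in used_d:
                open_tracks.append({
                    "frame_idx": [fi], "xy": [detections.xy[di]],
                    "element_ids": [detections.element_id[di]],
                    "charge": int(detections.charge[di])})
        still = []
        for tr in open_tracks:
            if fi - tr["frame_idx"][-1] > max_gap_frames:
                tracks_done.append(tr)
            else:
                still.append(tr)
        open_tracks = still
    tracks_done.extend(open_tracks)

    out = []
    for tr in tracks_done:
        fi_arr = np.array(tr["frame_idx"])
        out.append(PsTrack(frame_idx=fi_arr,
                           times=detections.frame_times[fi_arr],
                           xy=np.array(tr["xy"]), charge=tr["charge"],
                           element_ids=np.array(tr["element_ids"])))
    out.sort(key=lambda t: (t.birth, -t.duration))
    return out


def count_rotations(track: PsTrack, movie: PhaseMovie, node_xy: np.ndarray,
                    probe_radius: float) -> float:
    """Rotations executed over the track's lifetime.

    Phase at probe channels on a ring of ``probe_radius`` around the
    trajectory centroid is unwrapped over the track's time support; the
    median absolute total phase excursion across probes, divided by 2*pi,
    is the rotation count.  Robust to EGM morphology because it never looks
    for activation times.
    """
    center = track.centroid
    f0, f1 = int(track.frame_idx[0]), int(track.frame_idx[-1])
    if f1 <= f0:
        return 0.0
    node_xy = np.asarray(node_xy)
    turns = []
    for ang in (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi):
        probe = center + probe_radius * np.array([np.cos(ang), np.sin(ang)])
        p = int(np.argmin(((node_xy - probe) ** 2).sum(axis=1)))
        theta = movie.phase[f0:f1 + 1, p]
        if not np.all(np.isfinite(theta)):
            continue
        unwrapped = np.unwrap(theta)
        turns.append(abs(unwrapped[-1] - unwrapped[0]) / TWO_PI)
    if not turns:
        return 0.0
    rotations = float(np.median(turns))
    track.rotations = rotations
    return rotations


def filter_rotors(tracks: list[PsTrack], min_rotations: float = 1.0
                  ) -> list[PsTrack]:
    """Keep tracks that completed at least ``min_rotations`` full turns."""
    return [t for t in tracks
            if np.isfinite(t.rotations) and t.rotations >= min_rotations]


def tracks_to_csv(tracks: list[PsTrack], path,
                  to_world=None) -> None:
    """Flat CSV of all track points: frame_ms, x, y, z, charge, track_id.

    ``to_world`` optionally maps chart (x, y) arrays to (n, 3) world
    coordinates (e.g. ``BasketGeometry.chart_to_world``); without it z=0.
    """
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_ms", "x_mm", "y_mm", "z_mm", "charge",
                    "track_id"])
        for tid, tr in enumerate(tracks):
            if to_world is not None:
                world = to_world(tr.xy[:, 0], tr.xy[:, 1])
            else:
                world = np.column_stack([tr.xy, np.zeros(len(tr.xy))])
            for t, p in zip(tr.times, world):
                w.writerow([f"{t:.6g}", f"{p[0]:.6g}", f"{p[1]:.6g}",
                            f"{p[2]:.6g}", tr.charge, tid])


def anatomical_reentry_track(movie: PhaseMovie, node_xy: np.ndarray,
                             center: tuple[float, float], ring_radius: float,
                             n_probes: int = 24) -> PsTrack | None:
    """Ground-truth track for a reentry circulating a non-conducting hole.

    The topological charge of such a circuit sits inside the hole, where no
    tissue element can carry it; it is recovered as the winding number of
    phase along a ring of probe nodes just outside the hole.  Returns a
    track pinned at the hole center over the frames with winding +-1, or
    None if circulation is never seen.
    """
    node_xy = np.asarray(node_xy)
    ang = 2.0 * np.pi * np.arange(n_probes) / n_probes
    ring = np.column_stack([center[0] + ring_radius * np.cos(ang),
                            center[1] + ring_radius * np.sin(ang)])
    probes = np.array([int(np.argmin(((node_xy - p) ** 2).sum(axis=1)))
                       for p in ring])
    theta = movie.phase[:, probes]
    d = wrap_angle(np.diff(np.concatenate([theta, theta[:, :1]], axis=1),
                           axis=1))
    winding = np.round(d.sum(axis=1) / TWO_PI).astype(int)
    hit = np.nonzero(np.abs(winding) == 1)[0]
    if len(hit) == 0:
        return None
    charge = int(np.sign(winding[hit].sum())) or 1
    hit = hit[winding[hit] == charge]
    xy = np.tile(np.asarray(center, dtype=float), (len(hit), 1))
    track = PsTrack(frame_idx=hit, times=movie.frame_times[hit], xy=xy,
                    charge=charge, element_ids=np.full(len(hit), -1))
    # rotations from the unwrapped phase of one ring probe
    th = movie.phase[hit[0]:hit[-1] + 1, probes[0]]
    if np.all(np.isfinite(th)):
        track.rotations = abs(np.unwrap(th)[-1] - np.unwrap(th)[0]) / TWO_PI
    return track
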