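"""Classification of basket-map PS tracks and summary detection metrics.

A basket-detected PS trajectory is one of:

* ``TRUE_ROTOR`` — it shadows a ground-truth tissue PS (time-resolved
  distance, after projecting the basket PS through the basket center onto
  the tissue, below a match threshold);
* ``IMPS`` (imaginary PS) — no tissue counterpart, but the electrodes
  surrounding it activate *sequentially* around it cycle after cycle: the
  signature of a far-field-driven phantom;
* ``FIPS`` (false interpolation PS) — no tissue counterpart and
  non-sequential surrounding activation: an artifact of inter-electrode
  interpolation of spatially undersampled wavefronts.

"Sequential" is operationalized as circular monotonicity of the
surrounding electrodes' unipolar activation times (steepest negative
deflection per cycle): the activation order must be a rotation of the
geometric order around the PS, in either direction.  For 4 electrodes 8 of
the 24 orderings qualify, so the chance level of the per-cycle test is 1/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .basket import BasketGeometry, DistanceMap
from .forward_egm import EgmSet
from .ps_detection import PsTrack

__all__ = ["ClassifiedTrack", "DetectionReport", "activation_sequence_score",
           "classify_tracks", "classification_to_csv",
           "detection_percentages", "coverage_metrics",
           "trajectory_distance", "DEFAULT_MATCH_THRESHOLD",
           "DEFAULT_SEQ_THRESHOLD"]

DEFAULT_MATCH_THRESHOLD = 10.0   # mm
DEFAULT_SEQ_THRESHOLD = 0.8
LABELS = ("TRUE_ROTOR", "IMPS", "FIPS")


@dataclass
class ClassifiedTrack:
    track: PsTrack
    label: str
    match_distance: float = np.nan       # mm, median to nearest gt track
    sequential_score: float = np.nan
    surrounding_electrodes: list[str] = field(default_factory=list)
    score_undefined: bool = False


@dataclass
class DetectionReport:
    """Summary of one mapping run."""

    label_percent: dict                  # label -> % of window frames present
    coverage: dict | None = None
    trajectory_stats: dict | None = None # min/median/max mm
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"label_percent": self.label_percent,
                   "coverage": self.coverage,
                   "trajectory_stats": self.trajectory_stats,
                   "thresholds": self.thresholds}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def classification_to_csv(classified: list[ClassifiedTrack], path) -> None:
    """Per-track classification table."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "label", "birth_ms", "death_ms",
                    "rotations", "charge", "match_distance_mm",
                    "sequential_score", "surrounding_electrodes"])
        for tid, ct in enumerate(classified):
            tr = ct.track
            w.writerow([tid, ct.label, f"{tr.birth:.6g}",
                        f"{tr.death:.6g}", f"{tr.rotations:.4g}",
                        tr.charge, f"{ct.match_distance:.4g}",
                        f"{ct.sequential_score:.4g}",
                        " ".join(ct.surrounding_electrodes)])


def _project_to_plane(points: np.ndarray, center: np.ndarray,
                      plane_z: float = 0.0) -> np.ndarray:
    """Rays from the basket center through ``points``, intersected with the
    tissue plane z = plane_z; points whose ray never reaches the plane fall
    back to their own position."""
    points = np.atleast_2d(points)
    out = points.copy()
    dz = points[:, 2] - center[2]
    ok = np.abs(dz) > 1e-9
    t = np.where(ok, (plane_z - center[2]) / np.where(ok, dz, 1.0), np.nan)
    good = ok & (t > 0)
    out[good] = center + t[good, None] * (points[good] - center)
    return out


def _surrounding_cell(geometry: BasketGeometry, xy_chart: np.ndarray
                      ) -> list[int]:
    """Flat electrode indices of the lattice cell containing a chart point."""
    r = geometry.radius
    s, e = geometry.n_splines, geometry.electrodes_per_spline
    lat = geometry.arc_latitudes()
    phi = (xy_chart[0] / r) % (2 * np.pi)
    i0 = int(phi / (2 * np.pi / s)) % s
    j0 = int(np.clip(np.searchsorted(lat, xy_chart[1]) - 1, 0, e - 2))
    return [i0 * e + j0, ((i0 + 1) % s) * e + j0,
            ((i0 + 1) % s) * e + j0 + 1, i0 * e + j0 + 1]


def _activation_times(traces: np.ndarray, times: np.ndarray,
                      t0: float, t1: float) -> np.ndarray:
    """Steepest-negative-slope time per channel within [t0, t1); NaN for
    channels with no deflection there."""
    sel = (times >= t0) & (times < t1)
    if sel.sum() < 3:
        return np.full(traces.shape[1], np.nan)
    seg = traces[sel]
    tt = times[sel]
    dv = np.diff(seg, axis=0)
    k = np.argmin(dv, axis=0)
    out = 0.5 * (tt[k] + tt[k + 1])
    flat = dv.min(axis=0) > -1e-12
    out[flat] = np.nan
    return out


def _circularly_sequential(order_angles: np.ndarray,
                           act_times: np.ndarray) -> bool:
    """True when activation order is a rotation of the geometric circular
    order around the PS, clockwise or counterclockwise."""
    ok = np.isfinite(act_times)
    if ok.sum() < 3:
        return False
    ang = order_angles[ok]
    t = act_times[ok]
    geom_order = np.argsort(ang)          # CCW geometric order
    t_ring = t[geom_order]
    rank = np.argsort(np.argsort(t_ring))  # rank of each position by time
    n = len(rank)
    for direction in (1, -1):
        seq = rank[::direction]
        start = int(np.argmin(seq))
        rolled = np.roll(seq, -start)
        if np.array_equal(rolled, np.arange(n)):
            return True
    return False


def activation_sequence_score(ps_xy_chart: np.ndarray,
                              geometry: BasketGeometry,
                              egm_set: EgmSet,
                              cycle_length: float,
                              t_start: float, t_end: float
                              ) -> tuple[float, list[str], bool]:
    """Fraction of cycles in [t_start, t_end] whose surrounding-electrode
    activation order is circularly monotone around the PS.

    Returns (score, surrounding electrode ids, undefined_flag); the flag is
    set when fewer than 3 surrounding electrodes ever show activity, in
    which case the score is meaningless and callers should treat the track
    as interpolation-born.
    """
    cell = _surrounding_cell(geometry, np.asarray(ps_xy_chart))
    ids = [egm_set.electrode_ids[k] for k in cell]
    traces = egm_set.traces[:, cell]
    times = egm_set.frame_times

    r = geometry.radius
    lat = geometry.arc_latitudes()
    s, e = geometry.n_splines, geometry.electrodes_per_spline
    ang = []
    for k in cell:
        i, j = divmod(k, e)
        dx_ = np.angle(np.exp(1j * (2 * np.pi * i / s - ps_xy_chart[0] / r))) * r
        dy_ = lat[j] - ps_xy_chart[1]
        ang.append(np.arctan2(dy_, dx_))
    ang = np.asarray(ang)

    n_cycles = int((t_end - t_start) // cycle_length)
    if n_cycles < 1:
        return np.nan, ids, True
    good = 0
    counted = 0
    any_active = np.zeros(len(cell), dtype=bool)
    for c in range(n_cycles):
        t0 = t_start + c * cycle_length
        at = _activation_times(traces, times, t0, t0 + cycle_length)
        any_active |= np.isfinite(at)
        counted += 1
        if _circularly_sequential(ang, at):
            good += 1
    if any_active.sum() < 3:
        return np.nan, ids, True
    return good / counted, ids, False


def _track_world(track: PsTrack, geometry: BasketGeometry | None
                 ) -> np.ndarray:
    if geometry is None:
        return np.column_stack([track.xy, np.zeros(len(track.xy))])
    return geometry.chart_to_world(track.xy[:, 0], track.xy[:, 1])


def _pairwise_distance(track_a: PsTrack, track_b: PsTrack,
                       geometry_a: BasketGeometry | None,
                       geometry_b: BasketGeometry | None,
                       plane_z: float = 0.0) -> np.ndarray:
    """Per-frame distances over the temporal overlap (matched by time)."""
    ta = np.round(track_a.times, 6)
    tb = np.round(track_b.times, 6)
    common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
    if len(common) == 0:
        return np.empty(0)
    pa = _track_world(track_a, geometry_a)[ia]
    pb = _track_world(track_b, geometry_b)[ib]
    if geometry_a is not None:
        pa = _project_to_plane(pa, geometry_a.center, plane_z)
    if geometry_b is not None:
        pb = _project_to_plane(pb, geometry_b.center, plane_z)
    return np.linalg.norm(pa - pb, axis=1)


def classify_tracks(basket_tracks: list[PsTrack],
                    ground_truth_tracks: list[PsTrack],
                    geometry: BasketGeometry,
                    egm_set: EgmSet,
                    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
                    seq_threshold: float = DEFAULT_SEQ_THRESHOLD,
                    default_cycle_ms: float = 120.0,
                    plane_z: float = 0.0) -> list[ClassifiedTrack]:
    """Label every basket track TRUE_ROTOR / IMPS / FIPS.

    Ground truth comes from PS detection on the tissue-surface phase maps
    (the endocardial reference).  Matching uses the median time-resolved
    distance between the basket PS projected through the basket center onto
    the tissue plane and the tissue PS.
    """
    out = []
    for tr in basket_tracks:
        best = np.inf
        for gt in ground_truth_tracks:
            d = _pairwise_distance(tr, gt, geometry, None, plane_z)
            if len(d) >= max(1, len(tr.times) // 4):
                best = min(best, float(np.median(d)))
        if best <= match_threshold:
            out.append(ClassifiedTrack(track=tr, label="TRUE_ROTOR",
                                       match_distance=best))
            continue
        cl = tr.mean_cycle_length
        if not np.isfinite(cl) or cl <= 0:
            cl = default_cycle_ms
        score, ids, undefined = activation_sequence_score(
            tr.centroid, geometry, egm_set, cl, tr.birth, tr.death)
        if undefined:
            out.append(ClassifiedTrack(track=tr, label="FIPS",
                                       match_distance=best,
                                       sequential_score=np.nan,
                                       surrounding_electrodes=ids,
                                       score_undefined=True))
        elif score >= seq_threshold:
            out.append(ClassifiedTrack(track=tr, label="IMPS",
                                       match_distance=best,
                                       sequential_score=score,
                                       surrounding_electrodes=ids))
        else:
            out.append(ClassifiedTrack(track=tr, label="FIPS",
                                       match_distance=best,
                                       sequential_score=score,
                                       surrounding_electrodes=ids))
    return out


def detection_percentages(classified: list[ClassifiedTrack],
                          frame_times: np.ndarray,
                          window: tuple[float, float] | None = None) -> dict:
    """Percent of analysis-window frames with >= 1 track of each label."""
    frame_times = np.asarray(frame_times)
    if window is not None:
        sel = (frame_times >= window[0]) & (frame_times <= window[1])
    else:
        sel = np.ones(len(frame_times), dtype=bool)
    n_frames = int(sel.sum())
    if n_frames == 0:
        raise ValueError("empty analysis window")
    base_times = np.round(frame_times[sel], 6)
    out = {}
    for label in LABELS:
        present = np.zeros(n_frames, dtype=bool)
        for ct in classified:
            if ct.label != label:
                continue
            present |= np.isin(base_times, np.round(ct.track.times, 6))
        out[label] = 100.0 * present.mean()
    return out


def coverage_metrics(dmap: DistanceMap, tissue_xy: np.ndarray,
                     meander_bbox: tuple[float, float, float, float] | None
                     ) -> dict:
    """Tissue and rotor-meander coverage fractions by distance bucket.

    Coverage = percent of tissue nodes within d <= 5 mm (near) and
    5 < d <= 10 mm (mid) of at least one electrode; the meander variant
    restricts to nodes inside the ground-truth trajectory bounding box.
    """
    d = dmap.tissue_to_electrode
    out = {"tissue_near_pct": 100.0 * float(np.mean(d <= 5.0)),
           "tissue_mid_pct": 100.0 * float(np.mean((d > 5.0) & (d <= 10.0)))}
    if meander_bbox is None:
        out["meander_near_pct"] = None
        out["meander_mid_pct"] = None
        return out
    x0, x1, y0, y1 = meander_bbox
    xy = np.asarray(tissue_xy)
    sel = (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & \
          (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
    if not sel.any():
        out["meander_near_pct"] = None
        out["meander_mid_pct"] = None
        return out
    dm = d[sel]
    out["meander_near_pct"] = 100.0 * float(np.mean(dm <= 5.0))
    out["meander_mid_pct"] = 100.0 * float(np.mean((dm > 5.0) & (dm <= 10.0)))
    return out


def trajectory_distance(true_track: PsTrack, detected_track: PsTrack,
                        geometry: BasketGeometry | None = None,
                        plane_z: float = 0.0) -> dict:
    """min/median/max distance (mm) between the tissue trajectory and the
    basket-detected trajectory over their temporal overlap."""
    d = _pairwise_distance(detected_track, true_track, geometry, None,
                           plane_z)
    if len(d) == 0:
        raise ValueError("tracks have no temporal overlap")
    return {"min_mm": float(d.min()), "median_mm": float(np.median(d)),
            "max_mm": float(d.max()), "n_frames": int(len(d))}
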