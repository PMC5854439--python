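"""Instantaneous-phase computation for electrogram and Vm movies.

Pipeline: zero-phase 4th-order Butterworth band-pass (default 7–10 Hz,
matched to a ~8–9 Hz reentrant rhythm), frequency-domain Hilbert transform,
four-quadrant phase theta(t) = atan2(HT[x], x) in (-pi, pi], and trimming of
500 ms at each end where the filter and transform ring.

Phase convention: for a locally sinusoidal signal x ~ cos(omega t + phi0)
theta decreases through each cycle and wraps at -pi -> +pi; the sharp
negative deflection of a unipolar EGM (local activation) crosses theta = 0
from positive to negative.  Ground-truth tissue maps are computed by
feeding -Vm through the same pipeline so that activation (Vm upstroke =
downstroke of -Vm) carries the same phase signature as an EGM activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .forward_egm import EgmSet

__all__ = ["PhaseMovie", "bandpass", "hilbert_phase", "trim_edges",
           "phase_movie_from_traces", "DEFAULT_BAND", "DEFAULT_TRIM_MS"]

DEFAULT_BAND = (7.0, 10.0)   # Hz
DEFAULT_TRIM_MS = 500.0


@dataclass
class PhaseMovie:
    """Per-channel instantaneous phase over frames.

    ``phase`` has shape (n_frames, n_channels), values in (-pi, pi]; NaN
    columns mark channels whose phase was undefined (all-zero input).
    """

    frame_times: np.ndarray
    phase: np.ndarray
    provenance: str = "from_egm"        # or "from_vm_ground_truth"
    trimmed_ms: float = 0.0

    @property
    def cadence(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    def to_csv(self, path, channel_ids=None) -> None:
        """Per-channel phase table (small cases only)."""
        import csv
        n_ch = self.phase.shape[1]
        ids = channel_ids or [f"ch{i + 1:03d}" for i in range(n_ch)]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_ms"] + list(ids))
            for i, t in enumerate(self.frame_times):
                w.writerow([f"{t:.6g}"] +
                           [f"{v:.6g}" for v in self.phase[i]])

    def to_hdf5(self, path, group="phase_movie") -> None:
        import h5py
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in list(g):
                del g[name]
            g.create_dataset("frame_times", data=self.frame_times)
            g.create_dataset("phase", data=self.phase,
                             compression="gzip", compression_opts=1)
            g.attrs["provenance"] = self.provenance
            g.attrs["trimmed_ms"] = self.trimmed_ms


def _butter_sos(lo_hz: float, hi_hz: float, fs: float):
    return signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(egm_set: EgmSet, lo_hz: float = DEFAULT_BAND[0],
             hi_hz: float = DEFAULT_BAND[1]) -> EgmSet:
    """Zero-phase (forward–backward) band-pass filtering of all traces.

    Forward–backward application squares the magnitude response and cancels
    the group delay, so activation timing is not shifted.  DC is removed by
    construction of the band-pass.
    """
    fs = egm_set.sampling_rate_hz
    if fs < 4.0 * hi_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for hi={hi_hz} Hz")
    filtered = filter_traces(egm_set.traces, fs, lo_hz, hi_hz)
    return EgmSet(electrode_ids=egm_set.electrode_ids,
                  electrode_coords=egm_set.electrode_coords,
                  traces=filtered, frame_times=egm_set.frame_times,
                  source_mask=egm_set.source_mask)


def filter_traces(traces: np.ndarray, fs: float,
                  lo_hz: float = DEFAULT_BAND[0],
                  hi_hz: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Array-level zero-phase band-pass along axis 0."""
    traces = np.asarray(traces)
    sos = _butter_sos(lo_hz, hi_hz, fs)
    padlen = min(3 * 10 * 4, traces.shape[0] - 2)
    if traces.shape[0] < 3 * padlen // 2 + 2:
        raise ValueError("trace too short for the band-pass impulse response")
    x = traces.astype(np.float64) - traces.mean(axis=0, keepdims=True)
    return signal.sosfiltfilt(sos, x, axis=0).astype(traces.dtype)


def hilbert_phase(filtered: np.ndarray) -> np.ndarray:
    """Four-quadrant instantaneous phase of filtered, zero-mean signals.

    The analytic signal is built in the frequency domain over the full
    record; edge artefacts are the caller's business (see
    :func:`trim_edges`).  All-zero channels get NaN phase.
    """
    x = np.asarray(filtered, dtype=np.float64)
    analytic = signal.hilbert(x, axis=0)
    theta = np.arctan2(analytic.imag, analytic.real)
    dead = np.ptp(x, axis=0) == 0.0
    if np.ndim(theta) > 1:
        theta[:, dead] = np.nan
    elif dead:
        theta[:] = np.nan
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    theta[theta == -np.pi] = np.pi
    return theta


def trim_edges(movie: PhaseMovie, margin_ms: float = DEFAULT_TRIM_MS
               ) -> PhaseMovie:
    """Drop ``margin_ms`` from both ends (filter/Hilbert edge artefacts)."""
    if margin_ms == 0:
        return movie
    t = movie.frame_times
    span = t[-1] - t[0]
    if 2 * margin_ms >= span:
        raise ValueError(
            f"margin {margin_ms} ms exceeds half the record ({span} ms)")
    keep = (t >= t[0] + margin_ms) & (t <= t[-1] - margin_ms)
    return PhaseMovie(frame_times=t[keep], phase=movie.phase[keep],
                      provenance=movie.provenance,
                      trimmed_ms=movie.trimmed_ms + margin_ms)


def phase_movie_from_traces(traces: np.ndarray, frame_times: np.ndarray,
                            band: tuple[float, float] = DEFAULT_BAND,
                            trim_ms: float = DEFAULT_TRIM_MS,
                            provenance: str = "from_egm",
                            negate: bool = False) -> PhaseMovie:
    """Full pipeline: band-pass -> Hilbert phase -> edge trim.

    Set ``negate=True`` when feeding transmembrane potential so the ground
    truth shares the EGM activation-phase convention.
    """
    fs = 1000.0 / float(frame_times[1] - frame_times[0])
    x = np.asarray(traces)
    if x.ndim == 1:
        x = x[:, None]
    theta = np.empty(x.shape, dtype=np.float32)
    block = max(1, int(2.0e8 / (16 * x.shape[0])))  # cap transient memory
    for j0 in range(0, x.shape[1], block):
        seg = x[:, j0:j0 + block].astype(np.float64)
        if negate:
            seg = -seg
        theta[:, j0:j0 + block] = hilbert_phase(filter_traces(seg, fs, *band))
    movie = PhaseMovie(frame_times=np.asarray(frame_times), phase=theta,
                       provenance=provenance)
    return trim_edges(movie, trim_ms)
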