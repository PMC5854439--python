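"""Regional variants of the CRN human atrial action-potential model.

Nine regional cell types are defined by dimensionless multipliers on the
maximal conductances of I_to, I_CaL and I_Kr (control), composed with a
chronic-AF remodeling profile that additionally rescales I_K1, I_Kur and
I_Ks — differently for right-atrial and left-atrial regions.  Single-cell
pacing and action-potential-duration (APD) measurement live here too.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import crn_constants as C
from ._crn_kernels import crn_rhs, pace_cell

__all__ = [
    "MembraneModel", "PacingProtocol", "ApTrace",
    "build_membrane_model", "crn_derivatives", "pace_single_cell",
    "measure_apd", "initial_state", "NoActionPotentialError",
]

CONDITIONS = ("control", "cAF")


class NoActionPotentialError(ValueError):
    """Raised when a trace contains no action potential to measure."""


@dataclass(frozen=True)
class MembraneModel:
    """One regional CRN variant (control or chronic-AF remodeled)."""

    region_tag: str
    condition: str
    conductance_scalars: dict[str, float]
    membrane_capacitance: float = C.CM_PF
    state_dim: int = C.STATE_DIM

    def scalar_vector(self) -> np.ndarray:
        """Scalars in kernel order (g_to, g_CaL, g_Kr, g_K1, g_Kur, g_Ks)."""
        s = self.conductance_scalars
        return np.array([s["g_to"], s["g_CaL"], s["g_Kr"],
                         s["g_K1"], s["g_Kur"], s["g_Ks"]])

    def to_yaml(self, path: str | Path) -> None:
        """Flat key→value provenance dump."""
        import yaml
        payload = {
            "region_tag": self.region_tag,
            "condition": self.condition,
            "membrane_capacitance_pF": self.membrane_capacitance,
            "state_dim": self.state_dim,
        }
        payload.update({k: float(v) for k, v in self.conductance_scalars.items()})
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic stimulus train: ``n_beats`` pulses at basic cycle length
    ``bcl`` (ms), each ``stim_duration`` ms long at ``stim_amplitude``
    pA/pF (magnitude; applied as inward/depolarizing current).

    The default amplitude is the original CRN pacing pulse (2 nA over a
    100 pF cell = 20 pA/pF, 2 ms).  Stronger pulses excite just as reliably
    but keep charging the membrane past the sodium-driven peak, inflating
    the AP amplitude that peak-referenced APD thresholds are computed from
    and thereby biasing APD measurements low; tissue pacing, which faces an
    electrotonic load, uses a stronger pulse (see ``tissue_sim``).
    """

    bcl: float = 1000.0
    n_beats: int = 60
    stim_amplitude: float = 20.0
    stim_duration: float = 2.0

    def __post_init__(self):
        if self.stim_duration >= self.bcl:
            raise ValueError("stim_duration must be shorter than bcl")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class ApTrace:
    """A membrane-potential recording from a paced single cell."""

    times: np.ndarray          # ms, uniform
    vm: np.ndarray             # mV
    protocol: PacingProtocol = field(default_factory=PacingProtocol)

    def __post_init__(self):
        if len(self.times) != len(self.vm):
            raise ValueError("times and vm must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_ms", "vm_mV"])
            for t, v in zip(self.times, self.vm):
                w.writerow([f"{t:.6g}", f"{v:.6g}"])

    def to_hdf5(self, path: str | Path, group: str = "ap_trace") -> None:
        import h5py
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in ("times", "vm"):
                if name in g:
                    del g[name]
            g.create_dataset("times", data=self.times)
            g.create_dataset("vm", data=self.vm)
            g.attrs["bcl_ms"] = self.protocol.bcl


def build_membrane_model(region_tag: str, condition: str = "control") -> MembraneModel:
    """Compose the regional conductance scalars with the cAF remodeling.

    Control scalars rescale g_to, g_CaL, g_Kr per region; under ``cAF`` the
    remodeling multipliers (RA profile for right-atrial regions, LA profile
    for left-atrial ones) are applied multiplicatively on top.
    """
    if region_tag not in C.REGION_SCALARS:
        raise ValueError(
            f"unknown region_tag {region_tag!r}; expected one of {C.REGION_TAGS}")
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")

    g_to, g_cal, g_kr = C.REGION_SCALARS[region_tag]
    scalars = {"g_to": g_to, "g_CaL": g_cal, "g_Kr": g_kr,
               "g_K1": 1.0, "g_Kur": 1.0, "g_Ks": 1.0}
    if condition == "cAF":
        family = "RA" if region_tag in C.RA_FAMILY else "LA"
        for channel, mult in C.CAF_MULTIPLIERS[family].items():
            scalars[channel] *= mult
    return MembraneModel(region_tag=region_tag, condition=condition,
                         conductance_scalars=scalars)


def initial_state() -> np.ndarray:
    """Quiescent baseline state vector (shared across variants)."""
    return np.array([C.INITIAL_STATE[name] for name in C.STATE_NAMES])


def crn_derivatives(state: np.ndarray, model: MembraneModel,
                    stim_current: float = 0.0) -> np.ndarray:
    """dstate/dt for one cell.  ``stim_current`` in pA/pF (inward negative)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (C.STATE_DIM,):
        raise ValueError(f"state must have shape ({C.STATE_DIM},)")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains NaN/Inf")
    return crn_rhs(state, model.scalar_vector(), float(stim_current))


def pace_single_cell(model: MembraneModel, protocol: PacingProtocol,
                     dt: float = 0.01, record_stride: int = 2,
                     state: np.ndarray | None = None) -> ApTrace:
    """Integrate a paced single cell and return the vm trace.

    Rush–Larsen for the gates, forward Euler for vm and concentrations.
    The stimulus magnitude in the protocol is applied as an inward
    (depolarizing, negative) current.  ``state``, if given, is advanced in
    place so pacing can be continued across calls.
    """
    if dt > 0.02:
        raise ValueError("dt must be <= 0.02 ms for the explicit scheme")
    own_state = state if state is not None else initial_state()
    times, vm, ok = pace_cell(own_state, model.scalar_vector(), dt,
                              protocol.n_beats, protocol.bcl,
                              -abs(protocol.stim_amplitude),
                              protocol.stim_duration, record_stride)
    if not ok:
        raise FloatingPointError(
            f"numerical blow-up (|vm| > 200 mV) pacing {model.region_tag} "
            f"{model.condition} at BCL {protocol.bcl} ms with dt={dt}")
    return ApTrace(times=times, vm=vm, protocol=protocol)


def measure_apd(trace: ApTrace, repolarization_fraction: float = 0.9) -> float:
    """APD on the last beat, from maximal upstroke velocity to the time vm
    falls below rest + (1 - fraction) * amplitude.

    Rest is taken just before the final stimulus (per-beat diastolic value),
    amplitude as peak minus that rest.  Crossing time is found by linear
    interpolation between samples.
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization_fraction must be in (0, 1)")
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.vm, dtype=float)
    bcl = trace.protocol.bcl
    t_last_stim = (trace.protocol.n_beats - 1) * bcl
    i0 = int(np.searchsorted(t, t_last_stim))
    if i0 >= len(t) - 2:
        raise ValueError("trace does not contain a full beat after the final stimulus")

    v_rest = v[max(i0 - 1, 0)]
    seg_t, seg_v = t[i0:], v[i0:]
    peak = float(seg_v.max())
    if peak < -40.0:
        raise NoActionPotentialError(
            f"no action potential detected on the last beat (peak {peak:.1f} mV)")
    amplitude = peak - v_rest

    dvdt = np.diff(seg_v) / np.diff(seg_t)
    i_up = int(np.argmax(dvdt))
    t_up = float(seg_t[i_up])

    threshold = v_rest + (1.0 - repolarization_fraction) * amplitude
    i_peak = int(np.argmax(seg_v))
    below = np.nonzero(seg_v[i_peak:] < threshold)[0]
    if len(below) == 0:
        raise ValueError(
            "repolarization threshold never reached on the last beat "
            "(measurement window too short)")
    k = i_peak + below[0]
    # linear interpolation of the downward crossing
    t1, t2 = seg_t[k - 1], seg_t[k]
    v1, v2 = seg_v[k - 1], seg_v[k]
    t_cross = t1 + (threshold - v1) * (t2 - t1) / (v2 - v1)
    return float(t_cross - t_up)
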