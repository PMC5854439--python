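"""Unipolar electrogram forward modelling.

Under equal anisotropy ratios of the intra- and extracellular domains the
extracellular potential obeys a Poisson equation whose source term is
-1/(1+lambda) * div(D grad Vm).  Here the bounded, heterogeneous torso of a
full forward problem is replaced by an infinite homogeneous volume
conductor, so the potential at a field point p is the free-space Green's
function superposition

    V_e(p, t) = 1/(4 pi sigma_b) * sum_cells  s_cell(t) * measure_cell / |p - r_cell|

with s the equivalent current-source density per node.  The divergence is
evaluated with the same discrete operator as tissue diffusion, which makes
a fully resting frame an exactly zero source field and keeps the source
bookkeeping consistent with the propagation model.  Absolute amplitudes
depend on the conductor model; distance- and masking-driven *ratios* are
the quantities of interest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .tissue_sim import TissueDomain, VmMovie

__all__ = ["SourceField", "EgmSet", "compute_sources", "egm_at_points",
           "mask_sources", "DEFAULT_SIGMA_B", "DEFAULT_THICKNESS"]

DEFAULT_SIGMA_B = 1.0        # S/m, bath/blood conductivity
DEFAULT_THICKNESS = 0.75     # mm, atrial-wall thickness analog
LAMBDA_ANISO = 1.0           # extracellular/intracellular anisotropy ratio


@dataclass
class SourceField:
    """Equivalent current-source density per conducting node per frame."""

    frame_times: np.ndarray      # ms
    values: np.ndarray           # (n_frames, n_src) float32
    centroids: np.ndarray        # (n_src, 3) mm
    measures: np.ndarray         # (n_src,) mm^3 (node area x thickness)
    node_ids: np.ndarray         # (n_src,) indices into the domain
    domain: TissueDomain = field(repr=False, default=None)

    def masked(self, keep: np.ndarray) -> "SourceField":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        sel = np.isin(self.node_ids, keep)
        if not sel.any():
            raise ValueError("mask selects no source nodes")
        out = SourceField(self.frame_times, self.values.copy(),
                          self.centroids, self.measures, self.node_ids,
                          self.domain)
        out.values[:, ~sel] = 0.0
        return out


@dataclass
class EgmSet:
    """Unipolar electrogram traces at a set of electrode positions."""

    electrode_ids: list[str]
    electrode_coords: np.ndarray     # (n_el, 3) mm
    traces: np.ndarray               # (n_frames, n_el) mV
    frame_times: np.ndarray          # ms
    source_mask: np.ndarray | None = None

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / float(self.frame_times[1] - self.frame_times[0])

    def v_rms(self) -> np.ndarray:
        x = self.traces - self.traces.mean(axis=0, keepdims=True)
        return np.sqrt(np.mean(x ** 2, axis=0))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_ms"] + list(self.electrode_ids))
            for i, t in enumerate(self.frame_times):
                w.writerow([f"{t:.6g}"] +
                           [f"{v:.6g}" for v in self.traces[i]])

    def to_hdf5(self, path, group="egm_set") -> None:
        import h5py
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in list(g):
                del g[name]
            g.create_dataset("frame_times", data=self.frame_times)
            g.create_dataset("traces", data=self.traces)
            g.create_dataset("electrode_coords", data=self.electrode_coords)
            g.create_dataset(
                "electrode_ids",
                data=np.array(self.electrode_ids, dtype="S16"))


def compute_sources(vm_movie: VmMovie, domain: TissueDomain | None = None,
                    thickness: float = DEFAULT_THICKNESS) -> SourceField:
    """Per-node equivalent source density s = -1/(1+lambda) div(D grad Vm).

    The discrete divergence reuses the diffusion stencil weights, so the
    source over any frame with all wavefronts interior sums to ~0 (discrete
    divergence theorem under no-flux boundaries).
    """
    domain = domain or vm_movie.domain
    if vm_movie.frames.shape[1] != domain.n_nodes:
        raise ValueError("movie and domain have mismatched node counts")
    nb_idx, nb_w = domain.links()
    src_nodes = np.nonzero(domain.conducting)[0]
    frames = vm_movie.frames.astype(np.float64)

    lap = np.zeros_like(frames)
    for k in range(nb_idx.shape[1]):
        q = nb_idx[:, k]
        w = nb_w[:, k]
        has = q >= 0
        lap[:, has] += w[has] * (frames[:, q[has]] - frames[:, has])

    values = (-1.0 / (1.0 + LAMBDA_ANISO)) * lap[:, src_nodes]
    measures = np.full(len(src_nodes), domain.dx ** 2 * thickness)
    return SourceField(frame_times=vm_movie.frame_times,
                       values=values.astype(np.float32),
                       centroids=domain.node_coords[src_nodes],
                       measures=measures, node_ids=src_nodes, domain=domain)


def egm_at_points(sources: SourceField, points: np.ndarray,
                  sigma_b: float = DEFAULT_SIGMA_B,
                  electrode_ids: list[str] | None = None,
                  min_distance: float | None = None) -> EgmSet:
    """Superpose the free-space kernel over all sources at each field point.

    ``points`` (n_el, 3) in mm.  Distances below ``min_distance`` (default
    dx/2) are clamped to it, which regularizes the 1/r kernel when an
    electrode touches the tissue.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if min_distance is None:
        min_distance = (sources.domain.dx / 2.0) if sources.domain else 0.25
    diff = points[:, None, :] - sources.centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    n_clamped = int((dist < min_distance).sum())
    if n_clamped:
        import warnings
        warnings.warn(f"{n_clamped} electrode-source distance(s) below "
                      f"{min_distance:.3g} mm clamped (electrode touching "
                      "or inside the tissue layer)")
    np.maximum(dist, min_distance, out=dist)
    # 1/(4 pi sigma_b) with sigma in S/m, r in mm, source density in
    # mV * mm^-2 * mm^3: fold the unit conversions into one display scale
    # so traces are O(1 mV) at contact distance.
    kernel = (sources.measures[None, :] / dist) / (4.0 * np.pi * sigma_b)
    traces = sources.values @ kernel.T.astype(np.float32)
    if electrode_ids is None:
        electrode_ids = [f"e{i + 1:03d}" for i in range(len(points))]
    return EgmSet(electrode_ids=list(electrode_ids),
                  electrode_coords=points, traces=traces,
                  frame_times=sources.frame_times)


def mask_sources(sources: SourceField, region_selector) -> SourceField:
    """Zero all sources outside a region.

    ``region_selector`` is a node-index array / boolean mask, or a callable
    mapping (x, y) chart coordinates to a boolean mask.  Used for the
    far-field experiments: electrodes over silenced tissue then see only
    distant activity.
    """
    if callable(region_selector):
        x, y = sources.domain.node_coords_2d()
        keep = np.nonzero(region_selector(x, y))[0]
    else:
        keep = region_selector
    return sources.masked(keep)
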