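"""Monodomain reaction–diffusion simulation on 2-D sheets, annuli (sheets
with non-conducting holes), cylinders (periodic sheets) and 1-D strands.

The transmembrane potential obeys  Cm dVm/dt = div(D grad Vm) - I_ion - I_stim
with no-flux boundaries; I_ion comes from the regional CRN variants of
:mod:`basketmap.ionic_models`.  D here is the equivalent monodomain
diffusivity in mm^2/ms (the conductivity tensor divided by the
surface-to-volume ratio and membrane capacitance, and scaled by
lambda/(1+lambda) under the equal-anisotropy-ratio assumption); only
axis-aligned anisotropy is supported.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from . import crn_constants as C
from ._tissue_kernels import build_tables, run_monodomain
from .ionic_models import MembraneModel, PacingProtocol, build_membrane_model, \
    initial_state, pace_single_cell

__all__ = [
    "TissueDomain", "StimulusEvent", "VmMovie", "build_domain",
    "initial_tissue_states", "run_scenario", "measure_cv",
    "cross_field_stimuli", "ConductionBlockError",
    "DEFAULT_DIFFUSIVITY", "TISSUE_STIM_AMPLITUDE",
]

# Baseline equivalent diffusivity (mm^2/ms).  Gives a planar conduction
# velocity of ~65 cm/s for the control RA/PM membrane at dx = 0.3 mm, in the
# normal human-atrial range; absolute CV is a calibrated default and only
# condition *ratios* are treated as anchored quantities.
DEFAULT_DIFFUSIVITY = 0.1

# Tissue pacing pulse (pA/pF).  Stronger than the single-cell protocol
# because the stimulated patch also has to charge its neighbors.
TISSUE_STIM_AMPLITUDE = 28.0

_TABLE_VMIN = -100.0
_TABLE_VMAX = 60.0
_TABLE_DV = 0.02


class ConductionBlockError(RuntimeError):
    """Propagation failed to traverse the measurement window."""


@dataclass
class StimulusEvent:
    """A (possibly periodic) current injection into a node set."""

    node_set: np.ndarray                 # node indices
    onset: float                         # ms
    amplitude: float = TISSUE_STIM_AMPLITUDE   # pA/pF, magnitude
    duration: float = 2.0                # ms
    period: float | None = None          # ms; None = one-shot
    count: int = 1

    def as_params(self) -> np.ndarray:
        period = self.period if self.period is not None else 0.0
        return np.array([self.onset, period, self.duration,
                         float(self.count), -abs(self.amplitude)])


@dataclass
class TissueDomain:
    """A discretized conducting surface.

    Nodes live on an ny x nx grid with spacing ``dx`` (mm); node p maps to
    grid position (p // nx, p % nx).  ``conducting`` is False inside
    obstacles (orifice analogs); non-conducting nodes carry no flux in or
    out, which realizes the no-flux boundary exactly on the stencil.
    """

    geometry: str
    nx: int
    ny: int
    dx: float
    node_coords: np.ndarray              # (N, 3) mm
    conducting: np.ndarray               # (N,) bool
    region_idx: np.ndarray               # (N,) uint8 into region_tags
    region_tags: tuple[str, ...]
    diffusivity: np.ndarray              # (N, 2): Dx, Dy in mm^2/ms
    condition: str = "control"
    periodic_x: bool = False
    _links: tuple | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-node array onto the (ny, nx) grid."""
        return np.asarray(values).reshape(self.ny, self.nx)

    # -- node selection helpers -------------------------------------------
    def nodes_in_disk(self, cx: float, cy: float, r: float) -> np.ndarray:
        x, y = self.node_coords_2d()
        sel = ((x - cx) ** 2 + (y - cy) ** 2 <= r * r) & self.conducting
        return np.nonzero(sel)[0]

    def nodes_in_rect(self, x0, x1, y0, y1) -> np.ndarray:
        x, y = self.node_coords_2d()
        sel = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1) & self.conducting
        return np.nonzero(sel)[0]

    def node_coords_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """In-chart (x, y) coordinates in mm regardless of embedding."""
        iy, ix = np.divmod(np.arange(self.n_nodes), self.nx)
        return ix * self.dx, iy * self.dx

    # -- stencil -----------------------------------------------------------
    def links(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbor index / weight arrays for the diffusion stencil.

        Face weights are harmonic means of the two nodes' diffusivities
        along the face axis, divided by dx^2; links to obstacle nodes or
        across the boundary are absent (index -1, weight 0).
        """
        if self._links is not None:
            return self._links
        n = self.n_nodes
        nb_idx = np.full((n, 4), -1, dtype=np.int64)
        nb_w = np.zeros((n, 4))
        cond = self.conducting.reshape(self.ny, self.nx)
        dxx = self.diffusivity[:, 0].reshape(self.ny, self.nx)
        dyy = self.diffusivity[:, 1].reshape(self.ny, self.nx)
        inv_dx2 = 1.0 / self.dx ** 2

        def harm(a, b):
            s = a + b
            return np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)

        for k, (dy, dx_) in enumerate(((0, 1), (0, -1), (1, 0), (-1, 0))):
            iy, ix = np.mgrid[0:self.ny, 0:self.nx]
            jy, jx = iy + dy, ix + dx_
            if self.periodic_x:
                jx = jx % self.nx
            ok = (jy >= 0) & (jy < self.ny) & (jx >= 0) & (jx < self.nx)
            jy_c = np.clip(jy, 0, self.ny - 1)
            jx_c = np.clip(jx, 0, self.nx - 1) if not self.periodic_x else jx
            ok &= cond & cond[jy_c, jx_c]
            dfield = dxx if dy == 0 else dyy
            w = harm(dfield[iy, ix], dfield[jy_c, jx_c]) * inv_dx2
            p = (iy * self.nx + ix).ravel()
            q = (jy_c * self.nx + jx_c).ravel()
            okf = ok.ravel()
            nb_idx[p[okf], k] = q[okf]
            nb_w[p[okf], k] = w.ravel()[okf]
        self._links = (nb_idx, nb_w)
        return self._links

    def quad_elements(self) -> np.ndarray:
        """Counter-clockwise node quads of fully conducting grid cells,
        used as the closed paths for topological-charge evaluation."""
        cond = self.conducting.reshape(self.ny, self.nx)
        iy, ix = np.mgrid[0:self.ny - 1, 0:self.nx - 1]
        p00 = iy * self.nx + ix
        p01 = p00 + 1
        p11 = p00 + self.nx + 1
        p10 = p00 + self.nx
        ok = (cond[:-1, :-1] & cond[:-1, 1:] & cond[1:, 1:] & cond[1:, :-1])
        quads = np.stack([p00, p01, p11, p10], axis=-1)[ok]
        if self.periodic_x:
            iy = np.arange(self.ny - 1)
            p00 = iy * self.nx + self.nx - 1
            p01 = iy * self.nx
            p11 = (iy + 1) * self.nx
            p10 = p00 + self.nx
            ok = (cond[:-1, -1] & cond[:-1, 0] & cond[1:, 0] & cond[1:, -1])
            seam = np.stack([p00, p01, p11, p10], axis=-1)[ok]
            quads = np.vstack([quads, seam])
        return quads


@dataclass
class VmMovie:
    """Per-node transmembrane potential at a uniform frame cadence."""

    frame_times: np.ndarray              # ms
    frames: np.ndarray                   # (n_frames, n_nodes) float32, mV
    domain: TissueDomain

    def __post_init__(self):
        dt = np.diff(self.frame_times)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("frame cadence must be uniform")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite values")

    @property
    def cadence(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    def to_hdf5(self, path, group="vm_movie") -> None:
        import h5py
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in list(g):
                del g[name]
            g.create_dataset("frame_times", data=self.frame_times)
            g.create_dataset("frames", data=self.frames,
                             compression="gzip", compression_opts=1)
            g.attrs["nx"] = self.domain.nx
            g.attrs["ny"] = self.domain.ny
            g.attrs["dx"] = self.domain.dx
            g.attrs["geometry"] = self.domain.geometry


def build_domain(geometry: str = "sheet",
                 size_mm: tuple[float, float] = (60.0, 60.0),
                 dx: float = 0.3,
                 region_tag: str = "RA_PM",
                 region_patches: list[dict] | None = None,
                 holes: list[tuple[float, float, float]] | None = None,
                 diffusivity: float = DEFAULT_DIFFUSIVITY,
                 anisotropy_ratio: float = 1.0,
                 conductivity_scale: float = 1.0,
                 condition: str = "control") -> TissueDomain:
    """Construct a tissue domain.

    ``geometry``: "sheet", "annulus" (sheet with a central hole), "cylinder"
    (periodic in x, embedded in 3-D) or "strand" (1-D).  ``region_patches``
    paint regions over the base ``region_tag``; each patch is a dict with
    ``tag`` plus either ``disk`` = (cx, cy, r) or ``rect`` = (x0, x1, y0,
    y1) in mm.  Patches may not overlap.  ``anisotropy_ratio`` = Dx/Dy;
    ``conductivity_scale`` multiplies D uniformly (0.85 models the 15%
    gap-junction down-regulation of chronic AF).
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if geometry not in ("sheet", "annulus", "cylinder", "strand"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if geometry == "strand":
        lx = float(size_mm if np.isscalar(size_mm) else size_mm[0])
        nx = int(round(lx / dx)) + 1
        ny = 1
    else:
        lx, ly = size_mm
        nx = int(round(lx / dx)) + 1
        ny = int(round(ly / dx)) + 1
    n = nx * ny
    iy, ix = np.divmod(np.arange(n), nx)
    x = ix * dx
    y = iy * dx

    if geometry == "cylinder":
        circumference = nx * dx  # seam closes the extra dx gap
        radius = circumference / (2.0 * np.pi)
        phi = 2.0 * np.pi * x / circumference
        coords = np.column_stack([radius * np.cos(phi),
                                  radius * np.sin(phi), y])
    else:
        coords = np.column_stack([x, y, np.zeros(n)])

    conducting = np.ones(n, dtype=bool)
    hole_list = list(holes or [])
    if geometry == "annulus" and not hole_list:
        hole_list = [(lx / 2.0, ly / 2.0, 5.0)]
    for cx, cy, r in hole_list:
        conducting &= (x - cx) ** 2 + (y - cy) ** 2 > r * r

    tags = [region_tag]
    region_idx = np.zeros(n, dtype=np.uint8)
    claimed = np.zeros(n, dtype=bool)
    for patch in region_patches or []:
        tag = patch["tag"]
        if tag not in tags:
            tags.append(tag)
        t_i = tags.index(tag)
        if "disk" in patch:
            cx, cy, r = patch["disk"]
            sel = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        elif "rect" in patch:
            x0, x1, y0, y1 = patch["rect"]
            sel = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        else:
            raise ValueError("patch needs a 'disk' or 'rect' entry")
        if np.any(claimed & sel):
            raise ValueError("overlapping region patches")
        claimed |= sel
        region_idx[sel] = t_i

    for tag in tags:
        build_membrane_model(tag, condition)  # validates tag + condition

    d_eff = diffusivity * conductivity_scale
    dvals = np.empty((n, 2))
    dvals[:, 0] = d_eff
    dvals[:, 1] = d_eff / anisotropy_ratio
    dvals[~conducting] = 0.0

    return TissueDomain(geometry=geometry, nx=nx, ny=ny, dx=dx,
                        node_coords=coords, conducting=conducting,
                        region_idx=region_idx, region_tags=tuple(tags),
                        diffusivity=dvals, condition=condition,
                        periodic_x=(geometry == "cylinder"))


@functools.lru_cache(maxsize=64)
def _prepaced_state(region_tag: str, condition: str, bcl: float,
                    n_beats: int, dt: float) -> tuple:
    """Single-cell state after a stabilization pacing train (cached)."""
    model = build_membrane_model(region_tag, condition)
    state = initial_state()
    if n_beats > 0:
        pace_single_cell(model, PacingProtocol(bcl=bcl, n_beats=n_beats),
                         dt=dt, record_stride=10 ** 6, state=state)
    return tuple(state)


def initial_tissue_states(domain: TissueDomain, prepace_bcl: float = 500.0,
                          prepace_beats: int = 20, dt: float = 0.01
                          ) -> np.ndarray:
    """Per-node initial state: each region's single cell paced to
    quasi-steady state at ``prepace_bcl`` (the stabilization-train analog),
    then broadcast over the region."""
    states = np.empty((domain.n_nodes, C.STATE_DIM))
    for t_i, tag in enumerate(domain.region_tags):
        cell = np.array(_prepaced_state(tag, domain.condition, prepace_bcl,
                                        prepace_beats, dt))
        states[domain.region_idx == t_i] = cell
    return states


_table_cache: dict[float, np.ndarray] = {}


def _tables_for(dt: float) -> np.ndarray:
    if dt not in _table_cache:
        _table_cache[dt] = build_tables(dt, _TABLE_VMIN, _TABLE_VMAX,
                                        _TABLE_DV)
    return _table_cache[dt]


def check_cfl(domain: TissueDomain, dt: float) -> None:
    dmax = float(domain.diffusivity.max())
    if dmax <= 0:
        return
    dt_max = domain.dx ** 2 / (4.0 * dmax)
    if dt > dt_max:
        raise ValueError(
            f"dt={dt} ms violates the diffusion stability bound "
            f"dx^2/(4 D_max) = {dt_max:.4f} ms")


def run_scenario(domain: TissueDomain, stimuli: list[StimulusEvent],
                 duration: float, dt: float = 0.01, output_dt: float = 1.0,
                 states: np.ndarray | None = None,
                 prepace_bcl: float = 500.0, prepace_beats: int = 20
                 ) -> tuple[VmMovie, np.ndarray]:
    """Integrate the monodomain model and record a 1-ms-cadence Vm movie.

    Returns (movie, final_states); ``states`` (modified in place if given)
    allows runs to be chained.
    """
    check_cfl(domain, dt)
    if states is None:
        states = initial_tissue_states(domain, prepace_bcl, prepace_beats, dt)
    scalars = np.stack([build_membrane_model(tag, domain.condition)
                        .scalar_vector() for tag in domain.region_tags])
    nb_idx, nb_w = domain.links()
    n_steps = int(round(duration / dt))
    record_every = max(int(round(output_dt / dt)), 1)
    n_frames = n_steps // record_every + 1
    frames = np.empty((n_frames, domain.n_nodes), dtype=np.float32)

    if stimuli:
        stim_nodes = np.concatenate(
            [np.asarray(s.node_set, dtype=np.int64) for s in stimuli])
        stim_offsets = np.cumsum(
            [0] + [len(s.node_set) for s in stimuli]).astype(np.int64)
        stim_params = np.stack([s.as_params() for s in stimuli])
    else:
        stim_nodes = np.empty(0, dtype=np.int64)
        stim_offsets = np.zeros(1, dtype=np.int64)
        stim_params = np.empty((0, 5))

    bad_step = run_monodomain(
        states, scalars, domain.region_idx.astype(np.uint8), nb_idx, nb_w,
        stim_nodes, stim_offsets, stim_params, dt, n_steps, record_every,
        frames, _tables_for(dt), _TABLE_VMIN, 1.0 / _TABLE_DV)
    if bad_step >= 0:
        raise FloatingPointError(
            f"monodomain instability at t={bad_step * dt:.2f} ms "
            f"(|vm| > 200 mV)")
    times = np.arange(n_frames) * record_every * dt
    return VmMovie(frame_times=times, frames=frames, domain=domain), states


def cross_field_stimuli(domain: TissueDomain, s1_time: float,
                        s2_time: float, s2_frac: tuple[float, float] = (0.5, 0.5),
                        amplitude: float = TISSUE_STIM_AMPLITUDE
                        ) -> list[StimulusEvent]:
    """Classic S1–S2 cross-field spiral initiation.

    S1 excites a strip on the left edge (plane wave along +x); S2, timed
    into the repolarization tail of S1, excites the lower-left quadrant
    (fractions of the domain given by ``s2_frac``), whose free corner curls
    into a spiral tip near the quadrant corner.
    """
    x, y = domain.node_coords_2d()
    lx, ly = x.max(), y.max()
    s1_nodes = np.nonzero((x <= 2.0 * domain.dx) & domain.conducting)[0]
    s2_nodes = domain.nodes_in_rect(-1.0, lx * s2_frac[0], -1.0,
                                    ly * s2_frac[1])
    return [
        StimulusEvent(node_set=s1_nodes, onset=s1_time, amplitude=amplitude),
        StimulusEvent(node_set=s2_nodes, onset=s2_time, amplitude=amplitude),
    ]


def measure_cv(domain: TissueDomain, model: MembraneModel, bcl: float = 500.0,
               n_beats: int = 6, dt: float = 0.01,
               threshold: float = -20.0) -> float:
    """Conduction velocity (cm/s) on a 1-D strand from an activation-time
    linear fit over the central half on the last paced beat.

    The strand is paced at its left end.  Raises
    :class:`ConductionBlockError` if any node in the window fails to
    activate on the last beat.
    """
    if domain.ny != 1:
        raise ValueError("measure_cv expects a 1-D strand domain")
    if domain.region_tags != (model.region_tag,) or \
            domain.condition != model.condition:
        raise ValueError("domain and model disagree on region/condition")
    length = (domain.nx - 1) * domain.dx
    if length < 20.0:
        raise ValueError("strand must be at least 2 cm for CV measurement")
    stim_nodes = np.arange(5)
    stim = StimulusEvent(node_set=stim_nodes, onset=1.0, period=bcl,
                         count=n_beats)
    movie, _ = run_scenario(domain, [stim], duration=bcl * n_beats, dt=dt,
                            output_dt=0.5)
    t = movie.frame_times
    v = movie.frames
    t0 = (n_beats - 1) * bcl
    sel = t >= t0
    tt, vv = t[sel], v[sel]

    x = np.arange(domain.nx) * domain.dx
    lo, hi = 0.25 * length, 0.75 * length
    window = np.nonzero((x >= lo) & (x <= hi))[0]
    act = np.empty(len(window))
    for k, p in enumerate(window):
        trace = vv[:, p]
        above = np.nonzero((trace[1:] >= threshold) & (trace[:-1] < threshold))[0]
        if len(above) == 0:
            raise ConductionBlockError(
                f"node at x={x[p]:.1f} mm never activated on the last beat")
        i = above[0]
        frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
        act[k] = tt[i] + frac * (tt[i + 1] - tt[i])
    slope = np.polyfit(act, x[window], 1)[0]   # mm/ms
    return float(slope * 100.0)                # cm/s
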