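"""Generators for every test input: analytic phase-field oracles, the
standard rotor + far-field-pacing tissue scenario, an aliasing fixture that
provokes interpolation phantoms (FIPS), and nested source masks for the
far-field (IMPS) experiments.

The standard scenario is a chronic-AF sheet with one non-conducting orifice
hosting a sustained reentry — the desk-scale analog of a stable atrial
rotor (the anatomically anchored variety; a multi-electrode map cannot and
need not distinguish it from a functional one).  A periodic point source in
the far corner plays the ectopic pacing train.  All generators are
deterministic; ``seed`` only perturbs optional jitter and is accepted for
interface uniformity.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from . import crn_constants as CC
from ._crn_kernels import rush_larsen_step
from .ionic_models import PacingProtocol, build_membrane_model, \
    initial_state, pace_single_cell
from .phase_mapping import PhaseMovie
from .tissue_sim import StimulusEvent, TissueDomain, VmMovie, build_domain, \
    run_scenario

__all__ = ["ScenarioSpec", "analytic_vortex_movie", "make_standard_scenario",
           "make_pacing_only_scenario", "make_aliasing_fixture",
           "make_farfield_masks", "limit_cycle_states",
           "STANDARD_SCENARIO_BAND"]

# The shipped scenario's reentry runs at ~6.9 Hz (144 ms cycle); its phase
# maps are band-passed around that rate.
STANDARD_SCENARIO_BAND = (5.0, 9.0)

_HOLE = (20.0, 28.0, 6.0)          # cx, cy, r (mm)
_PACE_SITE = (46.0, 4.0, 1.5)      # far-corner ectopic focus
_SIZE = (50.0, 50.0)
_DX = 0.5
_DIFFUSIVITY = 0.14                # base, before the 15% cAF reduction


@dataclass
class ScenarioSpec:
    """Provenance record for a generated scenario."""

    name: str
    condition: str
    size_mm: tuple
    dx: float
    hole: tuple | None
    diffusivity: float
    conductivity_scale: float
    pacing_cl: float | None
    pacing_onset: float | None
    duration: float
    dt: float
    band_hz: tuple
    rotor_center: tuple | None
    seed: int = 0
    extras: dict = field(default_factory=dict)


def analytic_vortex_movie(centers=((30.0, 30.0),), charges=(1,),
                          omega: float = 2.0 * np.pi * 8.0,
                          duration_ms: float = 1000.0,
                          grid_mm: tuple[float, float] = (60.0, 60.0),
                          dx: float = 1.0, cadence_ms: float = 1.0
                          ) -> SimpleNamespace:
    """Ideal rotating-vortex phase field, the PS-detection oracle.

    theta(x, y, t) = sum_k q_k * atan2(y - y_k, x - x_k) - omega * t,
    wrapped to (-pi, pi].  ``omega`` in rad/s.  Returns a namespace with
    ``movie`` (PhaseMovie), ``node_xy``, ``elements`` (grid quads) and the
    vortex parameters.
    """
    if omega == 0:
        raise ValueError("omega must be nonzero")
    nx = int(round(grid_mm[0] / dx)) + 1
    ny = int(round(grid_mm[1] / dx)) + 1
    iy, ix = np.divmod(np.arange(nx * ny), nx)
    x = ix * dx
    y = iy * dx
    base = np.zeros(nx * ny)
    for (cx, cy), q in zip(centers, charges):
        base = base + q * np.arctan2(y - cy, x - cx)
    times = np.arange(0.0, duration_ms + 0.5 * cadence_ms, cadence_ms)
    theta = base[None, :] - omega * (times[:, None] / 1000.0)
    theta = np.pi - np.mod(np.pi - theta, 2.0 * np.pi)
    movie = PhaseMovie(frame_times=times, phase=theta,
                       provenance="from_vm_ground_truth")

    iy2, ix2 = np.mgrid[0:ny - 1, 0:nx - 1]
    p00 = iy2 * nx + ix2
    elements = np.stack([p00, p00 + 1, p00 + nx + 1, p00 + nx],
                        axis=-1).reshape(-1, 4)
    return SimpleNamespace(movie=movie, node_xy=np.column_stack([x, y]),
                           elements=elements, centers=np.asarray(centers),
                           charges=np.asarray(charges), omega=omega, dx=dx)


@functools.lru_cache(maxsize=8)
def limit_cycle_states(region_tag: str = "RA_PM", condition: str = "cAF",
                       cycle_ms: int = 160, dt: float = 0.01) -> np.ndarray:
    """One steady pacing cycle of full state vectors, sampled every 1 ms.

    Used to paint rotational initial conditions: assigning each node the
    state at a phase proportional to its angle around a pivot starts a
    reentry without any S1-S2 timing search.
    """
    model = build_membrane_model(region_tag, condition)
    state = initial_state()
    pace_single_cell(model, PacingProtocol(bcl=500.0, n_beats=20), dt=dt,
                     record_stride=10 ** 6, state=state)
    sc = model.scalar_vector()
    n = int(round(cycle_ms / dt))
    stim_steps = int(round(2.0 / dt))
    for i in range(7 * n):   # settle onto the fast-rate limit cycle
        stim = -20.0 if (i % n) < stim_steps else 0.0
        rush_larsen_step(state, sc, stim, dt)
    per_ms = int(round(1.0 / dt))
    cycle = np.empty((cycle_ms, CC.STATE_DIM))
    for i in range(n):
        if i % per_ms == 0:
            cycle[i // per_ms] = state
        stim = -20.0 if i < stim_steps else 0.0
        rush_larsen_step(state, sc, stim, dt)
    return cycle


def _pinwheel_states(domain: TissueDomain, center: tuple[float, float],
                     region_tag: str, condition: str) -> np.ndarray:
    cyc = limit_cycle_states(region_tag, condition)
    x, y = domain.node_coords_2d()
    ang = np.arctan2(y - center[1], x - center[0])
    idx = ((ang + np.pi) / (2.0 * np.pi) * len(cyc)).astype(int) % len(cyc)
    return cyc[idx].copy()


def make_standard_scenario(condition: str = "cAF",
                           duration_ms: float = 6000.0,
                           pacing_cl: float | None = 110.0,
                           pacing_onset: float = 600.0,
                           pacing_stop_ms: float | None = None,
                           dt: float = 0.02,
                           seed: int = 0
                           ) -> SimpleNamespace:
    """The shipped two-source scenario: orifice-anchored reentry plus a
    high-frequency ectopic focus in the opposite corner.

    Returns a namespace with ``movie`` (1 ms cadence VmMovie), ``domain``,
    ``spec`` (ScenarioSpec), ``hole``/``rotor_center``, ``pace_site`` and
    ``stimuli``.  Raises RuntimeError if the reentry fails to sustain
    through the run (activity check over the final 300 ms).
    """
    domain = build_domain("annulus", _SIZE, dx=_DX, condition=condition,
                          diffusivity=_DIFFUSIVITY,
                          conductivity_scale=0.85 if condition == "cAF" else 1.0,
                          holes=[_HOLE])
    states = _pinwheel_states(domain, _HOLE[:2], "RA_PM", condition)
    stimuli = []
    if pacing_cl is not None:
        nodes = domain.nodes_in_disk(*_PACE_SITE)
        count = 100000
        if pacing_stop_ms is not None:
            count = max(int((pacing_stop_ms - pacing_onset) // pacing_cl), 0)
        stimuli.append(StimulusEvent(node_set=nodes, onset=pacing_onset,
                                     period=pacing_cl, count=count))
    movie, _ = run_scenario(domain, stimuli, duration=duration_ms, dt=dt,
                            output_dt=1.0, states=states)
    active = (movie.frames[-300:] > -40.0).mean(axis=1)
    if active.max() <= 0.0:
        raise RuntimeError(
            "reentry failed to sustain through the scenario; the domain or "
            "membrane configuration does not support circulation")
    spec = ScenarioSpec(name="standard_rotor_plus_pacing",
                        condition=condition, size_mm=_SIZE, dx=_DX,
                        hole=_HOLE, diffusivity=_DIFFUSIVITY,
                        conductivity_scale=0.85 if condition == "cAF" else 1.0,
                        pacing_cl=pacing_cl, pacing_onset=pacing_onset,
                        duration=duration_ms, dt=dt,
                        band_hz=STANDARD_SCENARIO_BAND,
                        rotor_center=_HOLE[:2], seed=seed)
    return SimpleNamespace(movie=movie, domain=domain, spec=spec,
                           hole=_HOLE, rotor_center=np.array(_HOLE[:2]),
                           pace_site=np.array(_PACE_SITE[:2]),
                           stimuli=stimuli)


def make_pacing_only_scenario(condition: str = "cAF",
                              duration_ms: float = 3000.0,
                              pacing_cl: float = 180.0,
                              dt: float = 0.02) -> SimpleNamespace:
    """Control scenario: the ectopic focus alone, no reentry — its target
    and plane-like waves carry no interior topological charge."""
    domain = build_domain("annulus", _SIZE, dx=_DX, condition=condition,
                          diffusivity=_DIFFUSIVITY,
                          conductivity_scale=0.85 if condition == "cAF" else 1.0,
                          holes=[_HOLE])
    nodes = domain.nodes_in_disk(*_PACE_SITE)
    stimuli = [StimulusEvent(node_set=nodes, onset=50.0, period=pacing_cl,
                             count=100000)]
    movie, _ = run_scenario(domain, stimuli, duration=duration_ms, dt=dt)
    spec = ScenarioSpec(name="pacing_only", condition=condition,
                        size_mm=_SIZE, dx=_DX, hole=_HOLE,
                        diffusivity=_DIFFUSIVITY,
                        conductivity_scale=0.85 if condition == "cAF" else 1.0,
                        pacing_cl=pacing_cl, pacing_onset=50.0,
                        duration=duration_ms, dt=dt,
                        band_hz=STANDARD_SCENARIO_BAND, rotor_center=None)
    return SimpleNamespace(movie=movie, domain=domain, spec=spec,
                           hole=_HOLE, rotor_center=None,
                           pace_site=np.array(_PACE_SITE[:2]),
                           stimuli=stimuli)


def make_aliasing_fixture(geometry, duration_ms: float = 3000.0,
                          freq_hz: float = 8.5,
                          base_wavelength_mm: float = 9.6,
                          modulation: float = 0.4):
    """Electrode EGMs of a traveling wave that undersamples coarse baskets.

    The wave moves along the splines with local wavelength
    base_wavelength / (1 + modulation*cos(longitude)); adjacent-ring phase
    offsets then exceed pi somewhere on the chart for ring spacings >=
    half the base wavelength (the 4x6 and 8x8 layouts), where linear
    interpolation of the oscillating EGMs produces amplitude nulls and
    spurious PS pairs — the FIPS mechanism.  A 16x16 layout samples the
    wave above its Nyquist rate everywhere and stays artifact-free.  The
    underlying field is a smooth traveling wave: the tissue ground truth
    carries no PS.

    Returns an :class:`~basketmap.forward_egm.EgmSet` at the electrodes.
    """
    from .forward_egm import EgmSet

    r = geometry.radius
    lon = np.repeat(geometry.longitudes(), geometry.electrodes_per_spline)
    lat = np.tile(geometry.arc_latitudes(), geometry.n_splines)
    k0 = 2.0 * np.pi / base_wavelength_mm
    phase_offset = k0 * lat * (1.0 + modulation * np.cos(lon))
    t = np.arange(0.0, duration_ms, 1.0)
    traces = np.cos(2.0 * np.pi * freq_hz * t[:, None] / 1000.0
                    - phase_offset[None, :]).astype(np.float32)
    return EgmSet(electrode_ids=geometry.electrode_ids,
                  electrode_coords=geometry.coords_flat,
                  traces=traces, frame_times=t)


def make_farfield_masks(scenario) -> dict[str, np.ndarray]:
    """Nested source masks for the far-field experiment.

    ``all`` — every conducting node; ``rotor_and_reentry`` — a generous
    disk around the orifice-anchored rotor (its wavefront and the circuit);
    ``rotor_core`` — a tight disk hugging the orifice.  Electrodes over
    excluded tissue then record only far field.
    """
    domain = scenario.domain
    cx, cy, rh = scenario.hole
    x, y = domain.node_coords_2d()
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    cond = domain.conducting
    masks = {
        "all": np.nonzero(cond)[0],
        "rotor_and_reentry": np.nonzero(cond & (r2 <= (rh + 14.0) ** 2))[0],
        "rotor_core": np.nonzero(cond & (r2 <= (rh + 6.0) ** 2))[0],
    }
    prev = None
    for name, nodes in masks.items():
        if prev is not None and not np.all(np.isin(nodes, prev)):
            raise AssertionError(f"mask {name} is not nested in its parent")
        prev = nodes
    return masks
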