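"""Parametric spherical basket catheter and its 2-D projection chart.

The basket is a sphere of configurable diameter carrying ``n_splines``
meridians (labelled A, B, ...), each with ``electrodes_per_spline``
electrodes equally spaced in arc length along the meridian and centered on
the equator.  Electrograms sampled at the electrodes are linearly
interpolated onto a dense periodic (longitude x arc-latitude) chart — the
basket's "2-D projection" — on which phase maps and PS detection run; the
pole caps beyond the outermost electrode rings are not interpolated.

Chart coordinates: x = longitude * sphere_radius (periodic), y = arc
latitude (mm along the meridian, 0 at the equator).  Chart distances
overestimate longitudinal separations near the poles; trajectory metrics
that need true 3-D positions use :meth:`BasketGeometry.chart_to_world`.
"""

from __future__ import annotations

import csv
import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = ["BasketGeometry", "Projection2D", "DistanceMap", "build_basket",
           "basket_with_density", "place_basket", "distance_map",
           "interpolate_to_projection", "interpolation_matrix",
           "chart_interp_matrix", "projection_grid", "DEFAULT_GRID_POINTS"]

DEFAULT_GRID_POINTS = (240, 240)     # (n_lon, n_lat) -> 57,600 points


def _rotation_from_z(w: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the unit vector ``w`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(w, z):
        return np.eye(3)
    if np.allclose(w, -z):
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, w)
    s = np.linalg.norm(axis)
    c = z @ w
    k = axis / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


@dataclass(frozen=True)
class BasketGeometry:
    """Electrode layout of a spherical basket catheter."""

    n_splines: int
    electrodes_per_spline: int
    diameter: float                    # mm
    spacing: float                     # mm, along-spline electrode spacing
    center: np.ndarray                 # (3,)
    orientation: np.ndarray            # pole-axis unit vector
    electrode_coords: np.ndarray       # (n_splines, n_el, 3) mm

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def spline_labels(self) -> list[str]:
        letters = string.ascii_uppercase
        return [letters[i % 26] * (i // 26 + 1) for i in range(self.n_splines)]

    @property
    def electrode_ids(self) -> list[str]:
        return [f"{s}{j + 1}" for s in self.spline_labels
                for j in range(self.electrodes_per_spline)]

    @property
    def coords_flat(self) -> np.ndarray:
        return self.electrode_coords.reshape(-1, 3)

    def arc_latitudes(self) -> np.ndarray:
        """Along-meridian arc position of each ring, 0 at the equator."""
        e = self.electrodes_per_spline
        return (np.arange(e) - (e - 1) / 2.0) * self.spacing

    def longitudes(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_splines) / self.n_splines

    def _frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (u, v, pole) frame for the current orientation."""
        w = self.orientation / np.linalg.norm(self.orientation)
        rot = _rotation_from_z(w)
        return rot[:, 0], rot[:, 1], w

    def chart_to_world(self, x_chart: np.ndarray, y_chart: np.ndarray
                       ) -> np.ndarray:
        """Map chart (x, y) mm back to 3-D points on the basket sphere."""
        r = self.radius
        phi = np.asarray(x_chart, dtype=float) / r
        beta = np.asarray(y_chart, dtype=float) / r
        u, v, w = self._frame()
        pts = (r * np.cos(beta)[..., None] *
               (np.cos(phi)[..., None] * u + np.sin(phi)[..., None] * v)
               + r * np.sin(beta)[..., None] * w)
        return self.center + pts

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["spline_label", "electrode_index",
                        "x_mm", "y_mm", "z_mm"])
            for i, s in enumerate(self.spline_labels):
                for j in range(self.electrodes_per_spline):
                    x, y, z = self.electrode_coords[i, j]
                    w.writerow([s, j + 1, f"{x:.6g}", f"{y:.6g}", f"{z:.6g}"])


def build_basket(n_splines: int = 8, n_electrodes: int = 8,
                 diameter: float = 31.0, spacing: float = 4.8
                 ) -> BasketGeometry:
    """Electrodes on meridians at equal arc spacing, centered on the
    equator, pole axis +z, centered at the origin."""
    if n_splines < 3:
        raise ValueError("need at least 3 splines")
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes per spline")
    r = diameter / 2.0
    if spacing * (n_electrodes - 1) >= np.pi * r:
        raise ValueError("electrode span overruns the poles")
    beta = (np.arange(n_electrodes) - (n_electrodes - 1) / 2.0) * spacing / r
    phi = 2.0 * np.pi * np.arange(n_splines) / n_splines
    coords = np.empty((n_splines, n_electrodes, 3))
    coords[..., 0] = r * np.cos(beta)[None, :] * np.cos(phi)[:, None]
    coords[..., 1] = r * np.cos(beta)[None, :] * np.sin(phi)[:, None]
    coords[..., 2] = r * np.sin(beta)[None, :]
    return BasketGeometry(n_splines=n_splines,
                          electrodes_per_spline=n_electrodes,
                          diameter=diameter, spacing=spacing,
                          center=np.zeros(3),
                          orientation=np.array([0.0, 0.0, 1.0]),
                          electrode_coords=coords)


def basket_with_density(n_splines: int, n_electrodes: int,
                        diameter: float = 31.0) -> BasketGeometry:
    """Alternative electrode densities covering the same latitude span as
    the reference 8x8 / 4.8 mm layout (the density-sweep configurations)."""
    span = 4.8 * (8 - 1)
    return build_basket(n_splines, n_electrodes, diameter,
                        spacing=span / (n_electrodes - 1))


def place_basket(geometry: BasketGeometry, center, orientation=None,
                 tissue_coords: np.ndarray | None = None,
                 clearance: float = 0.1) -> BasketGeometry:
    """Rigid placement: translate to ``center`` and align the pole axis to
    ``orientation``.

    If ``tissue_coords`` is given, electrodes that ended up below the
    tissue surface plane (sheet at z=0) are pushed back to ``clearance``
    mm above it, with a warning — the analog of a spline pressing into the
    wall.
    """
    center = np.asarray(center, dtype=float)
    if orientation is None:
        orientation = geometry.orientation
    w = np.asarray(orientation, dtype=float)
    w = w / np.linalg.norm(w)
    rot = _rotation_from_z(w)
    base = build_basket(geometry.n_splines, geometry.electrodes_per_spline,
                        geometry.diameter, geometry.spacing)
    coords = base.electrode_coords @ rot.T + center
    if tissue_coords is not None:
        z_t = float(np.median(np.asarray(tissue_coords)[:, 2]))
        low = coords[..., 2] < z_t
        if low.any():
            warnings.warn(f"{int(low.sum())} electrode(s) penetrated the "
                          "tissue plane; repositioned above it")
            coords[..., 2][low] = z_t + clearance
    return replace(geometry, center=center, orientation=w,
                   electrode_coords=coords)


@dataclass
class DistanceMap:
    """Electrode–tissue nearest distances, both directions."""

    electrode_to_tissue: np.ndarray     # (n_el,) mm
    tissue_to_electrode: np.ndarray     # (n_tissue,) mm

    def bucket_fractions(self, edges=(5.0, 10.0)) -> dict[str, float]:
        """Fraction of electrodes with d <= 5 mm, 5 < d <= 10 mm, d > 10 mm."""
        d = self.electrode_to_tissue
        lo, hi = edges
        return {"near": float(np.mean(d <= lo)),
                "mid": float(np.mean((d > lo) & (d <= hi))),
                "far": float(np.mean(d > hi))}


def distance_map(geometry: BasketGeometry, tissue_coords: np.ndarray
                 ) -> DistanceMap:
    tissue_coords = np.asarray(tissue_coords, dtype=float)
    if len(tissue_coords) == 0:
        raise ValueError("tissue surface is empty")
    el = geometry.coords_flat
    d_et = cKDTree(tissue_coords).query(el)[0]
    d_te = cKDTree(el).query(tissue_coords)[0]
    return DistanceMap(electrode_to_tissue=d_et, tissue_to_electrode=d_te)


@dataclass
class Projection2D:
    """Dense periodic chart sampling of electrode-borne values."""

    geometry: BasketGeometry = field(repr=False, default=None)
    n_lon: int = DEFAULT_GRID_POINTS[0]
    n_lat: int = DEFAULT_GRID_POINTS[1]
    x: np.ndarray = None                 # (G,) chart x, mm
    y: np.ndarray = None                 # (G,) chart y (arc latitude), mm
    values: np.ndarray = None            # (..., G)

    @property
    def n_points(self) -> int:
        return self.n_lon * self.n_lat

    def elements(self) -> np.ndarray:
        """CCW quads of the chart grid including the periodic seam."""
        i, j = np.mgrid[0:self.n_lon, 0:self.n_lat - 1]   # lon-major layout
        ip = (i + 1) % self.n_lon
        p00 = i * self.n_lat + j
        p10 = ip * self.n_lat + j
        p11 = ip * self.n_lat + j + 1
        p01 = i * self.n_lat + j + 1
        return np.stack([p00, p10, p11, p01], axis=-1).reshape(-1, 4)

    def to_hdf5(self, path, group="projection") -> None:
        import h5py
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in list(g):
                del g[name]
            g.create_dataset("x", data=self.x)
            g.create_dataset("y", data=self.y)
            if self.values is not None:
                g.create_dataset("values", data=self.values,
                                 compression="gzip", compression_opts=1)
            g.attrs["n_lon"] = self.n_lon
            g.attrs["n_lat"] = self.n_lat

    def element_centroids(self) -> np.ndarray:
        """Chart centroids; seam-aware in x via circular averaging."""
        els = self.elements()
        r = self.geometry.radius
        phi = self.x[els] / r
        cx = np.angle(np.exp(1j * phi).mean(axis=1)) % (2 * np.pi) * r
        cy = self.y[els].mean(axis=1)
        return np.column_stack([cx, cy])


def projection_grid(geometry: BasketGeometry,
                    grid_points: tuple[int, int] = DEFAULT_GRID_POINTS
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Chart coordinates of the interpolation lattice (lon-major order)."""
    n_lon, n_lat = grid_points
    r = geometry.radius
    lat = geometry.arc_latitudes()
    phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
    y = np.linspace(lat[0], lat[-1], n_lat)
    x = np.repeat(phi * r, n_lat)
    yy = np.tile(y, n_lon)
    return x, yy


def chart_interp_matrix(geometry: BasketGeometry, x: np.ndarray,
                        y: np.ndarray) -> sparse.csr_matrix:
    """Barycentric-linear interpolation weights at arbitrary chart points.

    The electrode lattice is triangulated with a fixed diagonal per quad
    (seam-aware because spline intervals wrap in longitude); weights
    reproduce electrode values exactly at electrode sites and constants
    everywhere.  Latitudes outside the electrode band are clamped to it.
    """
    s, e = geometry.n_splines, geometry.electrodes_per_spline
    lat = geometry.arc_latitudes()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = geometry.radius
    phi = np.mod(x / r, 2.0 * np.pi)
    dphi = 2.0 * np.pi / s

    fi = phi / dphi
    i0 = np.floor(fi).astype(int) % s
    u = fi - np.floor(fi)
    j0 = np.clip(np.searchsorted(lat, y, side="right") - 1, 0, e - 2)
    v = (y - lat[j0]) / (lat[j0 + 1] - lat[j0])
    v = np.clip(v, 0.0, 1.0)

    def eid(i, j):
        return (i % s) * e + j

    rows, cols, vals = [], [], []
    g = np.arange(len(x))
    # diagonal (0,0)-(1,1): lower triangle u >= v, upper otherwise
    lower = u >= v
    tri_nodes = np.where(lower[:, None],
                         np.stack([eid(i0, j0), eid(i0 + 1, j0),
                                   eid(i0 + 1, j0 + 1)], axis=1),
                         np.stack([eid(i0, j0), eid(i0 + 1, j0 + 1),
                                   eid(i0, j0 + 1)], axis=1))
    w_lower = np.stack([1.0 - u, u - v, v], axis=1)
    w_upper = np.stack([1.0 - v, u, v - u], axis=1)
    tri_w = np.where(lower[:, None], w_lower, w_upper)
    for k in range(3):
        rows.append(g)
        cols.append(tri_nodes[:, k])
        vals.append(tri_w[:, k])
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(x), s * e))
    return mat


_matrix_cache: dict[tuple, sparse.csr_matrix] = {}


def interpolation_matrix(geometry: BasketGeometry,
                         grid_points: tuple[int, int] = DEFAULT_GRID_POINTS
                         ) -> sparse.csr_matrix:
    key = (geometry.n_splines, geometry.electrodes_per_spline,
           round(geometry.diameter, 9), round(geometry.spacing, 9),
           grid_points)
    if key not in _matrix_cache:
        x, y = projection_grid(geometry, grid_points)
        _matrix_cache[key] = chart_interp_matrix(geometry, x, y)
    return _matrix_cache[key]


def interpolate_to_projection(electrode_values: np.ndarray,
                              geometry: BasketGeometry,
                              grid_points: tuple[int, int] = DEFAULT_GRID_POINTS
                              ) -> Projection2D:
    """Linearly interpolate per-electrode values onto the periodic chart.

    ``electrode_values``: (..., n_splines * n_el) in spline-major order
    (matching ``electrode_ids``); interpolation acts on the last axis and
    is exact at electrode sites.  Works for real EGM samples and for
    complex analytic signals alike.
    """
    w = interpolation_matrix(geometry, grid_points)
    vals = np.asarray(electrode_values)
    flat = vals.reshape(-1, vals.shape[-1])
    out = (w @ flat.T).T.reshape(vals.shape[:-1] + (w.shape[0],))
    x, y = projection_grid(geometry, grid_points)
    return Projection2D(geometry=geometry, n_lon=grid_points[0],
                        n_lat=grid_points[1], x=x, y=y, values=out)
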