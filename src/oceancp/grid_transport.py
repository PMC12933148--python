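"""Ocean grid geometry and mass-conserving tracer transport operators.

The transport operator is a sparse matrix ``A`` (units s^-1) acting on a
tracer concentration vector ``c`` over wet boxes with the convention

    dc/dt = A c + sources

Two exact discrete invariants characterise a valid advective–diffusive
operator and are enforced on construction and on load:

* uniform-field preservation, ``A @ 1 == 0`` — transporting a spatially
  constant tracer does nothing;
* volume-weighted mass conservation, ``v^T A == 0`` with ``v`` the box
  volume vector — transport neither creates nor destroys tracer.

A third property, non-negative off-diagonal entries, follows from the
monotone (upwind advection + central diffusion) discretisation used by
the synthetic builder.

The synthetic circulation is a single-basin meridional overturning cell
described by a streamfunction discretised at cell corners, so the
advective volume fluxes are non-divergent by construction, plus
horizontal and vertical diffusive exchange.  Full-scale applications
load an externally estimated transport matrix instead (see
:func:`read_transport_archive`); the synthetic builder exists so every
downstream computation can run and be verified at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp
import xarray as xr

from .constants import EARTH_RADIUS, SECONDS_PER_YEAR, SVERDRUP

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "SyntheticGridSpec",
    "TransportConstructionError",
    "TransportLoadError",
    "OperatorReport",
    "build_synthetic_transport",
    "validate_operator",
    "write_transport_archive",
    "read_transport_archive",
]


class TransportConstructionError(ValueError):
    """A constructed operator violates a conservation invariant."""


class TransportLoadError(ValueError):
    """An archive is missing fields or fails validation on load."""


@dataclass
class Grid:
    """Wet-box list over a structured latitude / longitude / depth grid.

    Parameters
    ----------
    lat_edges, lon_edges
        Cell edges in degrees, strictly increasing.
    layer_interfaces
        Depths of layer interfaces in metres, positive down, strictly
        increasing, starting at the surface (0 m).
    wet3d
        Boolean array of shape ``(nlat, nlon, nlayers)`` marking wet
        boxes.  Wet boxes must be contiguous from the surface downward
        in every column.
    n_euphotic_layers
        Number of top layers forming the euphotic zone (production and
        surface-restoring region).

    Only wet boxes carry state; all per-box arrays are flat over the wet
    boxes in C order of ``(ilat, ilon, ilayer)``.  ``index3d`` maps grid
    cells to wet-box indices (-1 for dry cells).
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    layer_interfaces: np.ndarray
    wet3d: np.ndarray
    n_euphotic_layers: int = 2

    # derived, populated in __post_init__
    index3d: np.ndarray = field(init=False, repr=False)
    ilat: np.ndarray = field(init=False, repr=False)
    ilon: np.ndarray = field(init=False, repr=False)
    ilayer: np.ndarray = field(init=False, repr=False)
    box_lat: np.ndarray = field(init=False, repr=False)
    box_lon: np.ndarray = field(init=False, repr=False)
    box_depth: np.ndarray = field(init=False, repr=False)
    box_volume: np.ndarray = field(init=False, repr=False)
    box_area: np.ndarray = field(init=False, repr=False)
    euphotic_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.layer_interfaces = np.asarray(self.layer_interfaces, dtype=float)
        self.wet3d = np.asarray(self.wet3d, dtype=bool)

        if self.layer_interfaces.ndim != 1 or len(self.layer_interfaces) < 2:
            raise ValueError("need at least one layer (two interfaces)")
        if np.any(np.diff(self.layer_interfaces) <= 0):
            raise ValueError("layer_interfaces must be strictly increasing")
        nlat, nlon, nlayers = self.wet3d.shape
        if len(self.lat_edges) != nlat + 1 or len(self.lon_edges) != nlon + 1:
            raise ValueError("edge arrays inconsistent with wet3d shape")
        if len(self.layer_interfaces) != nlayers + 1:
            raise ValueError("layer_interfaces inconsistent with wet3d shape")
        if not (1 <= self.n_euphotic_layers <= nlayers):
            raise ValueError("n_euphotic_layers out of range")
        # columns must be wet from the top down
        col_ok = np.all(np.diff(self.wet3d.astype(int), axis=2) <= 0)
        if not col_ok:
            raise ValueError("wet boxes must be contiguous from the surface")

        self.index3d = np.full((nlat, nlon, nlayers), -1, dtype=np.int64)
        self.index3d[self.wet3d] = np.arange(int(self.wet3d.sum()))
        self.ilat, self.ilon, self.ilayer = np.nonzero(self.wet3d)

        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        z_c = 0.5 * (self.layer_interfaces[:-1] + self.layer_interfaces[1:])
        self.box_lat = lat_c[self.ilat]
        self.box_lon = lon_c[self.ilon]
        self.box_depth = z_c[self.ilayer]

        # spherical cell areas: R^2 * dlon * (sin(lat_n) - sin(lat_s))
        phi = np.deg2rad(self.lat_edges)
        dlam = np.deg2rad(np.diff(self.lon_edges))
        band = EARTH_RADIUS**2 * (np.sin(phi[1:]) - np.sin(phi[:-1]))
        area2d = band[:, None] * dlam[None, :]
        self.box_area = area2d[self.ilat, self.ilon]
        self.box_volume = self.box_area * self.layer_thickness[self.ilayer]
        if np.any(self.box_volume <= 0):
            raise ValueError("all wet-box volumes must be strictly positive")
        self.euphotic_mask = self.ilayer < self.n_euphotic_layers

    @property
    def n_boxes(self) -> int:
        return len(self.box_volume)

    @property
    def n_layers(self) -> int:
        return self.wet3d.shape[2]

    @property
    def layer_thickness(self) -> np.ndarray:
        return np.diff(self.layer_interfaces)

    @property
    def euphotic_depth(self) -> float:
        """Depth of the euphotic-zone base, m."""
        return float(self.layer_interfaces[self.n_euphotic_layers])

    @property
    def column_id(self) -> np.ndarray:
        """Water-column label (flattened lat/lon index) per wet box."""
        return self.ilat * self.wet3d.shape[1] + self.ilon

    def columns(self) -> list[np.ndarray]:
        """Wet-box indices of each water column, ordered surface-down."""
        out = []
        nlat, nlon, _ = self.wet3d.shape
        for i in range(nlat):
            for j in range(nlon):
                idx = self.index3d[i, j, :]
                idx = idx[idx >= 0]
                if len(idx):
                    out.append(idx)
        return out

    def total_volume(self) -> float:
        return float(self.box_volume.sum())


@dataclass
class SyntheticGridSpec:
    """Dimensions and spacing of a desk-scale synthetic ocean grid.

    The default geometry is a global-scale single basin (80S-80N, full
    zonal extent, ~3.5 km deep), so that prescribing the observed
    global NPP total yields a realistic areal production density.
    Layer thicknesses stretch geometrically from ``top_thickness`` so
    the synthetic column mimics the thin-surface / thick-abyss layering
    of a z-coordinate ocean model.
    """

    n_lat: int = 8
    n_lon: int = 4
    n_layers: int = 8
    lat_min: float = -80.0
    lat_max: float = 80.0
    lon_min: float = 0.0
    lon_max: float = 360.0
    top_thickness: float = 50.0
    stretch: float = 1.6
    n_euphotic_layers: int = 2

    def build_grid(self) -> Grid:
        if self.n_layers < 2 or self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("need at least 2 layers and 1x1 columns")
        thick = self.top_thickness * self.stretch ** np.arange(self.n_layers)
        interfaces = np.concatenate([[0.0], np.cumsum(thick)])
        return Grid(
            lat_edges=np.linspace(self.lat_min, self.lat_max, self.n_lat + 1),
            lon_edges=np.linspace(self.lon_min, self.lon_max, self.n_lon + 1),
            layer_interfaces=interfaces,
            wet3d=np.ones((self.n_lat, self.n_lon, self.n_layers), bool),
            n_euphotic_layers=self.n_euphotic_layers,
        )


@dataclass
class OperatorReport:
    """Conservation diagnostics for a transport operator."""

    conservation_residual: float  # max |v^T A| / (||v||_inf * ||A||_inf)
    uniform_residual: float       # max |A 1| / ||A||_inf
    n_negative_offdiag: int
    n_boxes: int

    def ok(self, tol: float = 1.0e-10) -> bool:
        return (
            self.conservation_residual < tol
            and self.uniform_residual < tol
            and self.n_negative_offdiag == 0
        )


def validate_operator(
    A: sp.spmatrix, grid: Grid, negative_tol: float = 0.0
) -> OperatorReport:
    """Report how well ``A`` satisfies the transport invariants.

    ``negative_tol`` is the magnitude (relative to the largest entry)
    below which a negative off-diagonal is ignored as round-off.
    """
    A = sp.csr_matrix(A)
    if A.shape != (grid.n_boxes, grid.n_boxes):
        raise ValueError("operator shape inconsistent with grid")
    v = grid.box_volume
    scale = np.abs(A.data).max() if A.nnz else 1.0
    cons = np.abs(v @ A).max() / (np.abs(v).max() * scale)
    unif = np.abs(A @ np.ones(grid.n_boxes)).max() / scale
    off = A.copy().tolil()
    off.setdiag(0.0)
    off = off.tocsr()
    n_neg = int((off.data < -negative_tol * scale).sum())
    return OperatorReport(float(cons), float(unif), n_neg, grid.n_boxes)


def _streamfunction(spec: SyntheticGridSpec, psi0: float, grid: Grid) -> np.ndarray:
    """Overturning streamfunction (m^3 s^-1) at lat-interface x depth-interface corners.

    Vanishes on all boundaries, so the implied volume fluxes are
    non-divergent and confined to the basin.
    """
    yhat = np.linspace(0.0, 1.0, spec.n_lat + 1)
    zhat = grid.layer_interfaces / grid.layer_interfaces[-1]
    return psi0 * np.outer(np.sin(np.pi * yhat), np.sin(np.pi * zhat))


def build_synthetic_transport(
    spec: SyntheticGridSpec,
    overturning_sv: float = 30.0,
    kappa_h: float = 1.0e3,
    kappa_v: float = 2.0e-4,
    seed: int = 0,
    jitter: float = 0.3,
    tol: float = 1.0e-10,
) -> tuple[Grid, sp.csr_matrix]:
    """Construct a desk-scale grid and a conserving transport operator.

    Parameters
    ----------
    overturning_sv
        Amplitude of the single-cell meridional overturning
        streamfunction, Sv.
    kappa_h, kappa_v
        Horizontal and vertical diffusivities, m^2 s^-1.  Must be >= 0.
    seed
        Seeds a multiplicative log-normal jitter (sd ``jitter`` in log
        space) applied per diffusive face, breaking the symmetry of the
        idealised basin while preserving every conservation invariant.
        Construction is deterministic for a fixed seed.
    tol
        Invariant tolerance; violation raises
        :class:`TransportConstructionError`.
    """
    if kappa_h < 0 or kappa_v < 0:
        raise ValueError("diffusivities must be non-negative")
    grid = spec.build_grid()
    if spec.n_lat * spec.n_lon < 2:
        raise ValueError("need at least 2 water columns")
    rng = np.random.default_rng(seed)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    v = grid.box_volume

    def add_advection(i: int, j: int, q: float) -> None:
        # upwind: volume flux q >= 0 carries donor concentration i -> j
        if q == 0.0:
            return
        if q < 0.0:
            i, j, q = j, i, -q
        rows.append(np.array([j, i]))
        cols.append(np.array([i, i]))
        vals.append(np.array([q / v[j], -q / v[i]]))

    def add_exchange(i: int, j: int, k_vol: float) -> None:
        # symmetric diffusive exchange, k_vol in m^3 s^-1
        if k_vol <= 0.0:
            return
        rows.append(np.array([i, i, j, j]))
        cols.append(np.array([i, j, j, i]))
        vals.append(np.array([-k_vol / v[i], k_vol / v[i], -k_vol / v[j], k_vol / v[j]]))

    psi = _streamfunction(spec, overturning_sv * SVERDRUP, grid)
    nlat, nlon, nlayers = grid.wet3d.shape
    idx = grid.index3d
    thick = grid.layer_thickness
    z_c = 0.5 * (grid.layer_interfaces[:-1] + grid.layer_interfaces[1:])
    lat_c = 0.5 * (grid.lat_edges[:-1] + grid.lat_edges[1:])
    dy = np.deg2rad(np.diff(grid.lat_edges)) * EARTH_RADIUS
    dx_c = (
        np.deg2rad(np.diff(grid.lon_edges))[None, :]
        * EARTH_RADIUS
        * np.cos(np.deg2rad(lat_c))[:, None]
    )  # zonal width at cell centre, (nlat, nlon)

    def jfac() -> float:
        return float(np.exp(jitter * rng.standard_normal())) if jitter > 0 else 1.0

    for i in range(nlat):
        for j in range(nlon):
            for k in range(nlayers):
                b = idx[i, j, k]
                if b < 0:
                    continue
                # meridional face to the north (i+1)
                if i + 1 < nlat and idx[i + 1, j, k] >= 0:
                    nb = idx[i + 1, j, k]
                    q = (psi[i + 1, k + 1] - psi[i + 1, k]) / nlon
                    add_advection(b, nb, q)
                    face = dx_c[i, j] * thick[k]  # approximate interface width
                    add_exchange(b, nb, kappa_h * jfac() * face / dy[i])
                # zonal face to the east (j+1), diffusion only
                if j + 1 < nlon and idx[i, j + 1, k] >= 0:
                    nb = idx[i, j + 1, k]
                    face = dy[i] * thick[k]
                    add_exchange(b, nb, kappa_h * jfac() * face / dx_c[i, j])
                # vertical face below (k+1)
                if k + 1 < nlayers and idx[i, j, k + 1] >= 0:
                    nb = idx[i, j, k + 1]
                    q = (psi[i, k + 1] - psi[i + 1, k + 1]) / nlon  # positive down
                    add_advection(b, nb, q)
                    dz = z_c[k + 1] - z_c[k]
                    add_exchange(b, nb, kappa_v * jfac() * grid.box_area[b] / dz)

    n = grid.n_boxes
    if rows:
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        A = sp.csr_matrix((n, n))

    report = validate_operator(A, grid, negative_tol=1.0e-14)
    if report.conservation_residual >= tol:
        raise TransportConstructionError(
            f"volume-weighted conservation violated: residual "
            f"{report.conservation_residual:.3e} >= {tol:.1e}"
        )
    if report.uniform_residual >= tol:
        raise TransportConstructionError(
            f"uniform-field preservation violated: residual "
            f"{report.uniform_residual:.3e} >= {tol:.1e}"
        )
    if report.n_negative_offdiag:
        raise TransportConstructionError(
            f"{report.n_negative_offdiag} negative off-diagonal entries "
            "(non-monotone discretization)"
        )
    return grid, A


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------

_GEOMETRY_VARS = (
    "lat_edges",
    "lon_edges",
    "layer_interfaces",
    "wet3d",
    "A_row",
    "A_col",
    "A_val",
)


def _grid_to_dataset(grid: Grid, A: sp.spmatrix, units: str) -> xr.Dataset:
    coo = sp.coo_matrix(A)
    return xr.Dataset(
        {
            "lat_edges": ("lat_edge", grid.lat_edges),
            "lon_edges": ("lon_edge", grid.lon_edges),
            "layer_interfaces": ("layer_interface", grid.layer_interfaces),
            "wet3d": (("lat", "lon", "layer"), grid.wet3d.astype(np.int8)),
            "A_row": ("nnz", coo.row.astype(np.int64)),
            "A_col": ("nnz", coo.col.astype(np.int64)),
            "A_val": ("nnz", coo.data.astype(np.float64)),
        },
        attrs={
            "n_euphotic_layers": grid.n_euphotic_layers,
            "operator_units": units,
            "convention": "dc/dt = A c + sources; 0-based wet-box indexing",
            "depth_positive": "down",
        },
    )


def write_transport_archive(
    path: str, grid: Grid, A: sp.spmatrix, dialect: str = "netcdf", units: str = "s-1"
) -> None:
    """Write grid + operator to a NetCDF or HDF5 archive.

    The operator is stored as coordinate-sparse triplets
    (``A_row``/``A_col``/``A_val``) over wet boxes.
    """
    ds = _grid_to_dataset(grid, A, units)
    if dialect == "netcdf":
        ds.to_netcdf(path)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            for name in _GEOMETRY_VARS:
                f.create_dataset(name, data=ds[name].values)
            for k, val in ds.attrs.items():
                f.attrs[k] = val
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_transport_archive(
    path: str, dialect: str = "netcdf", tol: float = 1.0e-8
) -> tuple[Grid, sp.csr_matrix]:
    """Load a transport archive, validating invariants and units.

    Operators stored in y^-1 (``operator_units`` attribute containing
    "y") are converted to s^-1 on load; the conversion is logged.
    """
    if dialect == "netcdf":
        with xr.open_dataset(path) as ds:
            data = {name: (ds[name].values if name in ds else None) for name in _GEOMETRY_VARS}
            attrs = dict(ds.attrs)
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            data = {name: (f[name][()] if name in f else None) for name in _GEOMETRY_VARS}
            attrs = dict(f.attrs)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [k for k, val in data.items() if val is None]
    if missing:
        raise TransportLoadError(f"archive missing required fields: {missing}")

    grid = Grid(
        lat_edges=data["lat_edges"],
        lon_edges=data["lon_edges"],
        layer_interfaces=data["layer_interfaces"],
        wet3d=data["wet3d"].astype(bool),
        n_euphotic_layers=int(attrs.get("n_euphotic_layers", 2)),
    )
    n = grid.n_boxes
    row, col, val = data["A_row"], data["A_col"], data["A_val"]
    if len(row) and (row.max() >= n or col.max() >= n):
        raise TransportLoadError("operator indices exceed wet-box count")
    A = sp.coo_matrix((val, (row, col)), shape=(n, n)).tocsr()

    units = str(attrs.get("operator_units", "s-1")).lower()
    if "y" in units and "s" not in units.replace("sv", ""):
        logger.info("operator stored in y^-1; converting to s^-1")
        A = A / SECONDS_PER_YEAR
    report = validate_operator(A, grid, negative_tol=1.0e-12)
    if report.conservation_residual >= tol or report.uniform_residual >= tol:
        raise TransportLoadError(
            "loaded operator fails conservation validation: "
            f"conservation={report.conservation_residual:.3e}, "
            f"uniform={report.uniform_residual:.3e} (tol {tol:.1e})"
        )
    return grid, A
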