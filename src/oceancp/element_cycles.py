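"""Steady-state phosphorus, carbon and oxygen cycle solves.

The phosphorus cycle couples four reservoirs — dissolved inorganic
phosphorus (DIP), particulate organic phosphorus (POP), semilabile
dissolved organic phosphorus (DOP) and labile DOP — through a linear
system: biological uptake is proportional to DIP with an empirically
derived coefficient ``gamma``, the uptake is split between the organic
pools by fixed fractions, POP remineralizes along a Martin power-law
depth profile, and the dissolved pools decay back to DIP with
temperature-dependent (Q10) rate constants.  Because transport plus
these closed source/sink terms conserve total phosphorus, the steady
state is fixed by pinning the global volume-weighted mean DIP to a
prescribed inventory.

The carbon cycle is slaved to the phosphorus solution: organic carbon
production equals organic phosphorus production times a spatially
variable C:P ratio ``r_C:P = 1 / (cc * DIP + dd)``, split between
particulate organic carbon (POC), semilabile and refractory dissolved
organic carbon (DOC).  A fast-cycling labile DOC pool (12 h lifetime)
tops production up to the prescribed satellite NPP field.  DIC and
alkalinity are closed with fast surface restoring toward reference
surface values in place of a full carbonate-system gas exchange; this
choice does not affect the regenerated-tracer accounting that the
sequestration analysis uses.  Oxygen is carried with a fixed O2:P
stoichiometry and surface restoring to a linearized saturation, solely
so an O2 misfit term can be exercised by the inversion.

Key parameterizations:

* Martin particle-flux attenuation ``f(z) = f(z0) (z/z0)^(-b)`` with a
  temperature-dependent exponent ``b = b0 + btheta * theta_bar``, where
  ``theta_bar`` is the normalized temperature averaged over the top
  three model layers;
* Q10 remineralization kinetics ``k = kd * Q10^((T - T0) / 10)`` with
  reference temperature ``T0 = 30 degC``;
* variable uptake stoichiometry ``r_C:P = 1 / (cc [DIP] + dd)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import xarray as xr

from .grid_transport import Grid
from .synthetic_ocean import ForcingFields

logger = logging.getLogger(__name__)

__all__ = [
    "CycleParameters",
    "EquilibriumState",
    "ParameterDomainError",
    "SolverDiagnosticError",
    "normalized_surface_temperature",
    "martin_b",
    "q10_rate",
    "cp_ratio",
    "uptake_coefficient",
    "particle_operator",
    "dissolution_operator",
    "solve_p_cycle",
    "solve_c_cycle",
    "solve_equilibrium",
    "flux_weighted_mean",
]

P_POOLS = ("POP", "DOP", "DOPl")
C_POOLS = ("POC", "DOCs", "DOCl", "DOCr")

#: element -> organic pools contributing to its regenerated inventory
ELEMENT_POOLS = {"P": P_POOLS, "C": C_POOLS}

_SECONDS_PER_YEAR = 365.25 * 86400.0


class ParameterDomainError(ValueError):
    """Parameters leave the physically admissible domain."""


class SolverDiagnosticError(RuntimeError):
    """A steady-state solve produced an inadmissible field."""


@dataclass
class CycleParameters:
    """Biogeochemical parameters with bounds for the optimizable subset.

    Defaults are the synthetic-truth configuration used throughout the
    desk-scale experiments: carbon remineralizing faster and shallower
    than phosphorus (larger Martin exponent, larger reference decay
    rate), Redfield-excess production stoichiometry, and fixed
    constants for the labile (12 h) and refractory (16,000 y) pools.
    """

    # Martin exponents, b = b0 + btheta * theta_bar (dimensionless)
    bC0: float = 1.0
    bCtheta: float = 0.6
    bP0: float = 0.8
    bPtheta: float = 0.4
    # reference DOM remineralization rates at T0 (s^-1) and Q10 factors
    kdC: float = 0.5 / _SECONDS_PER_YEAR
    kdP: float = 0.05 / _SECONDS_PER_YEAR
    Q10C: float = 2.2
    Q10P: float = 2.0
    T0: float = 30.0  # degC, fixed reference
    # uptake stoichiometry r_C:P = 1 / (cc * DIP + dd)
    cc: float = 2.0           # m^3 mol^-1
    dd: float = 7.33e-3       # dimensionless (1/dd = C:P at DIP -> 0)
    # production split fractions
    sigma_dop: float = 0.30   # organic P production to semilabile DOP
    sigma_dopl: float = 0.0   # organic P production to labile DOP
    sigma_docs: float = 0.30  # non-labile organic C production to semilabile DOC
    sigma_docr: float = 0.002  # non-labile organic C production to refractory DOC
    # fixed pool lifetimes
    kappa_l: float = 1.0 / (12 * 3600.0)          # s^-1, labile, 12 h
    kappa_r: float = 1.0 / (16000 * _SECONDS_PER_YEAR)  # s^-1, refractory DOC
    # particulate inorganic carbon
    pic_rain_ratio: float = 0.07
    pic_dissolution_scale: float = 3000.0  # m, e-folding depth
    # oxygen stoichiometry (mol O2 : mol P), fixed
    o2_to_p: float = 150.0
    # closure constants
    dip_inventory: float = 2.17e-3     # mol m^-3, global mean DIP
    dic_surface_ref: float = 2.05      # mol m^-3
    alk_surface_ref: float = 2.35      # mol-eq m^-3
    surface_restore_rate: float = 1.0 / (30 * 86400.0)  # s^-1 (~1 month)
    # diagnostics
    particle_sinking_speed: float = 100.0 / 86400.0  # m s^-1, POP/POC/PIC conc diagnostic
    theta_normalization: str = "minmax"  # or "zscore"

    #: bounds of the optimizable parameters (data-driven registry — edit
    #: this dict to change the optimizable set without code changes)
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bC0": (0.2, 2.5),
            "bCtheta": (0.0, 2.0),
            "bP0": (0.2, 2.5),
            "bPtheta": (0.0, 2.0),
            "kdC": (1e-3 / _SECONDS_PER_YEAR, 50.0 / _SECONDS_PER_YEAR),
            "kdP": (1e-4 / _SECONDS_PER_YEAR, 10.0 / _SECONDS_PER_YEAR),
            "Q10C": (1.0, 5.0),
            "Q10P": (1.0, 5.0),
            "cc": (0.0, 50.0),
            "dd": (1e-4, 5e-2),
            "sigma_dop": (0.0, 0.9),
            "sigma_dopl": (0.0, 0.9),
            "sigma_docs": (0.0, 0.9),
            "sigma_docr": (0.0, 0.2),
            "pic_rain_ratio": (0.0, 0.3),
            "pic_dissolution_scale": (200.0, 10000.0),
        }
    )

    def validate(self) -> None:
        for name in ("kdC", "kdP", "kappa_l", "kappa_r", "surface_restore_rate"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be non-negative")
        for name in ("sigma_dop", "sigma_dopl", "sigma_docs", "sigma_docr",
                     "pic_rain_ratio"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterDomainError(f"{name} must be in [0, 1]")
        if self.sigma_dop + self.sigma_dopl > 1.0:
            raise ParameterDomainError("sigma_dop + sigma_dopl exceeds 1")
        if self.sigma_docs + self.sigma_docr > 1.0:
            raise ParameterDomainError("sigma_docs + sigma_docr exceeds 1")
        if self.Q10C < 1.0 or self.Q10P < 1.0:
            raise ParameterDomainError("Q10 must be >= 1")

    def replace(self, **kwargs) -> "CycleParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        out = {}
        for f in dc_fields(self):
            if f.name in ("bounds", "theta_normalization"):
                continue
            out[f.name] = float(getattr(self, f.name))
        return out

    # --- plain-text config (key: value, units in comments) ---------------

    _UNITS = {
        "kdC": "s-1", "kdP": "s-1", "kappa_l": "s-1", "kappa_r": "s-1",
        "surface_restore_rate": "s-1", "T0": "degC", "cc": "m3 mol-1",
        "pic_dissolution_scale": "m", "dip_inventory": "mol m-3",
        "dic_surface_ref": "mol m-3", "alk_surface_ref": "mol-eq m-3",
        "o2_to_p": "mol O2 / mol P", "particle_sinking_speed": "m s-1",
    }

    def to_config(self, path: str) -> None:
        lines = ["# oceancp cycle parameters (key: value)"]
        for name, val in self.to_dict().items():
            unit = self._UNITS.get(name, "dimensionless")
            lines.append(f"{name}: {val!r}  # {unit}")
        lines.append(f"theta_normalization: {self.theta_normalization}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str) -> "CycleParameters":
        kwargs: dict = {}
        valid = {f.name for f in dc_fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition(":")
                key = key.strip()
                if key not in valid or key == "bounds":
                    raise ParameterDomainError(f"unknown parameter {key!r} in {path}")
                val = val.strip()
                kwargs[key] = val if key == "theta_normalization" else float(val)
        return cls(**kwargs)


@dataclass
class EquilibriumState:
    """Steady-state tracer fields and rate diagnostics.

    ``concentrations`` maps tracer names to per-wet-box fields
    (mol m^-3 or mol-eq m^-3); ``production`` and ``remineralization``
    map organic pool names to volumetric rate fields (mol m^-3 s^-1).
    ``diagnostics`` carries gamma, r_C:P, and the per-box b and k
    fields actually used.
    """

    concentrations: dict[str, np.ndarray]
    production: dict[str, np.ndarray]
    remineralization: dict[str, np.ndarray]
    diagnostics: dict[str, np.ndarray]
    params: CycleParameters
    grid: Grid

    def bulk_doc(self) -> np.ndarray:
        """Bulk DOC = semilabile + labile + refractory model pools."""
        c = self.concentrations
        return c["DOCs"] + c["DOCl"] + c["DOCr"]

    def production_integral(self, pool: str) -> float:
        """Global production of ``pool`` in mol s^-1."""
        return float(self.production[pool] @ self.grid.box_volume)

    def remin_integral(self, pool: str) -> float:
        return float(self.remineralization[pool] @ self.grid.box_volume)

    def total_production(self, element: str) -> float:
        """Global organic production of an element (mol s^-1)."""
        return sum(
            self.production_integral(p)
            for p in ELEMENT_POOLS[element]
            if p in self.production
        )

    def to_dataset(self) -> xr.Dataset:
        data = {}
        for name, arr in self.concentrations.items():
            data[name] = ("box", arr)
        for name, arr in self.production.items():
            data[f"prod_{name}"] = ("box", arr)
        for name, arr in self.remineralization.items():
            data[f"remin_{name}"] = ("box", arr)
        for name, arr in self.diagnostics.items():
            if np.ndim(arr) == 1 and len(arr) == self.grid.n_boxes:
                data[f"diag_{name}"] = ("box", np.asarray(arr, float))
        data["volume"] = ("box", self.grid.box_volume)
        data["depth"] = ("box", self.grid.box_depth)
        data["lat"] = ("box", self.grid.box_lat)
        data["lon"] = ("box", self.grid.box_lon)
        return xr.Dataset(
            data,
            attrs={
                "concentration_units": "mol m-3",
                "rate_units": "mol m-3 s-1",
            },
        )


# ---------------------------------------------------------------------------
# parameterizations
# ---------------------------------------------------------------------------


def normalized_surface_temperature(
    T: np.ndarray,
    grid: Grid,
    n_avg_layers: int = 3,
    method: str | None = None,
) -> np.ndarray:
    """Normalized upper-ocean temperature ``theta_bar`` per water column.

    The temperature is volume-averaged over the top ``n_avg_layers``
    model layers of each column (fewer if the grid is shallower, with a
    warning), then normalized across columns: min-max to [0, 1] by
    default, or z-score.  Returns a per-box field constant within each
    column.  A degenerate range (constant temperature) maps to zeros.
    """
    method = method or "minmax"
    if grid.n_layers < n_avg_layers:
        logger.warning(
            "grid has %d layers < %d requested for surface average; "
            "averaging over available layers",
            grid.n_layers,
            n_avg_layers,
        )
    out = np.zeros(grid.n_boxes)
    col_means = []
    cols = grid.columns()
    for col in cols:
        top = col[grid.ilayer[col] < n_avg_layers]
        w = grid.box_volume[top]
        col_means.append(float(np.average(T[top], weights=w)))
    col_means = np.asarray(col_means)
    scale = max(np.abs(col_means).max(), 1.0)
    if method == "minmax":
        rng = col_means.max() - col_means.min()
        theta = (
            np.zeros_like(col_means)
            if rng <= 1e-12 * scale
            else (col_means - col_means.min()) / rng
        )
    elif method == "zscore":
        sd = col_means.std()
        theta = (
            np.zeros_like(col_means)
            if sd <= 1e-12 * scale
            else (col_means - col_means.mean()) / sd
        )
    else:
        raise ValueError(f"unknown normalization {method!r}")
    for col, th in zip(cols, theta):
        out[col] = th
    return out


def martin_b(theta_bar: np.ndarray, b0: float, btheta: float) -> np.ndarray:
    """Martin exponent field ``b = b0 + btheta * theta_bar``."""
    theta_bar = np.asarray(theta_bar, float)
    if not np.all(np.isfinite(theta_bar)):
        raise ValueError("theta_bar must be finite")
    b = b0 + btheta * theta_bar
    if np.any(b <= 0):
        raise ParameterDomainError("Martin exponent b must be positive everywhere")
    return b


def q10_rate(T: np.ndarray, kd: float, q10: float, t0: float = 30.0) -> np.ndarray:
    """Q10 rate law ``k = kd * Q10^((T - T0)/10)`` (s^-1)."""
    if kd < 0:
        raise ParameterDomainError("kd must be non-negative")
    if q10 < 1.0:
        raise ParameterDomainError("Q10 must be >= 1")
    return kd * q10 ** ((np.asarray(T, float) - t0) / 10.0)


def cp_ratio(dip: np.ndarray, cc: float, dd: float) -> np.ndarray:
    """Uptake stoichiometry ``r_C:P = 1 / (cc [DIP] + dd)`` (mol C : mol P)."""
    denom = cc * np.asarray(dip, float) + dd
    if np.any(denom <= 0):
        raise ParameterDomainError("cc*[DIP] + dd must be positive everywhere")
    return 1.0 / denom


def uptake_coefficient(
    satellite_npp: np.ndarray,
    surface_dip_obs: np.ndarray,
    r_cp_obs: np.ndarray,
    euphotic_mask: np.ndarray,
) -> np.ndarray:
    """Empirical uptake rate coefficient ``gamma`` (s^-1).

    ``gamma = NPP / (r_C:P(DIP_obs) * DIP_obs)`` per euphotic box, so
    that P uptake ``gamma * DIP`` reproduces the satellite NPP when the
    modeled DIP matches the observed surface climatology; zero outside
    the euphotic zone.
    """
    npp = np.asarray(satellite_npp, float)
    dip = np.asarray(surface_dip_obs, float)
    gamma = np.zeros_like(npp)
    m = np.asarray(euphotic_mask, bool)
    bad = m & (npp > 0) & (dip <= 0)
    if np.any(bad):
        raise ValueError("surface DIP observation is zero where NPP is positive")
    active = m & (npp > 0)
    gamma[active] = npp[active] / (r_cp_obs[active] * dip[active])
    return gamma


def _column_redistribution(
    grid: Grid, profile_fraction
) -> sp.csr_matrix:
    """Sparse map from euphotic volumetric production to subsurface remin.

    ``profile_fraction(col, z_interfaces)`` returns the fraction of the
    column export flux remaining at each interface depth below the
    export depth z0 (fraction 1 at z0).  The flux lost across a layer
    remineralizes there; flux reaching the seafloor remineralizes in
    the bottom wet box (no burial), so the map conserves mass exactly.
    """
    rows, cols_, vals = [], [], []
    v = grid.box_volume
    for col in grid.columns():
        lay = grid.ilayer[col]
        eup = col[lay < grid.n_euphotic_layers]
        sub = col[lay >= grid.n_euphotic_layers]
        if len(eup) == 0:
            continue
        if len(sub) == 0:
            # column no deeper than the euphotic zone: instant recycling
            # into the deepest euphotic box
            tgt = eup[-1]
            for e in eup:
                rows.append(tgt); cols_.append(e); vals.append(v[e] / v[tgt])
            continue
        z0 = grid.euphotic_depth
        interfaces = grid.layer_interfaces[
            grid.n_euphotic_layers : grid.n_euphotic_layers + len(sub) + 1
        ]
        frac = profile_fraction(col, interfaces, z0)  # len(sub)+1, frac[0] == 1
        layer_frac = frac[:-1] - frac[1:]
        layer_frac[-1] += frac[-1]  # seafloor flux -> bottom wet box
        for e in eup:
            for s_box, lf in zip(sub, layer_frac):
                if lf != 0.0:
                    rows.append(s_box); cols_.append(e)
                    vals.append(lf * v[e] / v[s_box])
    n = grid.n_boxes
    return sp.coo_matrix((vals, (rows, cols_)), shape=(n, n)).tocsr()


def particle_operator(b: np.ndarray, grid: Grid) -> sp.csr_matrix:
    """Martin-curve redistribution of particulate export.

    Maps a volumetric production-rate field (euphotic boxes) to the
    volumetric remineralization-rate field below, using the power law
    ``f(z) = f(z0) (z / z0)^(-b)`` with the column-top value of ``b``.
    Flux reaching the seafloor remineralizes in the bottom wet box, so
    the volume integral of the output equals the column export exactly.
    """
    b = np.asarray(b, float)
    if np.any(b <= 0):
        raise ParameterDomainError("Martin exponent b must be positive")

    def frac(col, interfaces, z0):
        return (interfaces / z0) ** (-b[col[0]])

    return _column_redistribution(grid, frac)


def dissolution_operator(scale: float, grid: Grid) -> sp.csr_matrix:
    """Exponential-profile redistribution for sinking PIC.

    Flux below the export depth decays as ``exp(-(z - z0)/scale)``;
    the remainder dissolves in the bottom wet box.
    """
    if scale <= 0:
        raise ParameterDomainError("dissolution scale must be positive")

    def frac(col, interfaces, z0):
        return np.exp(-(interfaces - z0) / scale)

    return _column_redistribution(grid, frac)


def flux_weighted_mean(
    field: np.ndarray, weight: np.ndarray, volume: np.ndarray
) -> float:
    """Volume- and weight-averaged scalar, ``sum(f w v) / sum(w v)``."""
    w = np.asarray(weight, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    denom = float(w @ volume)
    if denom == 0:
        raise ValueError("total weight is zero")
    return float((np.asarray(field, float) * w) @ volume / denom)


# ---------------------------------------------------------------------------
# steady-state solves
# ---------------------------------------------------------------------------


def _particle_conc_diagnostic(
    grid: Grid, production: np.ndarray, frac_op_b: np.ndarray | None,
    scale: float | None, sinking_speed: float,
) -> np.ndarray:
    """Diagnostic particle concentration = flux(z_center) / sinking speed."""
    conc = np.zeros(grid.n_boxes)
    v = grid.box_volume
    for col in grid.columns():
        lay = grid.ilayer[col]
        eup = col[lay < grid.n_euphotic_layers]
        sub = col[lay >= grid.n_euphotic_layers]
        export = float(production[eup] @ v[eup])  # mol s^-1
        if export == 0 or len(sub) == 0:
            continue
        z0 = grid.euphotic_depth
        zc = grid.box_depth[sub]
        if frac_op_b is not None:
            fr = (zc / z0) ** (-frac_op_b[col[0]])
        else:
            fr = np.exp(-(zc - z0) / scale)
        conc[sub] = export * fr / (grid.box_area[sub] * sinking_speed)
    return conc


def solve_p_cycle(
    params: CycleParameters,
    A: sp.spmatrix,
    forcing: ForcingFields,
    grid: Grid,
    dip_inventory: float | None = None,
) -> EquilibriumState:
    """Steady state of the coupled DIP / POP / DOP / labile-DOP system.

    The linear system is singular (transport plus closed biogeochemical
    sources conserves total P), so one DIP equation — for the
    largest-volume box, whose balance is implied by global conservation
    — is replaced by the inventory constraint pinning the global
    volume-weighted mean DIP to ``dip_inventory``.
    """
    params.validate()
    if dip_inventory is None:
        dip_inventory = params.dip_inventory
    n = grid.n_boxes
    v = grid.box_volume
    A = sp.csr_matrix(A)

    theta = normalized_surface_temperature(
        forcing.temperature, grid, method=params.theta_normalization
    )
    b_p = martin_b(theta, params.bP0, params.bPtheta)
    k_p = q10_rate(forcing.temperature, params.kdP, params.Q10P, params.T0)
    r_cp_obs = np.full(n, 1.0 / params.dd)
    eup = grid.euphotic_mask
    r_cp_obs[eup] = cp_ratio(forcing.surface_dip_obs[eup], params.cc, params.dd)
    gamma = uptake_coefficient(
        forcing.satellite_npp, forcing.surface_dip_obs, r_cp_obs, eup
    )

    s_p = particle_operator(b_p, grid)
    f_pop = 1.0 - params.sigma_dop - params.sigma_dopl
    G = sp.diags(gamma)
    Kp = sp.diags(k_p)
    Il = params.kappa_l * sp.identity(n)

    M = sp.bmat(
        [
            [A - G + f_pop * (s_p @ G), Kp, Il],
            [params.sigma_dop * G, A - Kp, None],
            [params.sigma_dopl * G, None, A - Il],
        ],
        format="csr",
    )
    rhs = np.zeros(3 * n)
    # replace the DIP balance of the largest box with the inventory constraint
    pin = int(np.argmax(v))
    M = M.tolil()
    M.rows[pin] = list(range(n))
    M.data[pin] = list(v / v.sum())
    M = M.tocsr()
    rhs[pin] = dip_inventory

    try:
        x = spla.splu(M.tocsc()).solve(rhs)
    except RuntimeError as exc:
        raise SolverDiagnosticError(
            "phosphorus steady-state solve failed (singular system: use the "
            "inventory constraint closure)"
        ) from exc
    dip, dop, dopl = x[:n], x[n : 2 * n], x[2 * n :]
    # pools with no production are exactly empty (solver leaves dust)
    if params.sigma_dop == 0.0:
        dop = np.zeros(n)
    if params.sigma_dopl == 0.0:
        dopl = np.zeros(n)
    tol = 1e-6 * dip_inventory
    worst = min(dip.min(), dop.min(), dopl.min())
    if worst < -tol:
        raise SolverDiagnosticError(
            f"negative P concentration beyond tolerance: min {worst:.3e} mol m-3"
        )

    uptake = gamma * dip
    prod = {
        "POP": f_pop * uptake,
        "DOP": params.sigma_dop * uptake,
        "DOPl": params.sigma_dopl * uptake,
    }
    remin = {
        "POP": np.asarray(s_p @ prod["POP"]),
        "DOP": k_p * dop,
        "DOPl": params.kappa_l * dopl,
    }
    pop_conc = _particle_conc_diagnostic(
        grid, prod["POP"], b_p, None, params.particle_sinking_speed
    )
    return EquilibriumState(
        concentrations={"DIP": dip, "DOP": dop, "DOPl": dopl, "POP": pop_conc},
        production=prod,
        remineralization=remin,
        diagnostics={
            "gamma": gamma,
            "theta_bar": theta,
            "b_P": b_p,
            "k_P": k_p,
            "r_cp_obs": r_cp_obs,
        },
        params=params,
        grid=grid,
    )


def solve_c_cycle(
    params: CycleParameters,
    A: sp.spmatrix,
    p_state: EquilibriumState,
    forcing: ForcingFields,
    grid: Grid,
) -> EquilibriumState:
    """Steady state of the carbon (DIC, ALK, PIC, POC, 3xDOC) and O2 tracers.

    Returns a combined state carrying both the phosphorus fields from
    ``p_state`` and the new carbon/oxygen fields, so downstream
    consumers see all tracers in one object.
    """
    params.validate()
    n = grid.n_boxes
    v = grid.box_volume
    A = sp.csr_matrix(A)
    eup = grid.euphotic_mask
    T = forcing.temperature

    dip = p_state.concentrations["DIP"]
    gamma = p_state.diagnostics["gamma"]
    r_cp = cp_ratio(dip, params.cc, params.dd)
    u_p = gamma * dip                       # total organic P production
    u_c = r_cp * u_p                        # non-labile organic C production

    f_poc = 1.0 - params.sigma_docs - params.sigma_docr
    prod = {
        "POC": f_poc * u_c,
        "DOCs": params.sigma_docs * u_c,
        "DOCr": params.sigma_docr * u_c,
    }
    resid = forcing.satellite_npp - u_c
    if np.any(resid < 0):
        deficit = float(np.minimum(resid, 0.0) @ v)
        log = logger.warning if np.all(resid[eup] <= 0) else logger.debug
        log(
            "modeled non-labile C production exceeds satellite NPP in %d boxes "
            "(clamped labile production; integrated deficit %.3e mol C s^-1)",
            int((resid < 0).sum()),
            -deficit,
        )
    prod["DOCl"] = np.clip(resid, 0.0, None)

    theta = p_state.diagnostics["theta_bar"]
    b_c = martin_b(theta, params.bC0, params.bCtheta)
    k_c = q10_rate(T, params.kdC, params.Q10C, params.T0)
    s_c = particle_operator(b_c, grid)

    def dissolved_solve(k_field, source):
        # (A - diag(k)) c = -source  (strictly dissipative, nonsingular)
        if not np.any(source > 0):
            return np.zeros(n)
        mat = (A - sp.diags(k_field)).tocsc()
        return spla.splu(mat).solve(-source)

    docs = dissolved_solve(k_c, prod["DOCs"])
    docr = dissolved_solve(np.full(n, params.kappa_r), prod["DOCr"])
    docl = dissolved_solve(np.full(n, params.kappa_l), prod["DOCl"])

    remin = {
        "POC": np.asarray(s_c @ prod["POC"]),
        "DOCs": k_c * docs,
        "DOCr": params.kappa_r * docr,
        "DOCl": params.kappa_l * docl,
    }

    # particulate inorganic carbon
    prod["PIC"] = params.pic_rain_ratio * prod["POC"]
    d_pic = dissolution_operator(params.pic_dissolution_scale, grid)
    pic_diss = np.asarray(d_pic @ prod["PIC"])

    lam = params.surface_restore_rate * eup.astype(float)
    Lam = sp.diags(lam)

    def restored_solve(source, ref_value):
        mat = (A - Lam).tocsc()
        return spla.splu(mat).solve(-(source + lam * ref_value))

    total_c_remin = sum(remin[p] for p in C_POOLS)
    dic_src = total_c_remin + pic_diss - u_c - prod["DOCl"] - prod["PIC"]
    dic = restored_solve(dic_src, params.dic_surface_ref)
    alk = restored_solve(2.0 * (pic_diss - prod["PIC"]), params.alk_surface_ref)

    # oxygen: photosynthetic source, respiratory sink, restore to a
    # linearized saturation at the surface
    total_p_remin = sum(p_state.remineralization[p] for p in P_POOLS)
    o2_sat = np.clip(0.35 - 0.0053 * T, 0.05, None)
    o2_src = params.o2_to_p * (u_p - total_p_remin)
    o2 = spla.splu((A - Lam).tocsc()).solve(-(o2_src + lam * o2_sat))

    worst = min(docs.min(), docl.min(), docr.min(), dic.min())
    if worst < -1e-6 * params.dic_surface_ref:
        raise SolverDiagnosticError(
            f"negative C concentration beyond tolerance: min {worst:.3e}"
        )
    if o2.min() < 0:
        # linear stoichiometric O2 has no respiration cutoff; negative
        # values in poorly ventilated boxes represent an oxygen debt
        # (the usual convention for linear O2 models) and are reported,
        # not raised.
        logger.info("O2 minimum %.3e mol m-3 (oxygen debt in %d boxes)",
                    float(o2.min()), int((o2 < 0).sum()))

    poc_conc = _particle_conc_diagnostic(
        grid, prod["POC"], b_c, None, params.particle_sinking_speed
    )
    pic_conc = _particle_conc_diagnostic(
        grid, prod["PIC"], None, params.pic_dissolution_scale,
        params.particle_sinking_speed,
    )

    concentrations = dict(p_state.concentrations)
    concentrations.update(
        {
            "DIC": dic,
            "ALK": alk,
            "PIC": pic_conc,
            "POC": poc_conc,
            "DOCs": docs,
            "DOCl": docl,
            "DOCr": docr,
            "O2": o2,
        }
    )
    production = dict(p_state.production)
    production.update(prod)
    reminz = dict(p_state.remineralization)
    reminz.update(remin)
    reminz["PIC"] = pic_diss
    diagnostics = dict(p_state.diagnostics)
    diagnostics.update({"r_cp": r_cp, "b_C": b_c, "k_C": k_c})
    return EquilibriumState(
        concentrations=concentrations,
        production=production,
        remineralization=reminz,
        diagnostics=diagnostics,
        params=params,
        grid=grid,
    )


def solve_equilibrium(
    params: CycleParameters,
    A: sp.spmatrix,
    forcing: ForcingFields,
    grid: Grid,
    dip_inventory: float | None = None,
) -> EquilibriumState:
    """Convenience wrapper: P cycle then C/O2 cycle."""
    p_state = solve_p_cycle(params, A, forcing, grid, dip_inventory)
    return solve_c_cycle(params, A, p_state, forcing, grid)
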