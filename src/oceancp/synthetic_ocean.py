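"""Synthetic forcing fields and observations with known ground truth.

This module generates every external input the cycle solves and the
inversion need — temperature, net primary production (NPP), a surface
phosphate climatology, and noisy "observations" of the six constrained
tracers — so that parameter recovery and sequestration analyses can be
exercised end-to-end on a desk-scale ocean without any downloads.

Defaults emulate the global-mean conditions of the full-scale analysis:
a prescribed global NPP of 55 Pg C y^-1, a surface-warm temperature
profile decaying over a ~500 m thermocline, and a surface phosphate
field of a few tenths of a mmol m^-3 enriched toward high latitudes
(mimicking upwelling/subpolar nutrient supply).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .constants import pg_per_year_to_mol_per_s
from .grid_transport import Grid

__all__ = ["ForcingFields", "ObservationSet", "make_forcing", "make_observations"]

#: tracers the inversion constrains; bulk DOC is the sum of the three
#: modelled DOC pools.
OBSERVED_TRACERS = ("DIP", "DOP", "DIC", "DOC", "ALK", "O2")


@dataclass
class ForcingFields:
    """External forcing: temperature, NPP and surface DIP climatology.

    ``satellite_npp`` is a volumetric carbon fixation rate
    (mol C m^-3 s^-1), nonzero only in euphotic boxes; its global
    volume integral equals the prescribed total.
    """

    temperature: np.ndarray      # degC per wet box
    satellite_npp: np.ndarray    # mol C m^-3 s^-1
    surface_dip_obs: np.ndarray  # mol m^-3, euphotic boxes (0 elsewhere)
    npp_total_pg_y: float
    seed: int = 0

    def npp_integral_pg_y(self, grid: Grid) -> float:
        from .constants import mol_per_s_to_pg_per_year

        return mol_per_s_to_pg_per_year(
            float(self.satellite_npp @ grid.box_volume), "C"
        )

    def to_dataset(self, grid: Grid) -> xr.Dataset:
        return xr.Dataset(
            {
                "temperature": ("box", self.temperature),
                "satellite_npp": ("box", self.satellite_npp),
                "surface_dip_obs": ("box", self.surface_dip_obs),
                "depth": ("box", grid.box_depth),
                "lat": ("box", grid.box_lat),
                "lon": ("box", grid.box_lon),
                "volume": ("box", grid.box_volume),
            },
            attrs={
                "npp_total_pg_y": self.npp_total_pg_y,
                "seed": self.seed,
                "temperature_units": "degC",
                "npp_units": "mol C m-3 s-1",
                "dip_units": "mol m-3",
            },
        )


@dataclass
class ObservationSet:
    """Gridded tracer observations with missingness masks.

    ``values[x]`` holds the observed concentration of tracer ``x`` per
    wet box; ``observed[x]`` is False where the observation is missing
    (precision weights are zero exactly there — see
    :func:`oceancp.inversion.precision_weights`).
    """

    values: dict[str, np.ndarray]
    observed: dict[str, np.ndarray]
    noise_sd: dict[str, float]
    provenance: str = "synthetic"
    seed: int | None = None

    def tracers(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_dataframe(self, grid: Grid) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "lat": grid.box_lat,
                "lon": grid.box_lon,
                "depth": grid.box_depth,
                "volume": grid.box_volume,
            }
        )
        for x in self.values:
            df[x] = self.values[x]
            df[f"{x}_observed"] = self.observed[x]
        return df


def _meridional_envelope(lat: np.ndarray, amplitude: float) -> np.ndarray:
    """Warm-equator / cold-pole modulation, peak-to-pole span = amplitude."""
    return amplitude * (np.cos(np.deg2rad(lat)) - 0.5)


def make_forcing(
    grid: Grid,
    surface_t: float = 24.0,
    deep_t: float = 2.0,
    thermocline_scale: float = 500.0,
    meridional_amplitude: float = 16.0,
    npp_total_pg_y: float = 55.0,
    dip_surface_mean: float = 5.0e-4,
    npp_noise: float = 0.2,
    seed: int = 0,
) -> ForcingFields:
    """Generate temperature, NPP and surface-DIP forcing on ``grid``.

    Temperature follows an exponential thermocline,
    ``T(z, lat) = deep_t + (surface_t + envelope(lat) - deep_t) * exp(-z / thermocline_scale)``,
    so it decreases with depth everywhere.  Surface DIP is enriched
    toward high latitudes (nutrient-rich subpolar water) around
    ``dip_surface_mean``.  The NPP field is shaped by the surface DIP
    climatology times a latitudinal light envelope with a log-normal
    spatial perturbation (sd ``npp_noise``), then rescaled so its global
    integral equals ``npp_total_pg_y`` exactly; only the shape is
    heuristic, the total is prescribed.

    Deterministic for a fixed ``seed``.
    """
    if npp_total_pg_y <= 0:
        raise ValueError("npp_total_pg_y must be positive")
    if dip_surface_mean <= 0:
        raise ValueError("dip_surface_mean must be positive")
    rng = np.random.default_rng(seed)

    env = _meridional_envelope(grid.box_lat, meridional_amplitude)
    t_surf = surface_t + env - deep_t
    temperature = deep_t + t_surf * np.exp(-grid.box_depth / thermocline_scale)

    eup = grid.euphotic_mask
    # high-latitude nutrient enrichment, mean fixed to dip_surface_mean
    dip_shape = 0.4 + 1.2 * np.sin(np.deg2rad(np.abs(grid.box_lat))) ** 2
    surface_dip = np.zeros(grid.n_boxes)
    surface_dip[eup] = dip_surface_mean * dip_shape[eup] / dip_shape[eup].mean()

    light = np.cos(np.deg2rad(grid.box_lat)) + 0.3
    shape = np.zeros(grid.n_boxes)
    shape[eup] = surface_dip[eup] * light[eup]
    if npp_noise > 0:
        shape[eup] *= np.exp(npp_noise * rng.standard_normal(int(eup.sum())))
    total_target = pg_per_year_to_mol_per_s(npp_total_pg_y, "C")
    npp = shape * (total_target / float(shape @ grid.box_volume))

    return ForcingFields(
        temperature=temperature,
        satellite_npp=npp,
        surface_dip_obs=surface_dip,
        npp_total_pg_y=npp_total_pg_y,
        seed=seed,
    )


def make_observations(
    equilibrium,
    noise_sd: float | dict[str, float] = 0.05,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Sample noisy observations of the six constrained tracers.

    Noise is multiplicative log-normal with a mean-preserving shift,
    ``obs = c * exp(sd * Z - sd^2 / 2)``, so concentrations stay
    positive and ``noise_sd = 0`` returns the model fields exactly.
    ``missing_fraction`` marks ``round(f * n)`` boxes per tracer as
    unobserved (weight zero downstream), chosen independently per
    tracer but reproducibly per seed.

    ``equilibrium`` must provide all six observed tracers; bulk DOC is
    the sum of the semilabile, labile and refractory model pools.
    """
    from .element_cycles import EquilibriumState  # noqa: F401  (type only)

    rng = np.random.default_rng(seed)
    if not isinstance(noise_sd, dict):
        noise_sd = {x: float(noise_sd) for x in OBSERVED_TRACERS}
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")

    values: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for x in OBSERVED_TRACERS:
        try:
            c = equilibrium.bulk_doc() if x == "DOC" else equilibrium.concentrations[x]
        except KeyError as exc:
            raise ValueError(f"equilibrium is missing observed tracer {x!r}") from exc
        c = np.asarray(c, dtype=float)
        sd = noise_sd.get(x, 0.0)
        obs = c.copy()
        if sd > 0:
            obs = c * np.exp(sd * rng.standard_normal(len(c)) - 0.5 * sd**2)
        mask = np.ones(len(c), dtype=bool)
        n_missing = int(round(missing_fraction * len(c)))
        if n_missing:
            mask[rng.choice(len(c), size=n_missing, replace=False)] = False
        values[x] = obs
        observed[x] = mask
    return ObservationSet(
        values=values,
        observed=observed,
        noise_sd=dict(noise_sd),
        provenance=f"synthetic-seed-{seed}",
        seed=seed,
    )
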