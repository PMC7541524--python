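"""Gravity design matrices for the longitudinal dyadic flow model.

The response is the log-transformed flow z = ln(1 + y); regressors per
ordered dyad-year are an intercept, the (untransformed) trade-agreement
indicator, log centroid distance, and sender/receiver blocks of logged
GDP per capita, population, pasture area and dietary-energy-supply
adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tradeflow.errors import AssemblyError, ValidationError
from tradeflow.trade_io import TradeTensor

EARTH_RADIUS_KM = 6371.0

#: design-matrix column names, in order
DESIGN_COLUMNS = (
    "intercept",
    "agreement",
    "ln_distance",
    "ln_gdp_pc_s",
    "ln_gdp_pc_r",
    "ln_population_s",
    "ln_population_r",
    "ln_pasture_s",
    "ln_pasture_r",
    "ln_des_s",
    "ln_des_r",
)

COUNTRY_COVARIATES = ("gdp_pc", "population", "pasture_km2", "des_pct")


@dataclass
class CountryPanel:
    """Node-level covariates: one row per country-year plus fixed centroids.

    ``data`` columns: country, year, gdp_pc, population, pasture_km2,
    des_pct.  ``coords`` columns: country, lat, lon.
    """

    data: pd.DataFrame
    coords: pd.DataFrame

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())


@dataclass
class DyadPanel:
    """Pair-level covariates.

    ``agreements`` columns: sender, receiver, year, agreement (0/1),
    symmetric within a dyad-year.  ``distances`` columns: sender, receiver,
    distance_km, symmetric and positive.
    """

    agreements: pd.DataFrame
    distances: pd.DataFrame


@dataclass
class DesignMatrices:
    """Per-year stacked design for the dyadic model.

    ``x`` has shape (T, D, 11) and ``z`` shape (T, D) where D = N(N-1)
    ordered dyads in lexicographic (sender, receiver) order.  ``senders``
    and ``receivers`` map each dyad row to indices into ``countries``.
    """

    countries: list[str]
    years: list[int]
    x: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    senders: np.ndarray = field(repr=False)
    receivers: np.ndarray = field(repr=False)
    columns: tuple[str, ...] = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        n, t = len(self.countries), len(self.years)
        d = n * (n - 1)
        if self.x.shape != (t, d, len(self.columns)):
            raise ValidationError(f"x shape {self.x.shape} != ({t}, {d}, 11)")
        if self.z.shape != (t, d):
            raise ValidationError(f"z shape {self.z.shape} != ({t}, {d})")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.z))):
            raise ValidationError("design contains non-finite entries")

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_dyads(self) -> int:
        return self.x.shape[1]

    def dyad_labels(self) -> list[tuple[str, str]]:
        return [
            (self.countries[i], self.countries[j])
            for i, j in zip(self.senders, self.receivers)
        ]


def great_circle_distance(lat1, lon1, lat2, lon2):
    """Haversine distance in km on a sphere of radius 6371 km.

    Accepts scalars or arrays (degrees).  Symmetric, zero iff the points
    coincide.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValidationError("latitude out of [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValidationError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def transform_response(tensor: TradeTensor) -> np.ndarray:
    """z = ln(1 + y), elementwise over the tensor; z = 0 iff y = 0."""
    y = tensor.values
    if np.any(y < 0):
        raise ValidationError("negative flow quantities")
    return np.log1p(y)


def inverse_transform_response(z: np.ndarray) -> np.ndarray:
    """y = exp(z) - 1, floored at zero."""
    return np.maximum(np.expm1(z), 0.0)


def distances_from_coords(coords: pd.DataFrame) -> pd.DataFrame:
    """All ordered-pair centroid distances from a country/lat/lon table."""
    c = coords.sort_values("country").reset_index(drop=True)
    codes = c["country"].to_numpy()
    lat = c["lat"].to_numpy(dtype=float)
    lon = c["lon"].to_numpy(dtype=float)
    i, j = np.meshgrid(np.arange(len(codes)), np.arange(len(codes)), indexing="ij")
    mask = i != j
    i, j = i[mask], j[mask]
    return pd.DataFrame(
        {
            "sender": codes[i],
            "receiver": codes[j],
            "distance_km": great_circle_distance(lat[i], lon[i], lat[j], lon[j]),
        }
    )


def build_design_matrices(
    panel: CountryPanel, dyads: DyadPanel, tensor: TradeTensor
) -> DesignMatrices:
    """Assemble response and covariate arrays for every ordered dyad-year.

    The agreement indicator enters untransformed; every other non-intercept
    covariate is natural-logged.  Zero pasture area is floored at 1 km²
    before logging so logs stay finite.  Rows are ordered lexicographically
    by (sender, receiver) country code.
    """
    countries = sorted(tensor.countries)
    years = list(tensor.years)
    n, t = len(countries), len(years)
    d = n * (n - 1)

    # country-year covariate lookup, positional by sorted country order
    cov = panel.data.set_index(["country", "year"]).sort_index()
    values = np.empty((n, t, len(COUNTRY_COVARIATES)))
    for ci, c in enumerate(countries):
        for ti, y in enumerate(years):
            try:
                row = cov.loc[(c, y)]
            except KeyError:
                raise AssemblyError(f"missing covariates for {c!r} in {y}")
            vals = row[list(COUNTRY_COVARIATES)].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise AssemblyError(f"missing covariate value for {c!r} in {y}")
            values[ci, ti] = vals
    # floor pasture at 1 km^2 pre-log
    values[:, :, 2] = np.maximum(values[:, :, 2], 1.0)
    if np.any(values <= 0):
        raise AssemblyError("covariates must be strictly positive before logging")
    log_cov = np.log(values)

    si, ri = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = si != ri
    senders, receivers = si[mask], ri[mask]

    dist_lookup = {
        (s, r): dk
        for s, r, dk in dyads.distances[["sender", "receiver", "distance_km"]].itertuples(
            index=False
        )
    }
    dist = np.empty(d)
    for k, (i, j) in enumerate(zip(senders, receivers)):
        key = (countries[i], countries[j])
        if key not in dist_lookup:
            raise AssemblyError(f"missing distance for dyad {key}")
        dist[k] = dist_lookup[key]
    if np.any(dist <= 0):
        raise ValidationError("distances must be positive for distinct countries")

    agr = dyads.agreements.set_index(["sender", "receiver", "year"])["agreement"]
    agreement = np.zeros((t, d))
    for ti, y in enumerate(years):
        for k, (i, j) in enumerate(zip(senders, receivers)):
            key = (countries[i], countries[j], y)
            try:
                agreement[ti, k] = float(agr.loc[key])
            except KeyError:
                raise AssemblyError(f"missing agreement for dyad {key}")

    # tensor may list countries in a different order than sorted
    perm = np.array([tensor.countries.index(c) for c in countries])
    zfull = transform_response(tensor)[np.ix_(perm, perm)]  # (n, n, t)
    z = zfull[senders, receivers, :].T.copy()  # (t, d)

    x = np.empty((t, d, len(DESIGN_COLUMNS)))
    x[:, :, 0] = 1.0
    x[:, :, 1] = agreement
    x[:, :, 2] = np.log(dist)[None, :]
    for ti in range(t):
        x[ti, :, 3] = log_cov[senders, ti, 0]
        x[ti, :, 4] = log_cov[receivers, ti, 0]
        x[ti, :, 5] = log_cov[senders, ti, 1]
        x[ti, :, 6] = log_cov[receivers, ti, 1]
        x[ti, :, 7] = log_cov[senders, ti, 2]
        x[ti, :, 8] = log_cov[receivers, ti, 2]
        x[ti, :, 9] = log_cov[senders, ti, 3]
        x[ti, :, 10] = log_cov[receivers, ti, 3]

    return DesignMatrices(
        countries=countries,
        years=years,
        x=x,
        z=z,
        senders=senders,
        receivers=receivers,
    )
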