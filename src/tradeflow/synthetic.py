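"""Synthetic country/dyad panels and trade tensors with known parameters.

Emulates the FAO-style inputs so every downstream stage (I/O, design,
model fit, clustering, robustness) is testable without any download: the
trade tensor is simulated from the same generative model the sampler fits,
so the true latent states and parameters are available for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from tradeflow.design import (
    CountryPanel,
    DyadPanel,
    build_design_matrices,
    distances_from_coords,
)
from tradeflow.errors import ConfigurationError
from tradeflow.netmodel import LatentStates
from tradeflow.trade_io import TradeTensor

DEFAULT_COVARIATE_RANGES = {
    "gdp_pc": (500.0, 80_000.0),  # constant-2010 USD
    "population": (100.0, 1_400_000.0),  # thousands
    "pasture_km2": (100.0, 5_000_000.0),
    "des_pct": (80.0, 160.0),
    "lat": (-60.0, 70.0),
    "lon": (-179.0, 180.0),
}


def _spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(m))))


@dataclass
class SyntheticConfig:
    """Generative-model parameters for the synthetic panels and tensor.

    ``beta`` may be a single length-11 coefficient vector (recycled across
    years) or a (n_years, 11) array.  ``phi_matrix`` is the 2x2 VAR(1)
    transition of the stacked (sender, receiver) effect; ``phi_gg`` the
    AR(1) coefficient of the dyadic residual pair; ``rho`` the reciprocity
    correlation within an unordered dyad.
    """

    n_countries: int
    n_years: int
    seed: int = 0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(11))
    phi_matrix: np.ndarray = field(default_factory=lambda: np.eye(2) * 0.5)
    phi_gg: float = 0.0
    rho: float = 0.0
    sigma2_gamma: float = 1.0
    sigma_eps: np.ndarray = field(default_factory=lambda: np.eye(2) * 0.1)
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    agreement_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ConfigurationError("n_countries must be >= 2")
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.ndim == 1:
            if self.beta.shape[0] != 11:
                raise ConfigurationError("beta vector must have length 11")
            self.beta = np.tile(self.beta, (self.n_years, 1))
        elif self.beta.shape != (self.n_years, 11):
            raise ConfigurationError("per-year beta must be (n_years, 11)")
        self.phi_matrix = np.asarray(self.phi_matrix, dtype=float).reshape(2, 2)
        if _spectral_radius(self.phi_matrix) >= 1.0:
            raise ConfigurationError("phi_matrix must have spectral radius < 1")
        if not abs(self.phi_gg) < 1.0:
            raise ConfigurationError("|phi_gg| must be < 1")
        if not abs(self.rho) < 1.0:
            raise ConfigurationError("|rho| must be < 1")
        if self.sigma2_gamma < 0:
            raise ConfigurationError("sigma2_gamma must be >= 0")
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float).reshape(2, 2)
        if np.any(np.linalg.eigvalsh(self.sigma_eps) < -1e-12):
            raise ConfigurationError("sigma_eps must be positive semi-definite")
        if not 0.0 <= self.agreement_prob <= 1.0:
            raise ConfigurationError("agreement_prob must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("beta", "phi_matrix", "sigma_eps"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def country_codes(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_countries)]

    def year_list(self) -> list[int]:
        return list(range(2000, 2000 + self.n_years))


def generate_country_panel(config: SyntheticConfig) -> tuple[CountryPanel, DyadPanel]:
    """Draw country-year covariates, centroids and dyad-year agreements.

    Covariates are log-uniform within the configured ranges (strictly
    positive); centroids are uniform and constant over years; agreements
    are i.i.d. Bernoulli per unordered dyad-year, recorded symmetrically on
    both ordered directions.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    codes = config.country_codes()
    years = config.year_list()
    n, t = config.n_countries, config.n_years
    ranges = config.covariate_ranges

    def log_uniform(key: str, size) -> np.ndarray:
        lo, hi = ranges[key]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    rows = {
        "country": np.repeat(codes, t),
        "year": np.tile(years, n),
        "gdp_pc": log_uniform("gdp_pc", n * t),
        "population": log_uniform("population", n * t),
        "pasture_km2": log_uniform("pasture_km2", n * t),
        "des_pct": log_uniform("des_pct", n * t),
    }
    data = pd.DataFrame(rows)

    lat_lo, lat_hi = ranges["lat"]
    lon_lo, lon_hi = ranges["lon"]
    coords = pd.DataFrame(
        {
            "country": codes,
            "lat": rng.uniform(lat_lo, lat_hi, size=n),
            "lon": rng.uniform(lon_lo, lon_hi, size=n),
        }
    )
    panel = CountryPanel(data=data, coords=coords)

    senders, receivers, yrs, agr = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            flags = rng.random(t) < config.agreement_prob
            for ti, y in enumerate(years):
                a = int(flags[ti])
                senders += [codes[i], codes[j]]
                receivers += [codes[j], codes[i]]
                yrs += [y, y]
                agr += [a, a]
    agreements = pd.DataFrame(
        {"sender": senders, "receiver": receivers, "year": yrs, "agreement": agr}
    )
    dyads = DyadPanel(agreements=agreements, distances=distances_from_coords(coords))
    return panel, dyads


def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """PSD-tolerant multivariate normal draws (zero covariance allowed)."""
    if np.allclose(cov, 0):
        return np.zeros((size, cov.shape[0]))
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=size, method="eigh")


def simulate_trade_tensor(
    panel: CountryPanel, dyads: DyadPanel, config: SyntheticConfig
) -> tuple[TradeTensor, LatentStates]:
    """Simulate flows from the dyadic mixed-effects gravity model.

    Sender/receiver pairs u_it follow a stationary VAR(1) with transition
    ``phi_matrix`` and innovation covariance ``sigma_eps``; the two dyadic
    effects of an unordered pair follow an AR(1) with coefficient
    ``phi_gg`` whose stationary law is bivariate normal with variance
    ``sigma2_gamma`` and correlation ``rho``.  On the log scale
    z = x'beta_t + s_it + r_jt + gamma_ijt and the stored quantity is
    y = exp(z) - 1 floored at zero.
    """
    rng = np.random.default_rng(config.seed + 1)
    codes = config.country_codes()
    years = config.year_list()
    n, t = config.n_countries, config.n_years

    zero = TradeTensor(codes, years, np.zeros((n, n, t)))
    design = build_design_matrices(panel, dyads, zero)

    phi = config.phi_matrix
    sig_eps = config.sigma_eps
    if np.allclose(sig_eps, 0):
        sigma1 = np.zeros((2, 2))
    else:
        sigma1 = solve_discrete_lyapunov(phi, sig_eps)
    u = np.empty((n, t, 2))
    u[:, 0, :] = _draw_mvn(rng, sigma1, n)
    for ti in range(1, t):
        eps = _draw_mvn(rng, sig_eps, n)
        u[:, ti, :] = u[:, ti - 1, :] @ phi.T + eps
    s = u[:, :, 0].copy()
    r = u[:, :, 1].copy()

    # dyadic pairs: stationary AR(1) with time-invariant marginal law
    sigma_g = config.sigma2_gamma * np.array([[1.0, config.rho], [config.rho, 1.0]])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = len(pairs)
    v = np.empty((m, t, 2))
    v[:, 0, :] = _draw_mvn(rng, sigma_g, m)
    innov_cov = (1.0 - config.phi_gg**2) * sigma_g
    for ti in range(1, t):
        eta = _draw_mvn(rng, innov_cov, m)
        v[:, ti, :] = config.phi_gg * v[:, ti - 1, :] + eta

    gamma = np.zeros((n, n, t))
    for mi, (i, j) in enumerate(pairs):
        gamma[i, j, :] = v[mi, :, 0]
        gamma[j, i, :] = v[mi, :, 1]

    beta = config.beta  # (t, 11)
    z = np.einsum("tdk,tk->td", design.x, beta)
    z += s[design.senders, :].T + r[design.receivers, :].T
    z += gamma[design.senders, design.receivers, :].T

    y = np.zeros((n, n, t))
    y[design.senders, design.receivers, :] = np.maximum(np.expm1(z), 0.0).T
    tensor = TradeTensor(codes, years, y)
    return tensor, LatentStates(s=s, r=r, gamma=gamma)
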