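"""Bayesian longitudinal dyadic mixed-effects network model.

The log-scale flow for an ordered dyad (i, j) in year t is

    z_ijt = x_ijt' beta_t + s_it + r_jt + gamma_ijt

where (s_it, r_it) follows a stationary VAR(1) with 2x2 transition Phi and
innovation covariance Sigma_eps, and the residual pair of an unordered dyad
(gamma_ijt, gamma_jit) is an AR(1) in t (coefficient phi_gg) whose
stationary cross-sectional law has variance sigma2_gamma and reciprocity
correlation rho.  Stacking one unordered dyad's residuals over directions
and years gives covariance Sigma_gamma (x) C_T with C_T[t,t'] =
phi_gg^|t-t'|; the sampler exploits this Kronecker/tridiagonal structure
throughout.

Estimation is a blocked Gibbs sampler: conjugate normal draws for the
stacked per-year coefficients and for each country's 2T-dimensional latent
trajectory, a Metropolis step for (phi_gg, rho, sigma2_gamma) on the
marginal dyad likelihood, a conjugate matrix-regression draw for Phi
(rejected outside the stationary region) and an inverse-Wishart draw for
Sigma_eps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_discrete_lyapunov, solve_triangular
from scipy.stats import invwishart

from tradeflow.design import DesignMatrices
from tradeflow.errors import FitError, ValidationError

LOG2PI = math.log(2.0 * math.pi)

PHI_PARAM_NAMES = ("phi_s", "phi_sr", "phi_rs", "phi_r", "phi_gg")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ModelParams:
    """One complete parameter state of the dyadic model."""

    beta: np.ndarray  # (T, 11)
    phi_matrix: np.ndarray  # 2x2: [[phi_s, phi_sr], [phi_rs, phi_r]]
    phi_gg: float
    rho: float
    sigma2_gamma: float
    sigma_eps: np.ndarray  # 2x2 innovation covariance

    def validate(self) -> None:
        if np.max(np.abs(np.linalg.eigvals(self.phi_matrix))) >= 1.0:
            raise ValidationError("phi_matrix not stationary")
        if not abs(self.phi_gg) < 1.0:
            raise ValidationError("|phi_gg| must be < 1")
        if not abs(self.rho) < 1.0:
            raise ValidationError("|rho| must be < 1")
        if not self.sigma2_gamma > 0:
            raise ValidationError("sigma2_gamma must be > 0")
        if np.any(np.linalg.eigvalsh(self.sigma_eps) <= 0):
            raise ValidationError("sigma_eps must be positive definite")


@dataclass
class LatentStates:
    """Latent sender/receiver effects and dyadic residuals.

    ``s`` and ``r`` are (N, T); ``gamma`` is (N, N, T) with zero diagonal
    (may be ``None`` when not tracked).
    """

    s: np.ndarray
    r: np.ndarray
    gamma: np.ndarray | None = None


@dataclass
class FitConfig:
    """MCMC settings and priors.

    Defaults mirror the chain length used for the reference analysis
    (11,000 iterations, 1,000 burn-in, thinning by 10); tests use reduced
    settings.
    """

    iterations: int = 11_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 0
    beta_prior_sd: float = 100.0
    phi_prior_sd: float = 1.0
    sigma_eps_prior_df: float = 4.0
    sigma_eps_prior_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    sigma2_gamma_prior_shape: float = 2.0
    sigma2_gamma_prior_rate: float = 1.0
    mh_step: float = 0.1
    store_latent: bool = True

    def n_saved(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Saved MCMC output plus chain metadata."""

    beta: np.ndarray  # (S, T, 11)
    phi_matrix: np.ndarray  # (S, 2, 2)
    phi_gg: np.ndarray  # (S,)
    rho: np.ndarray  # (S,)
    sigma2_gamma: np.ndarray  # (S,)
    sigma_eps: np.ndarray  # (S, 2, 2)
    s: np.ndarray | None  # (S, N, T)
    r: np.ndarray | None  # (S, N, T)
    countries: list[str]
    years: list[int]
    columns: tuple[str, ...]
    iterations: int
    burn_in: int
    thin: int
    seed: int

    @property
    def n_saved(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    """Posterior summaries in the two reporting styles used downstream.

    Coefficients: mean + 95% HPD + significance flag (HPD excludes zero).
    Phi parameters: median + equal-tail 2.5/97.5% quantiles.  Latent
    effects: posterior mean per country-year and its time average.
    """

    coefficients: pd.DataFrame
    phi: pd.DataFrame
    sender_effects: pd.DataFrame
    receiver_effects: pd.DataFrame


# ---------------------------------------------------------------------------
# covariance helpers


def ar1_inverse_correlation(phi: float, n: int) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of the AR(1) correlation matrix.

    C[t, t'] = phi^|t-t'|; the inverse is tridiagonal and |C| =
    (1 - phi^2)^(n-1).
    """
    if n == 1:
        return np.array([[1.0]]), 0.0
    one_m = 1.0 - phi * phi
    cinv = np.zeros((n, n))
    idx = np.arange(n)
    cinv[idx, idx] = 1.0 + phi * phi
    cinv[0, 0] = cinv[-1, -1] = 1.0
    cinv[idx[:-1], idx[1:]] = -phi
    cinv[idx[1:], idx[:-1]] = -phi
    return cinv / one_m, (n - 1) * math.log(one_m)


def dyad_residual_loglik(
    gam: np.ndarray, sigma2_gamma: float, rho: float, phi_gg: float
) -> float:
    """Gaussian log-likelihood of stacked dyad residuals.

    ``gam`` has shape (M, 2, T): per unordered dyad the two directed
    residual series.  The 2T covariance is Sigma_gamma (x) C_T; evaluation
    uses the Kronecker factorisation so the cost is O(M T^2) instead of
    O(M T^3).  Matches a dense multivariate-normal evaluation exactly.
    """
    m, two, t = gam.shape
    cinv, logdet_c = ar1_inverse_correlation(phi_gg, t)
    det_sg = sigma2_gamma**2 * (1.0 - rho * rho)
    if det_sg <= 0:
        return -np.inf
    sg_inv = np.array([[1.0, -rho], [-rho, 1.0]]) / (sigma2_gamma * (1.0 - rho * rho))
    e2 = np.einsum("mat,ts,mbs->ab", gam, cinv, gam)
    quad = float(np.sum(sg_inv * e2))
    logdet = t * math.log(det_sg) + 2.0 * logdet_c
    return -0.5 * (quad + m * logdet + m * 2 * t * LOG2PI)


def _var1_prior_precision(
    phi: np.ndarray, sigma_eps: np.ndarray, t: int
) -> np.ndarray:
    """Precision of the stationary VAR(1) path (time-major interleaved).

    Ordering is (s_1, r_1, s_2, r_2, ...); the first block uses the
    stationary covariance so the path prior is time-invariant.
    """
    q = np.linalg.inv(sigma_eps)
    sigma1 = solve_discrete_lyapunov(phi, sigma_eps)
    s1_inv = np.linalg.inv(sigma1)
    ptp = phi.T @ q @ phi
    k = np.zeros((2 * t, 2 * t))
    for ti in range(t):
        sl = slice(2 * ti, 2 * ti + 2)
        if ti == 0:
            k[sl, sl] += s1_inv
        else:
            k[sl, sl] += q
        if ti < t - 1:
            k[sl, sl] += ptp
            nxt = slice(2 * (ti + 1), 2 * (ti + 1) + 2)
            k[sl, nxt] = -phi.T @ q
            k[nxt, sl] = -q @ phi
    return k


# ---------------------------------------------------------------------------
# the Gibbs sampler


def _check_rank(design: DesignMatrices) -> None:
    k = len(design.columns)
    x_all = design.x.reshape(-1, k)
    rank = np.linalg.matrix_rank(x_all)
    for ti, year in enumerate(design.years):
        rank = min(rank, np.linalg.matrix_rank(design.x[ti]))
    if rank < k:
        # name the suspect columns: zero variance or duplicated
        suspects = []
        for ci, name in enumerate(design.columns):
            if ci == 0:
                continue
            col = design.x[:, :, ci]
            if np.allclose(col, col.flat[0]):
                suspects.append(name)
        raise FitError(
            "design matrix is rank deficient"
            + (f"; constant column(s): {', '.join(suspects)}" if suspects else "")
        )


def _pair_arrays(design: DesignMatrices):
    """Reindex ordered-dyad rows into (unordered dyad, direction) arrays."""
    n = design.n_countries
    row_of = {}
    for d, (i, j) in enumerate(zip(design.senders, design.receivers)):
        row_of[(int(i), int(j))] = d
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = len(pairs)
    t, _, k = design.x.shape
    xd = np.empty((m, 2, t, k))
    zd = np.empty((m, 2, t))
    i_arr = np.empty(m, dtype=int)
    j_arr = np.empty(m, dtype=int)
    for mi, (i, j) in enumerate(pairs):
        d0, d1 = row_of[(i, j)], row_of[(j, i)]
        xd[mi, 0] = design.x[:, d0, :]
        xd[mi, 1] = design.x[:, d1, :]
        zd[mi, 0] = design.z[:, d0]
        zd[mi, 1] = design.z[:, d1]
        i_arr[mi], j_arr[mi] = i, j
    return xd, zd, i_arr, j_arr


def gibbs_fit(design: DesignMatrices, config: FitConfig | None = None) -> PosteriorDraws:
    """Run the blocked Gibbs sampler on an assembled design.

    Requires at least two years and three countries.  Fully reproducible
    given ``config.seed``; every saved draw satisfies the stationarity and
    positive-definiteness invariants of :class:`ModelParams`.
    """
    config = config or FitConfig()
    n, t = design.n_countries, design.n_years
    k = len(design.columns)
    if t < 2:
        raise FitError("temporal model undefined for a single year (T >= 2 required)")
    if n < 3:
        raise FitError("at least 3 countries required")
    if config.n_saved() < 1:
        raise FitError("chain settings save no draws")
    _check_rank(design)

    rng = np.random.default_rng(config.seed)
    xd, zd, i_arr, j_arr = _pair_arrays(design)
    m = xd.shape[0]

    # gram matrices for the stacked-beta update, (T*K, T*K) per direction pair
    xflat = [xd[:, a].reshape(m, t * k) for a in (0, 1)]
    gram = [[xflat[a].T @ xflat[b] for b in (0, 1)] for a in (0, 1)]

    # ---- initial state: per-year ridge estimates, zero latents
    beta = np.empty((t, k))
    for ti in range(t):
        xt, zt = design.x[ti], design.z[ti]
        beta[ti] = np.linalg.solve(xt.T @ xt + 1e-6 * np.eye(k), xt.T @ zt)
    s = np.zeros((n, t))
    r = np.zeros((n, t))
    phi = np.eye(2) * 0.5
    sigma_eps = np.eye(2) * 0.1
    resid0 = zd - np.einsum("matk,tk->mat", xd, beta)
    sigma2_gamma = max(float(np.var(resid0)), 1e-8)
    rho_ = 0.0
    phi_gg = 0.0

    beta_prior_prec = 1.0 / config.beta_prior_sd**2
    phi_prior_prec = 1.0 / config.phi_prior_sd**2
    iw_df0 = config.sigma_eps_prior_df
    iw_scale0 = np.asarray(config.sigma_eps_prior_scale, dtype=float)
    ig_a, ig_b = config.sigma2_gamma_prior_shape, config.sigma2_gamma_prior_rate

    n_saved = config.n_saved()
    out_beta = np.empty((n_saved, t, k))
    out_phi = np.empty((n_saved, 2, 2))
    out_phi_gg = np.empty(n_saved)
    out_rho = np.empty(n_saved)
    out_s2g = np.empty(n_saved)
    out_seps = np.empty((n_saved, 2, 2))
    out_s = np.empty((n_saved, n, t)) if config.store_latent else None
    out_r = np.empty((n_saved, n, t)) if config.store_latent else None

    mh_step = config.mh_step
    mh_acc = 0
    mh_tries = 0
    save_idx = 0

    def mh_logpost(s2g: float, rho_v: float, pgg: float, gam: np.ndarray) -> float:
        if not (abs(rho_v) < 1.0 and abs(pgg) < 1.0 and s2g > 0):
            return -np.inf
        ll = dyad_residual_loglik(gam, s2g, rho_v, pgg)
        # inverse-gamma prior on sigma2_gamma; flat on rho, phi_gg
        return ll - (ig_a + 1.0) * math.log(s2g) - ig_b / s2g

    for it in range(config.iterations):
        # ---- current residual-structure inverses
        sg_inv = np.array([[1.0, -rho_], [-rho_, 1.0]]) / (
            sigma2_gamma * (1.0 - rho_ * rho_)
        )
        cinv, _ = ar1_inverse_correlation(phi_gg, t)

        # ---- (1) stacked beta | states, residual structure
        gp = (
            sg_inv[0, 0] * gram[0][0]
            + sg_inv[0, 1] * gram[0][1]
            + sg_inv[1, 0] * gram[1][0]
            + sg_inv[1, 1] * gram[1][1]
        )
        a_mat = gp * np.kron(cinv, np.ones((k, k)))
        a_mat[np.diag_indices_from(a_mat)] += beta_prior_prec
        rres = zd.copy()
        rres[:, 0, :] -= s[i_arr] + r[j_arr]
        rres[:, 1, :] -= s[j_arr] + r[i_arr]
        u_w = np.einsum("ab,mbt,ts->mas", sg_inv, rres, cinv)
        b_vec = np.einsum("matk,mat->tk", xd, u_w).ravel()
        cf = cho_factor(a_mat, lower=True)
        mean = cho_solve(cf, b_vec)
        noise = solve_triangular(cf[0].T, rng.standard_normal(t * k), lower=False)
        beta = (mean + noise).reshape(t, k)

        # ---- (2) per-country latent trajectories
        zres = zd - np.einsum("matk,tk->mat", xd, beta)  # (M, 2, T)
        rowsum = np.zeros((n, t))  # sum over partners of zres where i sends
        colsum = np.zeros((n, t))  # ... where i receives
        np.add.at(rowsum, i_arr, zres[:, 0, :])
        np.add.at(rowsum, j_arr, zres[:, 1, :])
        np.add.at(colsum, j_arr, zres[:, 0, :])
        np.add.at(colsum, i_arr, zres[:, 1, :])

        k_prior = _var1_prior_precision(phi, sigma_eps, t)
        omega_inv_tm = np.kron(cinv, sg_inv)  # time-major interleaved, 2T x 2T
        prec = k_prior + (n - 1) * omega_inv_tm
        cfu = cho_factor(prec, lower=True)
        s_tot = s.sum(axis=0)
        r_tot = r.sum(axis=0)
        for i in range(n):
            c_send = rowsum[i] - (r_tot - r[i])  # (T,)
            c_recv = colsum[i] - (s_tot - s[i])
            c_tm = np.empty(2 * t)
            c_tm[0::2] = c_send
            c_tm[1::2] = c_recv
            h = omega_inv_tm @ c_tm
            mu = cho_solve(cfu, h)
            ui = mu + solve_triangular(cfu[0].T, rng.standard_normal(2 * t), lower=False)
            s_tot += ui[0::2] - s[i]
            r_tot += ui[1::2] - r[i]
            s[i] = ui[0::2]
            r[i] = ui[1::2]

        # ---- (3) residual structure (phi_gg, rho, sigma2_gamma) by MH
        gam = zres.copy()
        gam[:, 0, :] -= s[i_arr] + r[j_arr]
        gam[:, 1, :] -= s[j_arr] + r[i_arr]
        cur_lp = mh_logpost(sigma2_gamma, rho_, phi_gg, gam)
        prop = rng.normal(0.0, mh_step, size=3)
        p_s2g = math.exp(math.log(sigma2_gamma) + prop[0])
        p_rho = rho_ + prop[1]
        p_pgg = phi_gg + prop[2]
        # log-scale proposal for sigma2_gamma: Jacobian term log(s2g)
        prop_lp = mh_logpost(p_s2g, p_rho, p_pgg, gam)
        log_ratio = (prop_lp + math.log(p_s2g)) - (cur_lp + math.log(sigma2_gamma))
        mh_tries += 1
        if math.log(rng.random()) < log_ratio:
            sigma2_gamma, rho_, phi_gg = p_s2g, p_rho, p_pgg
            mh_acc += 1
        if it < config.burn_in and mh_tries >= 50:
            rate = mh_acc / mh_tries
            mh_step *= math.exp(rate - 0.30)
            mh_acc = mh_tries = 0

        # ---- (4) Phi | latent states (conjugate, truncated to stationarity)
        u_lag = np.stack([s[:, :-1], r[:, :-1]], axis=-1).reshape(-1, 2)
        u_nxt = np.stack([s[:, 1:], r[:, 1:]], axis=-1).reshape(-1, 2)
        seps_inv = np.linalg.inv(sigma_eps)
        xtx = u_lag.T @ u_lag
        xty = u_lag.T @ u_nxt
        prec_b = np.kron(seps_inv, xtx)
        prec_b[np.diag_indices_from(prec_b)] += phi_prior_prec
        lin = (xty @ seps_inv).ravel(order="F")
        cfb = cho_factor(prec_b, lower=True)
        mu_b = cho_solve(cfb, lin)
        for _ in range(100):
            vb = mu_b + solve_triangular(
                cfb[0].T, rng.standard_normal(4), lower=False
            )
            cand = vb.reshape(2, 2, order="F").T  # B = Phi'
            if np.max(np.abs(np.linalg.eigvals(cand))) < 1.0:
                phi = cand
                break

        # ---- (5) Sigma_eps | innovations (inverse-Wishart)
        innov = u_nxt - u_lag @ phi.T
        scale = iw_scale0 + innov.T @ innov
        sigma_eps = invwishart.rvs(
            df=iw_df0 + innov.shape[0], scale=scale, random_state=rng
        )
        sigma_eps = np.atleast_2d(sigma_eps)

        if not (np.all(np.isfinite(beta)) and np.isfinite(sigma2_gamma)):
            raise FitError(f"non-finite state at iteration {it}")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if save_idx < n_saved:
                out_beta[save_idx] = beta
                out_phi[save_idx] = phi
                out_phi_gg[save_idx] = phi_gg
                out_rho[save_idx] = rho_
                out_s2g[save_idx] = sigma2_gamma
                out_seps[save_idx] = sigma_eps
                if config.store_latent:
                    out_s[save_idx] = s
                    out_r[save_idx] = r
                save_idx += 1

    return PosteriorDraws(
        beta=out_beta[:save_idx],
        phi_matrix=out_phi[:save_idx],
        phi_gg=out_phi_gg[:save_idx],
        rho=out_rho[:save_idx],
        sigma2_gamma=out_s2g[:save_idx],
        sigma_eps=out_seps[:save_idx],
        s=out_s[:save_idx] if config.store_latent else None,
        r=out_r[:save_idx] if config.store_latent else None,
        countries=list(design.countries),
        years=list(design.years),
        columns=tuple(design.columns),
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def hpd_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ceil(prob * n) sorted draws."""
    if not 0.0 < prob < 1.0:
        raise ValidationError("prob must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValidationError("need at least 2 finite draws")
    n = x.size
    window = int(math.ceil(prob * n))
    window = min(window, n)
    widths = x[window - 1 :] - x[: n - window + 1]
    best = int(np.argmin(widths))
    return float(x[best]), float(x[best + window - 1])


def time_series_se(draws, max_order: int | None = None) -> float:
    """Autocorrelation-adjusted standard error of an MCMC chain mean.

    Estimates the spectral density at frequency zero by fitting an
    autoregressive process (Yule-Walker, AIC order selection) and returns
    sqrt(spec0 / n).  Reduces to sd/sqrt(n) for white-noise chains.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 50:
        raise ValidationError("need at least 50 draws")
    v0 = float(np.var(x))
    if v0 == 0.0:
        raise ValidationError("constant chain has zero variance")
    from statsmodels.regression.linear_model import yule_walker

    if max_order is None:
        max_order = min(int(10.0 * math.log10(n)), n - 1)
    best_aic = n * math.log(v0)
    best_spec0 = v0
    for order in range(1, max_order + 1):
        try:
            ar, sigma = yule_walker(x, order=order, method="mle")
        except Exception:
            continue
        sigma2 = float(sigma) ** 2
        if sigma2 <= 0:
            continue
        aic = n * math.log(sigma2) + 2.0 * order
        if aic < best_aic:
            best_aic = aic
            denom = 1.0 - float(np.sum(ar))
            best_spec0 = sigma2 / denom**2
    return math.sqrt(best_spec0 / n)


def summarize_posterior(draws: PosteriorDraws, prob: float = 0.95) -> PosteriorSummary:
    """Posterior summary tables.

    Coefficient rows use mean + HPD (significant iff the HPD excludes 0);
    Phi rows use median with equal-tail 2.5/97.5% quantiles; latent effects
    are posterior means per country-year.
    """
    if draws.n_saved == 0:
        raise ValidationError("no saved draws")
    rows = []
    for ti, year in enumerate(draws.years):
        for ci, name in enumerate(draws.columns):
            sample = draws.beta[:, ti, ci]
            lo, hi = hpd_interval(sample, prob)
            rows.append(
                {
                    "coefficient": name,
                    "year": year,
                    "mean": float(np.mean(sample)),
                    "hpd_lo": lo,
                    "hpd_hi": hi,
                    "significant": bool(lo > 0.0 or hi < 0.0),
                }
            )
    coefficients = pd.DataFrame(rows)

    phi_samples = {
        "phi_s": draws.phi_matrix[:, 0, 0],
        "phi_sr": draws.phi_matrix[:, 0, 1],
        "phi_rs": draws.phi_matrix[:, 1, 0],
        "phi_r": draws.phi_matrix[:, 1, 1],
        "phi_gg": draws.phi_gg,
    }
    phi = pd.DataFrame(
        [
            {
                "parameter": name,
                "median": float(np.median(v)),
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975)),
            }
            for name, v in phi_samples.items()
        ]
    )

    def effect_frame(arr: np.ndarray | None) -> pd.DataFrame:
        if arr is None:
            return pd.DataFrame(columns=["country", "year", "mean"])
        mean = arr.mean(axis=0)  # (N, T)
        recs = [
            {"country": c, "year": y, "mean": float(mean[ci, ti])}
            for ci, c in enumerate(draws.countries)
            for ti, y in enumerate(draws.years)
        ]
        return pd.DataFrame(recs)

    return PosteriorSummary(
        coefficients=coefficients,
        phi=phi,
        sender_effects=effect_frame(draws.s),
        receiver_effects=effect_frame(draws.r),
    )
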