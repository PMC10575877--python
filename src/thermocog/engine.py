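"""Posterior inference for Gaussian linear mixed models.

The spatiotemporal score model is, conditional on its variance components, a
Gaussian linear mixed model

    y = X beta + sum_b Z_b u_b + eps,   eps ~ N(0, sigma2 I),
    u_b ~ N(0, tau_b^{-1} Q_b^-)  restricted to per-group sum-to-zero,

with improper structure matrices Q_b (ICAR, RW1) or the identity. Each
constrained block is reparameterized as u_b = A_b v_b with A_b an orthonormal
basis of the constrained subspace, so the prior precision of v_b,
tau_b * A_b' Q_b A_b, is nonsingular and the joint conditional posterior of
(beta, v) is Gaussian with a closed-form precision.

Two engines share that core:

``laplace``
    Empirical Bayes: the log precisions (and log sigma2) are set to the mode
    of the marginal posterior (marginal likelihood times weakly informative
    Gamma priors on the precisions), and draws are taken from the exact
    Gaussian conditional at the mode. Deterministic apart from the seeded
    posterior draws; fast — one Cholesky per objective evaluation.

``mcmc``
    Blocked Gibbs with conjugate updates: (beta, v) jointly Gaussian given
    the precisions; each precision Gamma given its block; sigma2 via its
    conjugate update. Fully Bayesian in the variance components.

Fixed effects get a flat prior. Precisions get Gamma(shape, rate) priors,
default shape 1, rate 5e-5 — the weakly informative convention of the
hierarchical disease-mapping literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp

__all__ = ["RandomBlock", "DesignBundle", "EngineFit", "run_engine"]


@dataclass
class RandomBlock:
    """One random-effect block in the free (constrained) parameterization."""

    name: str
    Z: sp.csr_matrix          # n_obs x n_levels incidence (may carry x time)
    A: np.ndarray             # n_levels x n_free sum-to-zero basis
    S: np.ndarray             # n_free x n_free prior structure A'QA
    labels: tuple             # level labels, length n_levels

    @property
    def n_free(self) -> int:
        return self.A.shape[1]

    @property
    def n_levels(self) -> int:
        return self.A.shape[0]


@dataclass
class DesignBundle:
    """Response, fixed-effect columns and random blocks for one model fit."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: tuple
    blocks: list              # of RandomBlock
    meta: dict = field(default_factory=dict)


@dataclass
class EngineFit:
    """Posterior draws and hyperparameter estimates from one engine run."""

    engine: str
    fixed_names: tuple
    fixed_draws: np.ndarray             # p_fixed x n_draws
    block_draws: dict                   # name -> n_levels x n_draws (u scale)
    block_labels: dict
    sigma2_draws: np.ndarray            # n_draws
    tau: dict                           # name -> posterior summary dict
    mu_draws: np.ndarray                # n_obs x n_draws
    theta_mean_mu: np.ndarray           # predictor at posterior-mean coefs
    diagnostics: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return self.fixed_draws.shape[1]


def _summaries(draws: np.ndarray) -> dict:
    """mean/sd/2.5%/97.5% along the draw axis (last)."""
    return {
        "mean": draws.mean(axis=-1),
        "sd": draws.std(axis=-1, ddof=1) if draws.shape[-1] > 1 else np.zeros(draws.shape[:-1]),
        "q025": np.quantile(draws, 0.025, axis=-1),
        "q975": np.quantile(draws, 0.975, axis=-1),
    }


class _Core:
    """Shared precomputation: stacked design and prior structure slices."""

    def __init__(self, design: DesignBundle, prior_shape: float, prior_rate: float):
        X = np.asarray(design.X, dtype=float)
        self.y = np.asarray(design.y, dtype=float)
        self.n = len(self.y)
        parts = [X]
        self.slices = []
        p = X.shape[1]
        self.p_fixed = p
        for b in design.blocks:
            ZA = np.asarray(b.Z @ b.A)
            parts.append(ZA)
            self.slices.append((b, slice(p, p + b.n_free)))
            p += b.n_free
        self.p = p
        self.W = np.hstack(parts) if parts else np.empty((self.n, 0))
        self.WtW = self.W.T @ self.W
        self.Wty = self.W.T @ self.y
        self.yty = float(self.y @ self.y)
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.logdet_S = []
        for b, _ in self.slices:
            sign, ld = np.linalg.slogdet(b.S) if b.n_free else (1.0, 0.0)
            self.logdet_S.append(ld)

    def posterior_precision(self, sigma2: float, taus) -> np.ndarray:
        P = self.WtW / sigma2
        for (b, sl), tau in zip(self.slices, taus):
            P[sl, sl] += tau * b.S
        return P

    def neg2_log_marginal(self, sigma2: float, taus) -> float:
        """-2 log [marginal likelihood x Gamma priors], up to a constant."""
        P = self.posterior_precision(sigma2, taus)
        try:
            c, low = scipy.linalg.cho_factor(P, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError:
            return np.inf
        bvec = self.Wty / sigma2
        m = scipy.linalg.cho_solve((c, low), bvec, check_finite=False)
        logdet_P = 2.0 * float(np.sum(np.log(np.diag(c))))
        val = self.n * np.log(2 * np.pi * sigma2) + self.yty / sigma2 - bvec @ m + logdet_P
        a, r = self.prior_shape, self.prior_rate
        for (b, _), tau, ld in zip(self.slices, taus, self.logdet_S):
            val -= b.n_free * np.log(tau) + ld
            val -= 2.0 * ((a - 1.0) * np.log(tau) - r * tau)
        phi = 1.0 / sigma2
        val -= 2.0 * ((a - 1.0) * np.log(phi) - r * phi)
        return float(val)

    def neg2_log_marginal_and_grad(self, sigma2: float, taus):
        """Objective plus analytic gradient w.r.t. (log sigma2, log taus).

        Uses tr(P^-1 W'W) = [p - sum_b tau_b tr(P^-1_bb S_b)] / phi so only
        one explicit inverse of the posterior precision is needed.
        """
        phi = 1.0 / sigma2
        P = self.posterior_precision(sigma2, taus)
        try:
            c, low = scipy.linalg.cho_factor(P, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError:
            # extreme precisions can defeat the factorization numerically;
            # a relative jitter restores positive definiteness
            P = P + (1e-10 * np.trace(P) / self.p) * np.eye(self.p)
            c, low = scipy.linalg.cho_factor(P, lower=True, check_finite=False)
        bvec = self.Wty * phi
        m = scipy.linalg.cho_solve((c, low), bvec, check_finite=False)
        logdet_P = 2.0 * float(np.sum(np.log(np.diag(c))))
        a, r = self.prior_shape, self.prior_rate
        f = (self.n * np.log(2 * np.pi * sigma2) + self.yty * phi
             - bvec @ m + logdet_P)
        Pinv = scipy.linalg.cho_solve((c, low), np.eye(self.p),
                                      check_finite=False)
        g = np.empty(1 + len(self.slices))
        tr_bb = np.empty(len(self.slices))
        f -= float(np.sum(self.logdet_S))
        for j, ((b, sl), tau) in enumerate(zip(self.slices, taus)):
            tr_bb[j] = float(np.sum(Pinv[sl, sl] * b.S))
            quad = float(m[sl] @ (b.S @ m[sl]))
            dF_dtau = (quad + tr_bb[j] - b.n_free / tau
                       - 2.0 * (a - 1.0) / tau + 2.0 * r)
            g[1 + j] = tau * dF_dtau
            f -= b.n_free * np.log(tau) + 2.0 * ((a - 1.0) * np.log(tau)
                                                 - r * tau)
        f -= 2.0 * ((a - 1.0) * np.log(phi) - r * phi)
        rss = float(np.sum((self.y - self.W @ m) ** 2))
        tr_pinv_wtw = (self.p - float(np.sum(np.asarray(taus) * tr_bb))) / phi
        dF_dphi = (-self.n / phi + rss + tr_pinv_wtw
                   - 2.0 * (a - 1.0) / phi + 2.0 * r)
        g[0] = -phi * dF_dphi  # chain rule for x0 = log sigma2
        return float(f), g

    def conditional(self, sigma2: float, taus):
        """Cholesky factor and mean of the Gaussian (beta, v) posterior."""
        P = self.posterior_precision(sigma2, taus)
        c, low = scipy.linalg.cho_factor(P, lower=True, check_finite=False)
        m = scipy.linalg.cho_solve((c, low), self.Wty / sigma2, check_finite=False)
        return (c, low), m

    def draw(self, chol, m, rng, size: int, antithetic: bool = False) -> np.ndarray:
        c, _ = chol
        if antithetic:
            # paired +/-z draws: the sample mean is exactly m
            half = (size + 1) // 2
            z = rng.standard_normal((self.p, half))
            z = np.hstack([z, -z])[:, :size]
            if size % 2 == 1:
                z[:, -1] = 0.0
        else:
            z = rng.standard_normal((self.p, size))
        # P = L L', cov = P^{-1}; x = m + L^{-T} z
        x = scipy.linalg.solve_triangular(c, z, lower=True, trans="T", check_finite=False)
        return m[:, None] + x


def _ols_sigma2(core: _Core) -> float:
    """Residual variance of the fixed-effects-only least-squares fit (init)."""
    X = core.W[:, : core.p_fixed]
    if X.shape[1] == 0:
        return float(np.var(core.y)) or 1.0
    beta, *_ = np.linalg.lstsq(X, core.y, rcond=None)
    r = core.y - X @ beta
    dof = max(core.n - X.shape[1], 1)
    return max(float(r @ r / dof), 1e-8)


def _hessian(f, x0, f0, h=0.15):
    """Central finite-difference Hessian of f at x0 (f0 = f(x0))."""
    d = len(x0)
    H = np.zeros((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * h ** 2)
    return H


def _fit_laplace(core: _Core, n_draws: int, seed: int, sigma2_fixed,
                 maxfev: int, integrate_hyper: bool = False,
                 n_hyper: int = 9) -> tuple:
    k = len(core.slices)
    s2_init = _ols_sigma2(core)
    tau_init = np.full(k, 1.0 / max(0.2 * s2_init, 1e-6))
    est_sigma = sigma2_fixed is None

    def unpack(x):
        if est_sigma:
            return float(np.exp(x[0])), np.exp(x[1:])
        return float(sigma2_fixed), np.exp(x)

    def obj(x):
        if np.any(np.abs(x) > 40):
            return np.inf
        sigma2, taus = unpack(x)
        return core.neg2_log_marginal(sigma2, taus)

    def obj_grad(x):
        sigma2, taus = unpack(x)
        f, g_full = core.neg2_log_marginal_and_grad(sigma2, taus)
        return f, g_full if est_sigma else g_full[1:]

    x0 = np.concatenate([[np.log(s2_init)] if est_sigma else [], np.log(tau_init)])
    n_eval = 0
    if len(x0) > 0:
        res = scipy.optimize.minimize(
            obj_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * len(x0),
            options={"maxiter": maxfev, "ftol": 1e-10, "gtol": 1e-6})
        x_hat = res.x
        n_eval = res.nfev
        converged = bool(res.success or res.fun <= obj(x0) + 1e-9)
    else:
        x_hat = x0
        converged = True
    sigma2, taus = unpack(x_hat)
    rng = np.random.default_rng(seed)
    if integrate_hyper and len(x_hat) > 0:
        # propagate hyperparameter uncertainty: Gaussian approximation to the
        # marginal posterior of the log precisions at the mode, equal-weight
        # mixture of the conditional Gaussians at sampled hyper values
        f = lambda x: 0.5 * obj(x)
        H = _hessian(f, x_hat, f(x_hat))
        lam, V = scipy.linalg.eigh(H)
        lam = np.clip(lam, 1e-2, None)   # guard flat/indefinite directions
        Cov_half = V * (1.0 / np.sqrt(lam))
        per = max(n_draws // n_hyper, 2)
        parts, s2_parts = [], []
        for k in range(n_hyper):
            xk = x_hat if k == 0 else x_hat + Cov_half @ rng.standard_normal(len(x_hat))
            s2_k, taus_k = unpack(xk)
            try:
                chol, m = core.conditional(s2_k, taus_k)
            except scipy.linalg.LinAlgError:
                continue
            parts.append(core.draw(chol, m, rng, per, antithetic=True))
            s2_parts.append(np.full(per, s2_k))
        theta = np.hstack(parts)
        sigma2_draws = np.concatenate(s2_parts)
        n_draws = theta.shape[1]
    else:
        chol, m = core.conditional(sigma2, taus)
        theta = core.draw(chol, m, rng, n_draws, antithetic=True)
        sigma2_draws = np.full(n_draws, sigma2)
    tau_summary = {b.name: {"mean": float(t), "sd": np.nan,
                            "q025": np.nan, "q975": np.nan}
                   for (b, _), t in zip(core.slices, taus)}
    diag = {"engine": "laplace", "converged": converged, "n_obj_eval": int(n_eval)}
    return theta, sigma2_draws, tau_summary, diag


def _fit_gibbs(core: _Core, n_draws: int, warmup: int, seed: int,
               sigma2_fixed) -> tuple:
    rng = np.random.default_rng(seed)
    k = len(core.slices)
    sigma2 = sigma2_fixed if sigma2_fixed is not None else _ols_sigma2(core)
    taus = np.full(k, 1.0 / max(0.2 * sigma2, 1e-6))
    a, r = core.prior_shape, core.prior_rate
    keep_theta = np.empty((core.p, n_draws))
    keep_sigma2 = np.empty(n_draws)
    keep_tau = np.empty((k, n_draws))
    total = warmup + n_draws
    for it in range(total):
        chol, m = core.conditional(sigma2, taus)
        theta = core.draw(chol, m, rng, 1)[:, 0]
        for j, (b, sl) in enumerate(core.slices):
            v = theta[sl]
            q = float(v @ (b.S @ v))
            taus[j] = rng.gamma(a + 0.5 * b.n_free, 1.0 / (r + 0.5 * q))
        if sigma2_fixed is None:
            resid = core.y - core.W @ theta
            rss = float(resid @ resid)
            phi = rng.gamma(a + 0.5 * core.n, 1.0 / (r + 0.5 * rss))
            sigma2 = 1.0 / phi
        if it >= warmup:
            i = it - warmup
            keep_theta[:, i] = theta
            keep_sigma2[i] = sigma2
            keep_tau[:, i] = taus
    tau_summary = {}
    for j, (b, _) in enumerate(core.slices):
        s = _summaries(keep_tau[j])
        tau_summary[b.name] = {key: float(val) for key, val in s.items()}
    # crude split-half stationarity check on the (log) noise chain
    chain = np.log(keep_sigma2) if sigma2_fixed is None else keep_theta[0]
    h = n_draws // 2
    z = abs(chain[:h].mean() - chain[h:].mean()) / (chain.std(ddof=1) / np.sqrt(h) + 1e-12)
    diag = {"engine": "mcmc", "converged": bool(z < 5.0),
            "splithalf_z": float(z), "warmup": warmup}
    return keep_theta, keep_sigma2, tau_summary, diag


def run_engine(design: DesignBundle, engine: str = "laplace",
               n_draws: int = 800, warmup: int = 300, seed: int = 0,
               sigma2_fixed=None, prior_shape: float = 1.0,
               prior_rate: float = 5e-5, maxfev: int = 500,
               integrate_hyper: bool = False, n_hyper: int = 9) -> EngineFit:
    """Fit the Gaussian mixed model and return posterior draws.

    Identical inputs and seed give identical output. Non-convergence is
    reported through ``diagnostics['converged']``; the fit is still returned.
    """
    if engine not in ("laplace", "mcmc"):
        raise ValueError(f"unknown engine {engine!r}")
    core = _Core(design, prior_shape, prior_rate)
    if core.p == 0:
        raise ValueError("empty design: no fixed effects and no random blocks")
    rank = np.linalg.matrix_rank(core.WtW) if core.p <= 200 else core.p
    if rank < core.p and not design.blocks:
        raise ValueError(
            "singular design: fixed-effect columns are collinear "
            f"(rank {rank} < {core.p}); drop or combine columns")

    if engine == "laplace":
        theta, sigma2_draws, tau_summary, diag = _fit_laplace(
            core, n_draws, seed, sigma2_fixed, maxfev,
            integrate_hyper=integrate_hyper, n_hyper=n_hyper)
    else:
        theta, sigma2_draws, tau_summary, diag = _fit_gibbs(
            core, n_draws, warmup, seed, sigma2_fixed)
    if not diag.get("converged", True):
        warnings.warn(f"{engine} engine did not converge cleanly: {diag}")

    fixed_draws = theta[: core.p_fixed]
    block_draws, block_labels = {}, {}
    for b, sl in core.slices:
        block_draws[b.name] = b.A @ theta[sl]
        block_labels[b.name] = b.labels
    mu_draws = core.W @ theta
    theta_mean_mu = core.W @ theta.mean(axis=1)
    return EngineFit(engine=engine, fixed_names=design.fixed_names,
                     fixed_draws=fixed_draws, block_draws=block_draws,
                     block_labels=block_labels, sigma2_draws=sigma2_draws,
                     tau=tau_summary, mu_draws=mu_draws,
                     theta_mean_mu=theta_mean_mu, diagnostics=diag, seed=seed)
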