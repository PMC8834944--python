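"""Bayesian shared-component disadvantage-index model for areal counts.

The model for the count ``y_ik`` of outlet type ``k`` in block group ``i`` is

    y_ik ~ Poisson(theta_ik * E_ik)
    log(theta_ik) = alpha_k + beta_k * sum_j w_j q_ij + u_i + v_i + s_ik

with decile-scored covariates ``q_ij``, index weights ``w`` on the unit
simplex (Dirichlet prior), flat intercepts ``alpha_k``, vague normal index
effects ``beta_k ~ N(1, sigma_beta^2)`` with ``sigma_beta ~ Uniform(0, 100)``,
an unstructured shared effect ``u_i ~ N(0, 1/tau_u)``, a spatially
structured shared effect ``v_i`` and outlet-specific effects ``s_ik`` with
intrinsic CAR priors, and Gamma(0.05, 0.005) priors on all precisions.

Inference is Metropolis-within-Gibbs: vectorized single-site random-walk
updates for the random effects (parallelized over graph-coloring classes so
no two interacting sites update together), random-walk updates for the
intercepts and effects, an exact Gibbs draw for every precision, and a
softmax-reparametrized random-walk with Jacobian correction for the simplex
weights.  ``v`` and each ``s_k`` are recentered to sum zero every sweep, with
the removed mean absorbed into the (flat-prior) intercepts.

The sampler internally centers the index at its mean so the intercept and
effect random walks are nearly uncorrelated; stored intercept draws are
reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .adjacency import AdjacencyStructure

__all__ = [
    "PosteriorDraws",
    "SharedComponentCAR",
    "fit_shared_car",
    "gelman_rubin",
    "icar_logdensity",
    "poisson_log_likelihood",
    "sample_weight_prior",
]


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def poisson_log_likelihood(
    alpha: np.ndarray,
    beta: np.ndarray,
    w: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    s: np.ndarray,
    q: np.ndarray,
    y: np.ndarray,
    expected: np.ndarray,
) -> float:
    """Full Poisson log likelihood (including the log y! terms)."""
    ndi = q @ np.asarray(w, dtype=float)
    eta = (np.asarray(alpha, float)[None, :]
           + np.asarray(beta, float)[None, :] * ndi[:, None]
           + (np.asarray(u, float) + np.asarray(v, float))[:, None]
           + np.asarray(s, float))
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    mean = np.asarray(expected, float) * np.exp(eta)
    y = np.asarray(y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mean), 0.0)
    return float(np.sum(term - mean - gammaln(y + 1.0)))


def icar_logdensity(z: np.ndarray, tau: float, adj: AdjacencyStructure) -> float:
    """ICAR log pseudo-density up to a constant.

    ((n - n_components)/2) log(tau) - (tau/2) * sum_{i~j, i<j} (z_i - z_j)^2;
    the rank deficiency of the Laplacian is one per connected component.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = np.asarray(z, dtype=float)
    quad = float(z @ (adj.laplacian() @ z))  # equals the pairwise sum of squares
    rank = adj.n - adj.n_components
    return 0.5 * rank * np.log(tau) - 0.5 * tau * quad


def gelman_rubin(draws: np.ndarray) -> np.ndarray | float:
    """Potential scale reduction factor.

    ``draws`` has shape (n_chains, n_draws) or (n_chains, n_draws, k); with
    m draws per chain, within-chain variance W and between-chain variance B,
    the statistic is sqrt((W (m-1)/m + B/m) / W).  Zero within-chain variance
    yields NaN with a warning.
    """
    x = np.asarray(draws, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    n_chains, m, _ = x.shape
    if n_chains < 2 or m < 10:
        raise ValueError("need at least 2 chains and 10 draws per chain")
    within = x.var(axis=1, ddof=1).mean(axis=0)
    between = m * x.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((m - 1) / m * within + between / m) / within)
    if np.any(within == 0):
        warnings.warn("zero within-chain variance; Gelman-Rubin reported as NaN", stacklevel=2)
        rhat = np.where(within == 0, np.nan, rhat)
    return float(rhat[0]) if squeeze else rhat


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, chain-major.

    Array shapes: alpha/beta (chains, draws, 3); w (chains, draws, C);
    u/v (chains, draws, n); s (chains, draws, n, 3); tau_u/tau_v/tau_beta
    (chains, draws); tau_s (chains, draws, 3).
    """

    alpha: np.ndarray
    beta: np.ndarray
    w: np.ndarray
    u: np.ndarray
    v: np.ndarray
    s: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    tau_s: np.ndarray
    tau_beta: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (chains*draws, ...)."""
        a = getattr(self, name)
        return a.reshape((-1,) + a.shape[2:])


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _update_weights(
    z: np.ndarray,
    steps: np.ndarray,
    rng: np.random.Generator,
    dirichlet_alpha: np.ndarray,
    loglik_of_w,
    cur_ll: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One coordinate-wise Metropolis sweep over the free softmax logits.

    The last logit is pinned at zero; the target in logit space is the
    Dirichlet log density plus the softmax log-Jacobian, which together give
    sum_j dirichlet_alpha_j * log(w_j), plus the supplied log likelihood.

    Returns (z, w, loglik, accepted_flags).
    """
    c = len(z)
    w = _softmax(z)
    logw = np.log(w)
    accepted = np.zeros(c - 1, dtype=bool)
    for j in range(c - 1):
        z_prop = z.copy()
        z_prop[j] = z[j] + steps[j] * rng.standard_normal()
        w_prop = _softmax(z_prop)
        ll_prop = loglik_of_w(w_prop)
        log_ratio = (ll_prop - cur_ll
                     + float(dirichlet_alpha @ (np.log(w_prop) - logw)))
        if np.log(rng.random()) < log_ratio:
            z, w, logw, cur_ll = z_prop, w_prop, np.log(w_prop), ll_prop
            accepted[j] = True
    return z, w, cur_ll, accepted


def sample_weight_prior(
    dirichlet_alpha: np.ndarray,
    n_draws: int,
    *,
    thin: int = 25,
    n_burnin: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Draw simplex weights from the sampler's own kernel with the
    likelihood disabled; the stationary law is Dirichlet(dirichlet_alpha).

    This is the detailed-balance check for the softmax Metropolis update:
    it exercises exactly the kernel used inside :meth:`SharedComponentCAR.fit`.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    c = len(alpha)
    rng = np.random.default_rng(seed)
    z = np.zeros(c)
    steps = np.full(c - 1, 1.0)
    acc = np.zeros(c - 1)
    cnt = 0
    zero_ll = lambda w: 0.0  # noqa: E731
    for it in range(n_burnin):
        z, w, _, accepted = _update_weights(z, steps, rng, alpha, zero_ll, 0.0)
        acc += accepted
        cnt += 1
        if cnt == 50:
            steps *= np.exp(np.clip(acc / cnt - 0.44, -0.5, 0.5))
            acc[:] = 0.0
            cnt = 0
    out = np.empty((n_draws, c))
    for d in range(n_draws):
        for _ in range(thin):
            z, w, _, _ = _update_weights(z, steps, rng, alpha, zero_ll, 0.0)
        out[d] = w
    return out


def _run_chain(
    q: np.ndarray,
    y: np.ndarray,
    E: np.ndarray,
    adj: AdjacencyStructure,
    cfg: "SharedComponentCAR",
    seed: int,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    rng = np.random.default_rng(seed)
    n, C = q.shape
    K = y.shape[1]

    dir_alpha = (np.ones(C) if cfg.dirichlet_alpha is None
                 else np.asarray(cfg.dirichlet_alpha, dtype=float))
    if dir_alpha.shape != (C,) or (dir_alpha <= 0).any():
        raise ValueError("dirichlet_alpha must be positive with one entry per covariate")

    a_gam, b_gam = cfg.tau_gamma_shape, cfg.tau_gamma_rate
    tau_beta_min = 1.0 / cfg.sigma_beta_upper**2
    m0 = cfg.beta_prior_mean

    W = adj.weight_matrix()
    L = adj.laplacian()
    deg = adj.degree.astype(float)
    colors = adj.coloring()
    icar_rank = n - adj.n_components
    comp_masks = [adj.component_labels == c for c in range(adj.n_components)]

    ysum_k = y.sum(axis=0)              # per-type totals
    yrow = y.sum(axis=1)                # per-unit totals

    # --- state ------------------------------------------------------------
    z = np.zeros(C)
    w = _softmax(z)
    with np.errstate(divide="ignore"):
        alpha_t = np.log(np.maximum(ysum_k, 0.5) / E.sum(axis=0))  # centered-index intercepts
    alpha_t += 0.1 * rng.standard_normal(K)
    beta = 0.1 * rng.standard_normal(K)
    u = np.zeros(n)
    v = np.zeros(n)
    s = np.zeros((n, K))
    tau_u = tau_v = 10.0
    tau_s = np.full(K, 10.0)
    tau_beta = 1.0

    nd = q @ w
    x = nd - nd.mean()

    # proposal scales, adapted to cfg.target_accept during burn-in only
    step_alpha = np.full(K, 0.1)
    step_beta = np.full(K, 0.05)
    step_z = np.full(C - 1, 0.5)
    step_u = 0.5
    step_v = 0.5
    step_s = np.full(K, 0.5)

    fams = ["alpha", "beta", "z", "u", "v", "s"]
    acc = {f: 0.0 for f in fams}
    cnt = {f: 0.0 for f in fams}
    acc_total = {f: 0.0 for f in fams}
    cnt_total = {f: 0.0 for f in fams}

    n_store = (cfg.n_iter - cfg.n_burnin + cfg.thin - 1) // cfg.thin
    store = {
        "alpha": np.empty((n_store, K)),
        "beta": np.empty((n_store, K)),
        "w": np.empty((n_store, C)),
        "u": np.empty((n_store, n)),
        "v": np.empty((n_store, n)),
        "s": np.empty((n_store, n, K)),
        "tau_u": np.empty(n_store),
        "tau_v": np.empty(n_store),
        "tau_s": np.empty((n_store, K)),
        "tau_beta": np.empty(n_store),
    }
    kept = 0

    def rest_matrix():
        return (u + v)[:, None] + s

    def full_ll(x_, at, bt, rest):
        eta = at[None, :] + bt[None, :] * x_[:, None] + rest
        return float(np.sum(y * eta - E * np.exp(eta)))

    for it in range(cfg.n_iter):
        rest = rest_matrix()

        # ---- simplex weights (coordinate-wise softmax Metropolis) --------
        cur_ll = full_ll(x, alpha_t, beta, rest)
        if not np.isfinite(cur_ll):
            raise FloatingPointError(
                f"divergent chain at iteration {it}: non-finite posterior "
                f"(alpha={alpha_t}, beta={beta}, tau_u={tau_u}, tau_v={tau_v})"
            )

        def ll_of_w(w_prop):
            nd_p = q @ w_prop
            return full_ll(nd_p - nd_p.mean(), alpha_t, beta, rest)

        z, w, cur_ll, accepted = _update_weights(z, step_z, rng, dir_alpha, ll_of_w, cur_ll)
        acc["z"] += accepted.mean()
        cnt["z"] += 1
        nd = q @ w
        x = nd - nd.mean()

        # cached predictor pieces
        eta = alpha_t[None, :] + beta[None, :] * x[:, None] + rest
        mu = E * np.exp(eta)

        # ---- intercepts (flat prior; conditionally independent over k) ----
        d = step_alpha * rng.standard_normal(K)
        dll = ysum_k * d - mu.sum(axis=0) * np.expm1(d)
        ok = np.log(rng.random(K)) < dll
        da = d * ok
        alpha_t += da
        mu *= np.exp(da)[None, :]
        acc["alpha"] += ok.mean()
        cnt["alpha"] += 1

        # ---- index effects beta_k --------------------------------------
        d = step_beta * rng.standard_normal(K)
        g = np.exp(x[:, None] * d[None, :])
        dll = (x @ y) * d - (mu * (g - 1.0)).sum(axis=0)
        dll -= 0.5 * tau_beta * ((beta + d - m0) ** 2 - (beta - m0) ** 2)
        ok = np.log(rng.random(K)) < dll
        db = d * ok
        beta += db
        mu *= np.exp(x[:, None] * db[None, :])
        acc["beta"] += ok.mean()
        cnt["beta"] += 1

        # ---- tau_beta: exact Gibbs (shifted exponential, see module doc) --
        ssq = float(((beta - m0) ** 2).sum())
        tau_beta = tau_beta_min + rng.exponential(2.0 / max(ssq, 1e-300))

        # ---- unstructured shared effect u --------------------------------
        if cfg.include_u:
            d = step_u * rng.standard_normal(n)
            murow = mu.sum(axis=1)
            dll = yrow * d - murow * np.expm1(d) - 0.5 * tau_u * (2 * u * d + d * d)
            ok = np.log(rng.random(n)) < dll
            du = d * ok
            u += du
            mu *= np.exp(du)[:, None]
            acc["u"] += ok.mean()
            cnt["u"] += 1
            tau_u = rng.gamma(a_gam + 0.5 * n, 1.0 / (b_gam + 0.5 * float(u @ u)))

        # ---- structured shared effect v (chromatic single-site) ----------
        if cfg.include_v:
            rates = []
            for idx in colors:
                nbsum = W @ v
                d = step_v * rng.standard_normal(len(idx))
                vi = v[idx]
                murow = mu[idx].sum(axis=1)
                dll = (yrow[idx] * d - murow * np.expm1(d)
                       - 0.5 * tau_v * (deg[idx] * (2 * vi * d + d * d) - 2 * d * nbsum[idx]))
                ok = np.log(rng.random(len(idx))) < dll
                dv = d * ok
                v[idx] += dv
                mu[idx] *= np.exp(dv)[:, None]
                rates.append(ok.mean())
            acc["v"] += float(np.mean(rates))
            cnt["v"] += 1
            quad = float(v @ (L @ v))
            tau_v = rng.gamma(a_gam + 0.5 * icar_rank, 1.0 / (b_gam + 0.5 * quad))

        # ---- outlet-specific effects s_ik (chromatic, all types at once) --
        if cfg.include_s:
            rates = []
            for idx in colors:
                nbs = W @ s
                d = step_s[None, :] * rng.standard_normal((len(idx), K))
                si = s[idx]
                dll = (y[idx] * d - mu[idx] * np.expm1(d)
                       - 0.5 * tau_s[None, :] * (deg[idx, None] * (2 * si * d + d * d)
                                                 - 2 * d * nbs[idx]))
                ok = np.log(rng.random((len(idx), K))) < dll
                ds = d * ok
                s[idx] += ds
                mu[idx] *= np.exp(ds)
                rates.append(ok.mean())
            acc["s"] += float(np.mean(rates))
            cnt["s"] += 1
            for k in range(K):
                quad = float(s[:, k] @ (L @ s[:, k]))
                tau_s[k] = rng.gamma(a_gam + 0.5 * icar_rank, 1.0 / (b_gam + 0.5 * quad))

        # ---- sum-to-zero recentering (mean absorbed by flat intercepts) ---
        if cfg.include_v:
            m = v.mean()
            v -= m
            alpha_t += m
            if adj.n_components > 1:
                for mask in comp_masks:
                    v[mask] -= v[mask].mean()
        if cfg.include_s:
            mk = s.mean(axis=0)
            s -= mk[None, :]
            alpha_t += mk
            if adj.n_components > 1:
                for mask in comp_masks:
                    s[mask] -= s[mask].mean(axis=0)[None, :]

        # ---- adaptation (burn-in only) ------------------------------------
        if it < cfg.n_burnin and cnt["alpha"] >= cfg.adapt_interval:
            def tune(step, f):
                if cnt[f] > 0:
                    rate = acc[f] / cnt[f]
                    step = step * np.exp(np.clip(rate - cfg.target_accept, -0.5, 0.5))
                    acc_total[f] += acc[f]
                    cnt_total[f] += cnt[f]
                    acc[f] = 0.0
                    cnt[f] = 0.0
                return np.clip(step, 1e-5, 20.0)

            step_alpha = tune(step_alpha, "alpha")
            step_beta = tune(step_beta, "beta")
            step_z = tune(step_z, "z")
            step_u = float(tune(np.asarray(step_u), "u"))
            step_v = float(tune(np.asarray(step_v), "v"))
            step_s = tune(step_s, "s")

        # ---- storage -------------------------------------------------------
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            store["alpha"][kept] = alpha_t - beta * nd.mean()  # back to original scale
            store["beta"][kept] = beta
            store["w"][kept] = w
            store["u"][kept] = u
            store["v"][kept] = v
            store["s"][kept] = s
            store["tau_u"][kept] = tau_u
            store["tau_v"][kept] = tau_v
            store["tau_s"][kept] = tau_s
            store["tau_beta"][kept] = tau_beta
            kept += 1

    for f in fams:
        acc_total[f] += acc[f]
        cnt_total[f] += cnt[f]
    rates = {f: (acc_total[f] / cnt_total[f] if cnt_total[f] else np.nan) for f in fams}
    return store, rates


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SharedComponentCAR(BaseEstimator):
    """Shared-component Bayesian index model, scikit-learn estimator style.

    Parameters
    ----------
    dirichlet_alpha
        Dirichlet concentration for the index weights (default: all ones).
    beta_prior_mean
        Mean of the vague normal prior on the index effects (default 1).
    sigma_beta_upper
        Upper bound of the uniform prior on the effects' prior sd.
    tau_gamma_shape, tau_gamma_rate
        Gamma(shape, rate) prior for all random-effect precisions.
    include_u, include_v, include_s
        Toggle the unstructured shared, structured shared and
        outlet-specific components.
    n_iter, n_burnin, n_chains, thin, seed
        MCMC schedule; chain c uses ``seed + c``.  The reference analysis
        ran 2 chains of 75,000 iterations with 60,000 burn-in and thin 1;
        desk-scale defaults here are shorter.
    adapt_interval, target_accept
        Robbins-Monro proposal adaptation (burn-in only).

    Attributes (after fit)
    ----------------------
    draws_ : PosteriorDraws
    weights_, beta_, alpha_ : posterior medians
    ndi_ : posterior-median disadvantage index per unit
    rhat_ : dict of Gelman-Rubin diagnostics (alpha, beta, w, precisions)
    acceptance_ : per-chain Metropolis acceptance rates
    """

    def __init__(
        self,
        dirichlet_alpha=None,
        beta_prior_mean: float = 1.0,
        sigma_beta_upper: float = 100.0,
        tau_gamma_shape: float = 0.05,
        tau_gamma_rate: float = 0.005,
        include_u: bool = True,
        include_v: bool = True,
        include_s: bool = True,
        n_iter: int = 8000,
        n_burnin: int = 4000,
        n_chains: int = 2,
        thin: int = 1,
        seed: int = 0,
        adapt_interval: int = 50,
        target_accept: float = 0.44,
    ):
        self.dirichlet_alpha = dirichlet_alpha
        self.beta_prior_mean = beta_prior_mean
        self.sigma_beta_upper = sigma_beta_upper
        self.tau_gamma_shape = tau_gamma_shape
        self.tau_gamma_rate = tau_gamma_rate
        self.include_u = include_u
        self.include_v = include_v
        self.include_s = include_s
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.n_chains = n_chains
        self.thin = thin
        self.seed = seed
        self.adapt_interval = adapt_interval
        self.target_accept = target_accept

    def _validate(self, q, y, E, adj):
        q = np.asarray(q, dtype=float)
        y = np.asarray(y, dtype=float)
        E = np.asarray(E, dtype=float)
        if q.ndim != 2 or y.ndim != 2 or E.shape != y.shape or q.shape[0] != y.shape[0]:
            raise ValueError("q must be (n, C); y and expected must both be (n, K)")
        if adj.n != q.shape[0]:
            raise ValueError("adjacency does not cover the data units")
        if (E <= 0).any():
            raise ValueError("expected counts must be strictly positive for every cell")
        if (y < 0).any() or not np.all(np.isfinite(q)):
            raise ValueError("counts must be nonnegative and deciles finite")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if min(self.sigma_beta_upper, self.tau_gamma_shape, self.tau_gamma_rate) <= 0:
            raise ValueError("hyperparameters must be positive")
        return q, y, E

    def fit(self, q, y, expected, adjacency: AdjacencyStructure) -> "SharedComponentCAR":
        """Run the MCMC and store thinned post-burn-in draws.

        Parameters: decile matrix ``q`` (n x C), counts ``y`` (n x K),
        expected counts (n x K) and the areal adjacency.
        """
        q, y, E = self._validate(q, y, expected, adjacency)
        stores, rates = [], []
        for c in range(self.n_chains):
            st_, r_ = _run_chain(q, y, E, adjacency, self, self.seed + c)
            stores.append(st_)
            rates.append(r_)

        self.draws_ = PosteriorDraws(
            **{k: np.stack([st_[k] for st_ in stores]) for k in stores[0]}
        )
        self.acceptance_ = rates
        d = self.draws_
        self.weights_ = np.median(d.flat("w"), axis=0)
        self.beta_ = np.median(d.flat("beta"), axis=0)
        self.alpha_ = np.median(d.flat("alpha"), axis=0)
        ndi_draws = d.flat("w") @ q.T
        self.ndi_ = np.median(ndi_draws, axis=0)
        self.q_ = q
        self.rhat_ = {}
        if self.n_chains >= 2 and d.n_draws >= 10:
            self.rhat_ = {
                "alpha": gelman_rubin(d.alpha),
                "beta": gelman_rubin(d.beta),
                "w": gelman_rubin(d.w),
            }
            if self.include_u:
                self.rhat_["tau_u"] = gelman_rubin(d.tau_u)
            if self.include_v:
                self.rhat_["tau_v"] = gelman_rubin(d.tau_v)
            if self.include_s:
                self.rhat_["tau_s"] = gelman_rubin(d.tau_s)
        return self

    def log_likelihood_draw(self, i_chain: int, i_draw: int, y, expected) -> float:
        """Full Poisson log likelihood of one stored draw (for diagnostics)."""
        d = self.draws_
        return poisson_log_likelihood(
            d.alpha[i_chain, i_draw], d.beta[i_chain, i_draw], d.w[i_chain, i_draw],
            d.u[i_chain, i_draw], d.v[i_chain, i_draw], d.s[i_chain, i_draw],
            self.q_, y, expected,
        )


def fit_shared_car(q, y, expected, adjacency, **params) -> SharedComponentCAR:
    """Functional wrapper over :class:`SharedComponentCAR`."""
    return SharedComponentCAR(**params).fit(q, y, expected, adjacency)
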