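"""Multispecies co-occurrence occupancy model (MSOM).

The latent presence of S detection units (guilds) at a site is a binary
vector z in {0,1}^S whose distribution follows a multinomial-logit
log-linear model with natural parameters:

    P(z) = exp( sum_s f_s z_s + sum_{j<k} f_jk z_j z_k ) / Z,

where first-order f_s governs unit s conditional on the absence of the
others and second-order f_jk governs pairwise co-occurrence (f_jk > 0
means the pair occurs together more than expected under independence).
The all-absent state carries weight exp(0) = 1.  Conditional on z,
detections are occasion-wise Bernoulli with constant per-guild detection
probability p_s (no covariates, no binomial coefficient: the likelihood
is history-exact).  The marginal site likelihood sums the detection
probability over all 2^S latent states.

Fitting is by maximum likelihood with a quasi-Newton optimizer from
several jittered starts; the covariance of the estimates is the inverse
observed information, and confidence intervals for derived occupancy
probabilities (marginal, pairwise, conditional) use the delta method or,
optionally, a seeded parametric bootstrap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp

from .records import DetectionHistory

_BOUND = 15.0  # box bound on every parameter (logit / log-linear scale)


@dataclass(frozen=True)
class MSOMSpec:
    """Model specification: guild order, interaction order, occasions."""

    guild_names: tuple[str, ...]
    interaction_order: int = 2
    n_occasions: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "guild_names", tuple(self.guild_names))
        if not 2 <= self.S <= 3:
            raise ValueError("MSOM supports 2 or 3 detection units")
        if self.interaction_order not in (1, 2):
            raise ValueError("interaction_order must be 1 or 2")

    @property
    def S(self) -> int:
        return len(self.guild_names)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        if self.interaction_order == 1:
            return ()
        return tuple(itertools.combinations(range(self.S), 2))

    @property
    def n_params(self) -> int:
        return self.S + len(self.pairs) + self.S  # f1 + f2 + logit p

    def param_names(self) -> list[str]:
        g = self.guild_names
        names = [f"f[{s}]" for s in g]
        names += [f"f[{g[j]}:{g[k]}]" for j, k in self.pairs]
        names += [f"logit_p[{s}]" for s in g]
        return names

    def index_of(self, guild: str) -> int:
        try:
            return self.guild_names.index(guild)
        except ValueError:
            raise KeyError(f"unknown guild {guild!r}") from None


@dataclass(eq=False)
class NaturalParams:
    """First- and second-order natural parameters of the state distribution.

    ``second_order`` is ordered by ``itertools.combinations(range(S), 2)``
    and is ``None`` for a no-interaction model.
    """

    first_order: np.ndarray
    second_order: np.ndarray | None = None

    def __eq__(self, other) -> bool:
        if not isinstance(other, NaturalParams):
            return NotImplemented
        if (self.second_order is None) != (other.second_order is None):
            return False
        return np.array_equal(self.first_order, other.first_order) and (
            self.second_order is None
            or np.array_equal(self.second_order, other.second_order)
        )

    def __post_init__(self) -> None:
        self.first_order = np.asarray(self.first_order, dtype=float)
        if self.second_order is not None:
            self.second_order = np.asarray(self.second_order, dtype=float)
            S = self.first_order.size
            if self.second_order.size != S * (S - 1) // 2:
                raise ValueError("second_order must have one entry per unordered pair")

    @property
    def S(self) -> int:
        return self.first_order.size


@dataclass
class DetectionParams:
    """Per-guild per-occasion detection probabilities (0 < p < 1)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p <= 0) or np.any(self.p >= 1):
            raise ValueError("detection probabilities must lie strictly in (0, 1)")

    @property
    def logit(self) -> np.ndarray:
        return np.log(self.p) - np.log1p(-self.p)


class Estimate(NamedTuple):
    """Point estimate with delta-method (or bootstrap) uncertainty."""

    value: float
    se: float
    ci_low: float
    ci_high: float


def enumerate_states(S: int) -> np.ndarray:
    """All 2^S latent presence vectors in canonical binary-counting order
    (guild 0 is the least significant bit); stable across calls."""
    if not 1 <= S <= 4:
        raise ValueError("state enumeration supports 1 <= S <= 4")
    return np.array(
        [[(i >> s) & 1 for s in range(S)] for i in range(2**S)], dtype=int
    )


def state_probabilities(params: NaturalParams) -> np.ndarray:
    """Multinomial-logit probabilities over the 2^S presence states."""
    f1 = params.first_order
    if not np.all(np.isfinite(f1)) or (
        params.second_order is not None and not np.all(np.isfinite(params.second_order))
    ):
        raise ValueError("natural parameters must be finite")
    S = params.S
    states = enumerate_states(S)
    logw = states @ f1
    if params.second_order is not None:
        for (j, k), fjk in zip(itertools.combinations(range(S), 2), params.second_order):
            logw = logw + fjk * states[:, j] * states[:, k]
    return np.exp(logw - logsumexp(logw))


def _counts(y, K) -> tuple[np.ndarray, np.ndarray]:
    """Normalise per-guild histories/counts to (detections, occasions)."""
    ys, ks = [], []
    K_seq = K if isinstance(K, (list, tuple, np.ndarray)) else [K] * len(list(y))
    for y_s, k_s in zip(y, K_seq):
        if np.ndim(y_s) > 0:
            arr = np.asarray(y_s, float)
            obs = ~np.isnan(arr)
            ys.append(int(np.nansum(arr)))
            ks.append(int(obs.sum()))
        else:
            ys.append(int(y_s))
            ks.append(int(k_s))
    return np.array(ys), np.array(ks)


def site_likelihood(y, p, dist: np.ndarray, K) -> float:
    """Marginal likelihood of one site's detection data.

    ``y`` gives, per guild, either a detection count or a 0/1/NaN occasion
    history; ``K`` the matching number of (non-missing) occasions.  The
    latent state is summed out:

        L = sum_z P(z) * prod_s g(y_s | z_s),

    with g the occasion-wise Bernoulli product when z_s = 1 and the
    indicator of an all-zero history when z_s = 0.
    """
    p = np.asarray(p, dtype=float)
    ys, ks = _counts(y, K)
    if np.any((ks == 0) & (ys > 0)):
        raise ValueError("detections recorded for a guild with zero active occasions")
    S = p.size
    states = enumerate_states(S)
    if dist.size != 2**S:
        raise ValueError("state distribution size does not match number of guilds")
    total = 0.0
    for prob, z in zip(dist, states):
        term = prob
        for s in range(S):
            if z[s]:
                term *= p[s] ** ys[s] * (1 - p[s]) ** (ks[s] - ys[s])
            elif ys[s] > 0:
                term = 0.0
                break
        total += term
    return float(total)


# ---------------------------------------------------------------------------
# Likelihood internals (vectorised over unique count patterns)
# ---------------------------------------------------------------------------

def _pattern_table(site_y: np.ndarray, site_k: np.ndarray):
    tab = np.concatenate([site_y, site_k], axis=1)
    uniq, counts = np.unique(tab, axis=0, return_counts=True)
    S = site_y.shape[1]
    return uniq[:, :S], uniq[:, S:], counts.astype(float)


def _split_theta(theta: np.ndarray, spec: MSOMSpec):
    S, P = spec.S, len(spec.pairs)
    f1 = theta[:S]
    f2 = theta[S : S + P] if P else None
    lp = theta[S + P :]
    return f1, f2, lp


def _state_logweights(f1, f2, spec: MSOMSpec, states: np.ndarray) -> np.ndarray:
    logw = states @ f1
    if f2 is not None:
        for (j, k), fjk in zip(spec.pairs, f2):
            logw = logw + fjk * states[:, j] * states[:, k]
    return logw - logsumexp(logw)


def _loglik(theta, Y, Kc, w, spec: MSOMSpec, states: np.ndarray) -> float:
    f1, f2, lp = _split_theta(theta, spec)
    logp = -np.log1p(np.exp(-lp))
    log1mp = -np.log1p(np.exp(lp))
    logpi = _state_logweights(f1, f2, spec, states)
    det1 = Y * logp + (Kc - Y) * log1mp                      # (U, S), z_s = 1
    det0 = np.where(Y == 0, 0.0, -np.inf)                    # (U, S), z_s = 0
    zmask = states.astype(bool)[:, None, :]                  # (2^S, 1, S)
    per_state = np.where(zmask, det1[None], det0[None]).sum(axis=2)  # (2^S, U)
    site_ll = logsumexp(per_state + logpi[:, None], axis=0)
    return float(w @ site_ll)


def _numeric_grad(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        step = h * (1 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (fun(xp) - fun(xm)) / (2 * step)
    return g


def _numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    steps = h * (1 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += steps[i]
                xm[i] -= steps[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / steps[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [steps[i], steps[j]]
                xpm[i] += steps[i]
                xpm[j] -= steps[j]
                xmp[i] -= steps[i]
                xmp[j] += steps[j]
                xmm[[i, j]] -= [steps[i], steps[j]]
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * steps[i] * steps[j])
    return H


@dataclass
class MSOMFit:
    """Result of a maximum-likelihood MSOM fit."""

    spec: MSOMSpec
    params: NaturalParams
    detection: DetectionParams
    theta: np.ndarray
    loglik: float
    aic: float
    n_params: int
    vcov: np.ndarray | None
    converged: bool
    grad_norm: float
    n_sites: int
    site_y: np.ndarray = field(repr=False)
    site_k: np.ndarray = field(repr=False)

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names()

    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.n_params, np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        zq = norm.ppf(0.5 + level / 2)
        se = self.se()
        return np.column_stack([self.theta - zq * se, self.theta + zq * se])

    def state_distribution(self) -> np.ndarray:
        return state_probabilities(self.params)

    def to_dict(self) -> dict:
        return {
            "guilds": list(self.spec.guild_names),
            "interaction_order": self.spec.interaction_order,
            "param_names": self.param_names,
            "estimates": self.theta.tolist(),
            "se": self.se().tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_sites": self.n_sites,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
        }


def _histories_to_arrays(
    histories: Mapping[str, DetectionHistory] | Sequence[DetectionHistory],
    spec: MSOMSpec,
):
    if isinstance(histories, Mapping):
        hs = [histories[g] for g in spec.guild_names]
    else:
        by_guild = {h.guild: h for h in histories}
        hs = [by_guild[g] for g in spec.guild_names]
    n_sites = {h.n_sites for h in hs}
    if len(n_sites) != 1:
        raise ValueError("all guild histories must share the site dimension")
    site_y = np.column_stack([h.detections_per_site() for h in hs]).astype(int)
    site_k = np.column_stack([h.occasions_per_site() for h in hs]).astype(int)
    return site_y, site_k


def fit_msom(
    histories: Mapping[str, DetectionHistory] | Sequence[DetectionHistory],
    spec: MSOMSpec,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 1000,
) -> MSOMFit:
    """Fit the MSOM by maximum likelihood.

    Runs L-BFGS-B from ``n_starts`` starts: a data-driven start (f = 0,
    logit p at the naive per-guild detection rate) plus seeded jitters.
    Returns the best optimum; ``vcov`` is the inverse observed information
    there.  A singular information matrix disables interval methods with a
    warning rather than failing the fit.
    """
    site_y, site_k = _histories_to_arrays(histories, spec)
    zero_det = [g for s, g in enumerate(spec.guild_names) if site_y[:, s].sum() == 0]
    if zero_det:
        warnings.warn(
            f"guild(s) with zero detections: {zero_det}; estimates will sit on "
            "the parameter boundary",
            stacklevel=2,
        )
    Y, Kc, w = _pattern_table(site_y, site_k)
    states = enumerate_states(spec.S)
    nll = lambda th: -_loglik(th, Y, Kc, w, spec, states)

    rate = site_y.sum(axis=0) / np.maximum(site_k.sum(axis=0), 1)
    rate = np.clip(rate, 0.02, 0.98)
    base = np.concatenate(
        [np.zeros(spec.S + len(spec.pairs)), np.log(rate) - np.log1p(-rate)]
    )
    rng = np.random.default_rng(seed)
    starts = [base] + [
        base + rng.uniform(-0.5, 0.5, base.size) for _ in range(max(n_starts - 1, 0))
    ]
    bounds = [(-_BOUND, _BOUND)] * base.size

    best, diagnostics = None, []
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        diagnostics.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "MSOM optimisation failed from every start: " + "; ".join(map(str, diagnostics))
        )

    theta = best.x
    loglik = -best.fun
    grad_norm = float(np.linalg.norm(_numeric_grad(nll, theta)))
    H = _numeric_hessian(nll, theta)
    vcov: np.ndarray | None
    try:
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 1e-10 * max(eigvals.max(), 1.0):
            raise np.linalg.LinAlgError("information matrix not positive definite")
        vcov = np.linalg.inv(H)
        vcov = (vcov + vcov.T) / 2
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular observed information; confidence intervals disabled",
            stacklevel=2,
        )
        vcov = None

    f1, f2, lp = _split_theta(theta, spec)
    k = theta.size
    return MSOMFit(
        spec=spec,
        params=NaturalParams(f1.copy(), None if f2 is None else f2.copy()),
        detection=DetectionParams(expit(lp)),
        theta=theta,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_params=k,
        vcov=vcov,
        converged=bool(best.success),
        grad_norm=grad_norm,
        n_sites=site_y.shape[0],
        site_y=site_y,
        site_k=site_k,
    )


def total_loglik(fit_or_histories, spec: MSOMSpec | None = None, theta=None) -> float:
    """Total log-likelihood of a parameter vector on a dataset (utility for
    optimality checks)."""
    if isinstance(fit_or_histories, MSOMFit):
        fit = fit_or_histories
        site_y, site_k, spec = fit.site_y, fit.site_k, fit.spec
        theta = fit.theta if theta is None else np.asarray(theta, float)
    else:
        site_y, site_k = _histories_to_arrays(fit_or_histories, spec)
        theta = np.asarray(theta, float)
    Y, Kc, w = _pattern_table(site_y, site_k)
    return _loglik(theta, Y, Kc, w, spec, enumerate_states(spec.S))


def compare_models(fits: Sequence[MSOMFit]):
    """Rank fits on the same data by AIC (ascending); ties (< 1e-9) go to
    the model with fewer parameters.  Returns a list of dicts with
    ``delta_aic`` relative to the best model."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if f.site_y.shape != ref.site_y.shape or not (
            np.array_equal(f.site_y, ref.site_y) and np.array_equal(f.site_k, ref.site_k)
        ):
            raise ValueError("model comparison requires identical data across fits")
    order = sorted(
        range(len(fits)), key=lambda i: (round(fits[i].aic / 1e-9), fits[i].n_params)
    )
    best_aic = fits[order[0]].aic
    table = []
    for rank, i in enumerate(order):
        f = fits[i]
        table.append(
            {
                "model": i,
                "interaction_order": f.spec.interaction_order,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "delta_aic": f.aic - best_aic,
                "best": rank == 0,
            }
        )
    return table


# ---------------------------------------------------------------------------
# Derived occupancy quantities with uncertainty
# ---------------------------------------------------------------------------

def _dist_from_theta(theta: np.ndarray, spec: MSOMSpec) -> np.ndarray:
    f1, f2, _ = _split_theta(np.asarray(theta, float), spec)
    return state_probabilities(NaturalParams(f1, f2))


def _delta_method(fit: MSOMFit, func: Callable[[np.ndarray], float]) -> Estimate:
    est = float(func(fit.theta))
    if fit.vcov is None:
        return Estimate(est, np.nan, np.nan, np.nan)
    g = _numeric_grad(func, fit.theta)
    var = float(g @ fit.vcov @ g)
    se = np.sqrt(max(var, 0.0))
    lo = max(est - 1.959963984540054 * se, 0.0)
    hi = min(est + 1.959963984540054 * se, 1.0)
    return Estimate(est, se, lo, hi)


def _parametric_bootstrap(
    fit: MSOMFit, func: Callable[[np.ndarray], float], B: int, seed: int
) -> Estimate:
    rng = np.random.default_rng(seed)
    states = enumerate_states(fit.spec.S)
    dist = _dist_from_theta(fit.theta, fit.spec)
    p = fit.detection.p
    vals = np.empty(B)
    for b in range(B):
        z = states[rng.choice(states.shape[0], size=fit.n_sites, p=dist)]
        y = rng.binomial(fit.site_k, p[None, :] * z)
        Y, Kc, w = _pattern_table(y, fit.site_k)
        nll = lambda th: -_loglik(th, Y, Kc, w, fit.spec, states)
        res = optimize.minimize(
            nll,
            fit.theta,
            method="L-BFGS-B",
            bounds=[(-_BOUND, _BOUND)] * fit.theta.size,
            options={"ftol": 1e-10},
        )
        vals[b] = func(res.x)
    est = float(func(fit.theta))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return Estimate(est, float(vals.std(ddof=1)), max(float(lo), 0.0), min(float(hi), 1.0))


def _derived(fit, func, ci, B, seed) -> Estimate:
    if ci == "delta":
        return _delta_method(fit, func)
    if ci == "parametric":
        return _parametric_bootstrap(fit, func, B, seed)
    raise ValueError(f"unknown CI method {ci!r}")


def marginal_occupancy(
    fit: MSOMFit, s: str | int, ci: str = "delta", B: int = 200, seed: int = 0
) -> Estimate:
    """psi_s = P(z_s = 1): probability guild s occupies a site."""
    si = fit.spec.index_of(s) if isinstance(s, str) else int(s)
    states = enumerate_states(fit.spec.S)

    def func(theta):
        return float(_dist_from_theta(theta, fit.spec)[states[:, si] == 1].sum())

    return _derived(fit, func, ci, B, seed)


def cooccurrence_probability(
    fit: MSOMFit, s: str | int, t: str | int, ci: str = "delta", B: int = 200, seed: int = 0
) -> Estimate:
    """P(z_s = 1, z_t = 1): both guilds present at a site."""
    si = fit.spec.index_of(s) if isinstance(s, str) else int(s)
    ti = fit.spec.index_of(t) if isinstance(t, str) else int(t)
    if si == ti:
        raise ValueError("co-occurrence requires two distinct guilds")
    states = enumerate_states(fit.spec.S)
    mask = (states[:, si] == 1) & (states[:, ti] == 1)

    def func(theta):
        return float(_dist_from_theta(theta, fit.spec)[mask].sum())

    return _derived(fit, func, ci, B, seed)


def conditional_occupancy(
    fit: MSOMFit,
    s: str | int,
    given: str | int,
    present: bool = True,
    ci: str = "delta",
    B: int = 200,
    seed: int = 0,
) -> Estimate:
    """P(z_s = 1 | z_t = 1) (or given absence, z_t = 0)."""
    si = fit.spec.index_of(s) if isinstance(s, str) else int(s)
    ti = fit.spec.index_of(given) if isinstance(given, str) else int(given)
    if si == ti:
        raise ValueError("conditional occupancy requires two distinct guilds")
    states = enumerate_states(fit.spec.S)
    cond = states[:, ti] == (1 if present else 0)
    joint = cond & (states[:, si] == 1)
    dist0 = _dist_from_theta(fit.theta, fit.spec)
    if dist0[cond].sum() < 1e-12:
        raise ValueError("conditioning event has (numerically) zero probability")

    def func(theta):
        dist = _dist_from_theta(theta, fit.spec)
        return float(dist[joint].sum() / dist[cond].sum())

    return _derived(fit, func, ci, B, seed)
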