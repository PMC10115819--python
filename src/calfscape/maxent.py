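"""Extended pairwise maximum-entropy (Ising-like) community model.

The model assigns each community state ``sigma`` (presence/absence of taxa
plus 0-1 scaled chemical levels) a conditional probability given the
per-sample environment ``eps = (eps_a, eps_s)`` — an antibiotic-treatment
indicator and a scaled growth stage::

    P(sigma | eps) = exp(-E(sigma | eps)) / Z(eps)

    E(sigma | eps) = -( sum_{i<j} J_ij sigma_i sigma_j
                        + eps_a sum_i g_a_i sigma_i
                        + eps_s sum_i g_s_i sigma_i
                        + sum_i h_i sigma_i )

``J_ij > 0`` favours co-occurrence of components i and j, ``g_a_i`` is the
responsiveness of component i to antibiotic treatment, ``g_s_i`` its
dependence on growth stage, and ``h_i`` its baseline propensity.  The pair
sum is counted once per unordered pair (i < j); exported J values follow
this convention.

Parameters are estimated by maximum likelihood.  The default estimator is
Robbins-Monro stochastic approximation with persistent Gibbs chains (one
set of chains per distinct environment); for small all-binary systems an
exact-moment Newton maximiser of the same likelihood is available and is
used for the repeated refits behind the parameter p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "MaxEntParams",
    "FitSettings",
    "FitResult",
    "energy",
    "exact_distribution",
    "enumerate_states",
    "gibbs_sample",
    "fit",
    "significance",
]

_EXACT_N_MAX = 20


@dataclass
class MaxEntParams:
    """Parameters (h, J, g_a, g_s) of the extended pairwise model.

    ``J`` is symmetric with zero diagonal; the energy counts each unordered
    pair once, so ``J[i, j]`` is the full coupling of the pair (i, j).
    """

    h: np.ndarray
    J: np.ndarray
    g_a: np.ndarray
    g_s: np.ndarray
    component_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        self.g_a = np.asarray(self.g_a, dtype=float)
        self.g_s = np.asarray(self.g_s, dtype=float)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError(f"J must be ({n}, {n}), got {self.J.shape}")
        if self.g_a.size != n or self.g_s.size != n:
            raise ValueError("h, g_a and g_s must have equal length")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have a zero diagonal")
        for name, arr in (("h", self.h), ("J", self.J),
                          ("g_a", self.g_a), ("g_s", self.g_s)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.component_names is not None:
            if len(self.component_names) != n:
                raise ValueError("component_names length mismatch")

    @property
    def n_components(self) -> int:
        return self.h.size

    @classmethod
    def zeros(cls, n: int, component_names: Optional[list[str]] = None
              ) -> "MaxEntParams":
        return cls(np.zeros(n), np.zeros((n, n)), np.zeros(n), np.zeros(n),
                   component_names)

    def permuted(self, order: Sequence[int]) -> "MaxEntParams":
        """Relabel components by ``order`` (new i = old order[i])."""
        idx = np.asarray(order)
        names = ([self.component_names[i] for i in idx]
                 if self.component_names is not None else None)
        return MaxEntParams(self.h[idx], self.J[np.ix_(idx, idx)],
                            self.g_a[idx], self.g_s[idx], names)

    def as_vector(self) -> np.ndarray:
        iu = np.triu_indices(self.n_components, k=1)
        return np.concatenate([self.h, self.J[iu], self.g_a, self.g_s])

    @classmethod
    def from_vector(cls, theta: np.ndarray, n: int,
                    component_names: Optional[list[str]] = None
                    ) -> "MaxEntParams":
        theta = np.asarray(theta, dtype=float)
        n_pairs = n * (n - 1) // 2
        h = theta[:n]
        J = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        J[iu] = theta[n:n + n_pairs]
        J = J + J.T
        g_a = theta[n + n_pairs:2 * n + n_pairs]
        g_s = theta[2 * n + n_pairs:]
        return cls(h, J, g_a, g_s, component_names)


@dataclass
class FitSettings:
    """Tunable knobs of the stochastic-approximation estimator.

    The Robbins-Monro gain decays as ``a_t = a0 / (1 + t / tau)``; the final
    estimate averages the iterates over the last ``polyak_frac`` of the
    schedule, which removes most of the residual Monte-Carlo jitter.
    """

    n_iter: int = 5000
    a0: float = 0.1
    tau: float = 500.0
    n_chains: int = 50
    h_max: float = 10.0
    polyak_frac: float = 0.25
    backend: Literal["auto", "sa", "exact"] = "auto"
    exact_n_max: int = 14
    newton_max_iter: int = 60
    newton_tol: float = 1e-8
    newton_ridge: float = 1e-6


@dataclass
class FitResult:
    """A fitted model, optionally with per-parameter p-values.

    ``p_values`` (present after :func:`significance`) mirrors the parameter
    layout; ``trace`` records the max-abs moment mismatch per iteration for
    the stochastic-approximation path.
    """

    params: MaxEntParams
    seed: Optional[int] = None
    trace: Optional[np.ndarray] = None
    n_reps: int = 0
    p_values: Optional[MaxEntParams] = None
    settings: Optional[FitSettings] = None
    replicate_params: Optional[np.ndarray] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Energy and exact distribution


def _check_env(env: Sequence[float]) -> tuple[float, float]:
    eps_a, eps_s = float(env[0]), float(env[1])
    return eps_a, eps_s


def _fields(params: MaxEntParams, env: Sequence[float]) -> np.ndarray:
    eps_a, eps_s = _check_env(env)
    return params.h + eps_a * params.g_a + eps_s * params.g_s


def energy(sigma: np.ndarray, env: Sequence[float],
           params: MaxEntParams) -> float | np.ndarray:
    """Energy of one state (or a stack of states) under environment ``env``.

    Lower energy means higher probability.  Accepts a length-N vector or an
    (M, N) array of states; components may be binary or in [0, 1].
    """
    sigma = np.asarray(sigma, dtype=float)
    single = sigma.ndim == 1
    states = np.atleast_2d(sigma)
    if states.shape[1] != params.n_components:
        raise ValueError(
            f"state has {states.shape[1]} components, "
            f"model has {params.n_components}")
    f = _fields(params, env)
    # J symmetric, zero diagonal: 0.5 * s J s^T counts each pair once
    pair = 0.5 * np.einsum("mi,ij,mj->m", states, params.J, states)
    e = -(pair + states @ f)
    return float(e[0]) if single else e


def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary states as an (2^n, n) float array, index = bit pattern.

    Component i is bit i, so state index k has sigma_i = (k >> i) & 1.
    """
    if n > _EXACT_N_MAX:
        raise ValueError(f"refusing to enumerate 2^{n} states (max n = 20)")
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def exact_distribution(params: MaxEntParams, env: Sequence[float]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact Boltzmann distribution over all binary states.

    Returns ``(states, probs)`` where ``states`` is (2^N, N) and ``probs``
    sums to one.  Only valid when every component is binary; N <= 20.
    """
    n = params.n_components
    if n > _EXACT_N_MAX:
        raise ValueError(
            f"exact enumeration limited to N <= {_EXACT_N_MAX}, got {n}")
    states = enumerate_states(n)
    e = energy(states, env, params)
    log_p = -e - logsumexp(-e)
    return states, np.exp(log_p)


# ---------------------------------------------------------------------------
# Gibbs sampling


def _conditional_update(states: np.ndarray, i: int, fields_i: np.ndarray,
                        J_row: np.ndarray, is_binary: bool,
                        rng: np.random.Generator) -> None:
    """In-place Gibbs update of component i for a stack of chains."""
    local = states @ J_row + fields_i
    u = rng.random(states.shape[0])
    if is_binary:
        states[:, i] = (u < expit(local)).astype(float)
    else:
        states[:, i] = _truncated_exp_sample(local, u)


def _truncated_exp_sample(rate: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw from density on [0,1] proportional to exp(rate * x).

    This is the conditional of any energy linear in a continuous component
    confined to [0, 1]; rate -> 0 reduces to the uniform distribution.
    """
    rate = np.asarray(rate, dtype=float)
    out = np.empty_like(rate)
    small = np.abs(rate) < 1e-9
    out[small] = u[small]
    r = rate[~small]
    # log1p formulation is stable for both signs of the rate
    out[~small] = np.log1p(u[~small] * np.expm1(r)) / r
    return np.clip(out, 0.0, 1.0)


def gibbs_sample(params: MaxEntParams, env: Sequence[float], n_sweeps: int,
                 seed: int | np.random.Generator,
                 component_kinds: Optional[Sequence[str]] = None,
                 clamped: Optional[np.ndarray] = None,
                 init: Optional[np.ndarray] = None,
                 burn_in: int = 0, thin: int = 1) -> np.ndarray:
    """Single-chain Gibbs sampler; one recorded state per kept sweep.

    Binary components are resampled from their conditional Bernoulli,
    continuous ones from the truncated-exponential conditional on [0, 1].
    Components flagged in ``clamped`` (boolean mask) keep their initial
    value throughout.
    """
    n = params.n_components
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    kinds = (["binary"] * n if component_kinds is None
             else list(component_kinds))
    if len(kinds) != n:
        raise ValueError("component_kinds length mismatch")
    clamp = (np.zeros(n, dtype=bool) if clamped is None
             else np.asarray(clamped, dtype=bool))
    f = _fields(params, env)
    if init is None:
        state = np.zeros((1, n))
        for i in range(n):
            state[0, i] = rng.random() < 0.5 if kinds[i] == "binary" \
                else rng.random()
    else:
        state = np.array(init, dtype=float).reshape(1, n)
    free = [i for i in range(n) if not clamp[i]]
    kept = []
    for sweep in range(n_sweeps):
        for i in free:
            _conditional_update(state, i, f[i], params.J[i],
                                kinds[i] == "binary", rng)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            kept.append(state[0].copy())
    return np.array(kept)


# ---------------------------------------------------------------------------
# Sufficient statistics and likelihood machinery

def _suff_stats(states: np.ndarray, eps_a: np.ndarray, eps_s: np.ndarray,
                weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Weighted mean sufficient-statistics vector [h | J(i<j) | g_a | g_s].

    ``eps_a``/``eps_s`` are per-row environment values; weights default to
    uniform and must sum to 1 otherwise.
    """
    m, n = states.shape
    w = np.full(m, 1.0 / m) if weights is None else weights
    iu = np.triu_indices(n, k=1)
    mean_s = w @ states
    pair = (states * w[:, None]).T @ states
    return np.concatenate([mean_s, pair[iu],
                           (w * eps_a) @ states, (w * eps_s) @ states])


def _group_environments(env: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique environment rows and the per-row group index."""
    uniq, inverse = np.unique(env, axis=0, return_inverse=True)
    return uniq, inverse


class _ExactBackend:
    """Exact moments / Fisher information by state enumeration.

    Valid for all-binary systems with small N; precomputes the per-state
    statistic matrices once per environment.
    """

    def __init__(self, n: int, uniq_env: np.ndarray, env_weights: np.ndarray):
        self.n = n
        self.uniq_env = uniq_env
        self.env_weights = env_weights
        self.states = enumerate_states(n)
        m = self.states.shape[0]
        iu = np.triu_indices(n, k=1)
        base = np.concatenate(
            [self.states, self.states[:, iu[0]] * self.states[:, iu[1]]],
            axis=1)
        # statistic matrix per environment: [s | s_i s_j | eps_a s | eps_s s]
        self.T = []
        for (ea, es) in uniq_env:
            self.T.append(np.concatenate(
                [base, ea * self.states, es * self.states], axis=1))

    def _probs(self, params: MaxEntParams) -> list[np.ndarray]:
        out = []
        for (ea, es) in self.uniq_env:
            e = energy(self.states, (ea, es), params)
            out.append(np.exp(-e - logsumexp(-e)))
        return out

    def moments(self, params: MaxEntParams) -> np.ndarray:
        probs = self._probs(params)
        return sum(w * (p @ T) for w, p, T
                   in zip(self.env_weights, probs, self.T))

    def moments_and_fisher(self, params: MaxEntParams
                           ) -> tuple[np.ndarray, np.ndarray]:
        probs = self._probs(params)
        mu_total = np.zeros(self.T[0].shape[1])
        fisher = np.zeros((mu_total.size, mu_total.size))
        for w, p, T in zip(self.env_weights, probs, self.T):
            mu = p @ T
            cov = (T * p[:, None]).T @ T - np.outer(mu, mu)
            mu_total += w * mu
            fisher += w * cov
        return mu_total, fisher

    def sample(self, params: MaxEntParams, counts: Iterable[int],
               rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """IID samples per environment; returns (states, eps_a, eps_s)."""
        probs = self._probs(params)
        blocks, ea_all, es_all = [], [], []
        for (ea, es), p, c in zip(self.uniq_env, probs, counts):
            idx = rng.choice(p.size, size=c, p=p)
            blocks.append(self.states[idx])
            ea_all.append(np.full(c, ea))
            es_all.append(np.full(c, es))
        return (np.concatenate(blocks), np.concatenate(ea_all),
                np.concatenate(es_all))


def _fit_exact(obs: np.ndarray, backend: _ExactBackend,
               settings: FitSettings, theta0: Optional[np.ndarray] = None,
               free_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Damped Newton ascent of the exact log-likelihood (concave)."""
    n = backend.n
    theta = (np.zeros(obs.size) if theta0 is None else theta0.copy())
    free = (np.ones(obs.size, dtype=bool) if free_mask is None else free_mask)
    for _ in range(settings.newton_max_iter):
        params = MaxEntParams.from_vector(theta, n)
        mu, fisher = backend.moments_and_fisher(params)
        grad = (obs - mu)[free]
        if np.max(np.abs(grad)) < settings.newton_tol:
            break
        F = fisher[np.ix_(free, free)]
        F = F + settings.newton_ridge * np.eye(F.shape[0])
        step = np.linalg.solve(F, grad)
        # damp long steps; the likelihood is concave, short steps are safe
        norm = np.max(np.abs(step))
        if norm > 1.0:
            step = step / norm
        theta[free] += step
        theta[:n] = np.clip(theta[:n], -settings.h_max, settings.h_max)
    return theta


def _fit_sa(states: np.ndarray, eps_a: np.ndarray, eps_s: np.ndarray,
            kinds: list[str], settings: FitSettings,
            rng: np.random.Generator,
            theta0: Optional[np.ndarray] = None,
            free_mask: Optional[np.ndarray] = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Robbins-Monro moment matching with persistent Gibbs chains.

    One block of ``n_chains`` persistent chains is kept per distinct
    environment; each iteration performs a single Gibbs sweep per chain,
    then nudges theta along (observed - simulated) moments.
    """
    m, n = states.shape
    env = np.column_stack([eps_a, eps_s])
    uniq, inverse = _group_environments(env)
    env_w = np.bincount(inverse, minlength=uniq.shape[0]) / m
    obs = _suff_stats(states, eps_a, eps_s)
    n_par = obs.size
    theta = np.zeros(n_par) if theta0 is None else theta0.copy()
    free = (np.ones(n_par, dtype=bool) if free_mask is None else free_mask)

    k = settings.n_chains
    n_env = uniq.shape[0]
    chains = (rng.random((n_env * k, n)) < 0.5).astype(float)
    for i, kind in enumerate(kinds):
        if kind != "binary":
            chains[:, i] = rng.random(n_env * k)
    chain_ea = np.repeat(uniq[:, 0], k)
    chain_es = np.repeat(uniq[:, 1], k)
    chain_w = np.repeat(env_w / k, k)
    binary = np.array([kd == "binary" for kd in kinds])

    trace = np.empty(settings.n_iter)
    tail_start = int(settings.n_iter * (1.0 - settings.polyak_frac))
    theta_sum = np.zeros(n_par)
    tail_count = 0
    for t in range(settings.n_iter):
        params = MaxEntParams.from_vector(theta, n)
        f = params.h[None, :] + chain_ea[:, None] * params.g_a[None, :] \
            + chain_es[:, None] * params.g_s[None, :]
        u = rng.random((chains.shape[0], n))
        for i in range(n):
            local = chains @ params.J[i] + f[:, i]
            if binary[i]:
                chains[:, i] = (u[:, i] < expit(local)).astype(float)
            else:
                chains[:, i] = _truncated_exp_sample(local, u[:, i])
        sim = _suff_stats(chains, chain_ea, chain_es, weights=chain_w)
        mismatch = obs - sim
        a_t = settings.a0 / (1.0 + t / settings.tau)
        theta[free] += a_t * mismatch[free]
        theta[:n] = np.clip(theta[:n], -settings.h_max, settings.h_max)
        trace[t] = np.max(np.abs(mismatch[free])) if free.any() else 0.0
        if t >= tail_start:
            theta_sum += theta
            tail_count += 1
    if tail_count:
        theta = theta_sum / tail_count
    return theta, trace


def _prepare_fit_inputs(components, env):
    """Accept ComponentMatrix/EnvironmentMatrix or plain arrays."""
    if hasattr(components, "values_array"):
        states = components.values_array
        kinds = list(components.component_kinds)
        names = list(components.component_names)
    else:
        states = np.asarray(components, dtype=float)
        kinds = ["binary"] * states.shape[1]
        names = None
    if hasattr(env, "values_array"):
        env_arr = env.values_array
    else:
        env_arr = np.asarray(env, dtype=float)
    if env_arr.shape[0] != states.shape[0]:
        raise ValueError("components and environment row counts differ")
    return states, kinds, names, env_arr


def _free_mask_and_warnings(states: np.ndarray, env_arr: np.ndarray,
                            kinds: list[str]) -> np.ndarray:
    """Freeze unidentifiable parameters (constant environment columns)."""
    n = states.shape[1]
    n_pairs = n * (n - 1) // 2
    free = np.ones(2 * n + n_pairs + n, dtype=bool)
    if np.ptp(env_arr[:, 0]) == 0:
        free[n + n_pairs:2 * n + n_pairs] = False
        if np.any(env_arr[:, 0] != 0):
            warnings.warn("constant nonzero eps_a: g_a fixed at 0 "
                          "(absorbed into h)", stacklevel=3)
    if np.ptp(env_arr[:, 1]) == 0:
        free[2 * n + n_pairs:] = False
        if np.any(env_arr[:, 1] != 0):
            warnings.warn("constant nonzero eps_s: g_s fixed at 0 "
                          "(absorbed into h)", stacklevel=3)
    col_min = states.min(axis=0)
    col_max = states.max(axis=0)
    degenerate = [i for i in range(n)
                  if kinds[i] == "binary" and col_min[i] == col_max[i]]
    if degenerate:
        warnings.warn(
            f"components always present/absent: {degenerate}; their h "
            "diverges and is capped at +-h_max", stacklevel=3)
    return free


def fit(components, env, settings: Optional[FitSettings] = None,
        seed: int = 0) -> FitResult:
    """Maximum-likelihood fit of (h, J, g_a, g_s) to observed states.

    ``components`` is a ComponentMatrix (or plain binary array),
    ``env`` the aligned EnvironmentMatrix (or (m, 2) array of
    (eps_a, eps_s)).  Backend "sa" runs Robbins-Monro stochastic
    approximation; "exact" (all-binary, small N) maximises the exact
    likelihood by Newton ascent; "auto" picks exact when available.
    """
    settings = settings or FitSettings()
    states, kinds, names, env_arr = _prepare_fit_inputs(components, env)
    n = states.shape[1]
    all_binary = all(k == "binary" for k in kinds)
    backend = settings.backend
    if backend == "auto":
        backend = ("exact" if all_binary and n <= settings.exact_n_max
                   else "sa")
    if backend == "exact" and not all_binary:
        raise ValueError("exact backend requires all-binary components")
    if backend == "exact" and n > settings.exact_n_max:
        raise ValueError(
            f"exact backend limited to N <= {settings.exact_n_max}")
    free = _free_mask_and_warnings(states, env_arr, kinds)
    rng = np.random.default_rng(seed)
    trace = None
    if backend == "exact":
        uniq, inverse = _group_environments(env_arr)
        env_w = np.bincount(inverse, minlength=uniq.shape[0]) / states.shape[0]
        be = _ExactBackend(n, uniq, env_w)
        obs = _suff_stats(states, env_arr[:, 0], env_arr[:, 1])
        theta = _fit_exact(obs, be, settings, free_mask=free)
    else:
        theta, trace = _fit_sa(states, env_arr[:, 0], env_arr[:, 1], kinds,
                               settings, rng, free_mask=free)
    params = MaxEntParams.from_vector(theta, n, names)
    return FitResult(params=params, seed=seed, trace=trace,
                     settings=settings)


# ---------------------------------------------------------------------------
# Significance by repeated estimation runs


def _simulate_dataset(params: MaxEntParams, env_arr: np.ndarray,
                      kinds: list[str], settings: FitSettings,
                      rng: np.random.Generator, all_binary: bool,
                      exact_backend: Optional[_ExactBackend],
                      counts: Optional[np.ndarray]) -> np.ndarray:
    """Draw a dataset of the same design (same env rows) from ``params``."""
    if exact_backend is not None:
        states, _, _ = exact_backend.sample(params, counts, rng)
        return states
    n = params.n_components
    out = np.empty((env_arr.shape[0], n))
    uniq, inverse = _group_environments(env_arr)
    for gi, (ea, es) in enumerate(uniq):
        rows = np.flatnonzero(inverse == gi)
        samples = gibbs_sample(params, (ea, es), n_sweeps=50 + 5 * rows.size,
                               seed=rng, component_kinds=kinds,
                               burn_in=50, thin=5)
        out[rows] = samples[:rows.size]
    return out


def significance(components, env, settings: Optional[FitSettings] = None,
                 n_reps: int = 2000, seed: int = 0,
                 resample: Literal["parametric", "nonparametric"]
                 = "parametric") -> FitResult:
    """Per-parameter p-values from repeated estimation runs.

    The estimation algorithm is re-run ``n_reps`` times with independent
    RNG streams; by default each run re-simulates assemblages of the same
    size and environmental design from the fitted model before refitting
    (parametric resampling), so the spread of the replicate estimates
    tracks the sampling variability of the estimator.  With
    ``resample="nonparametric"`` each run refits a bootstrap resample of
    the observed samples instead.

    The two-sided p-value of each parameter is
    ``2 * min(frac(theta_rep <= 0), frac(theta_rep >= 0))`` floored at
    ``1 / (n_reps + 1)``.
    """
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} < 100 gives unstable p-values",
                      stacklevel=2)
    settings = settings or FitSettings()
    states, kinds, names, env_arr = _prepare_fit_inputs(components, env)
    n = states.shape[1]
    m = states.shape[0]
    base = fit(components, env, settings=settings, seed=seed)
    theta_hat = base.params.as_vector()
    free = _free_mask_and_warnings(states, env_arr, kinds)

    all_binary = all(k == "binary" for k in kinds)
    use_exact = all_binary and n <= settings.exact_n_max \
        and settings.backend != "sa"
    uniq, inverse = _group_environments(env_arr)
    counts = np.bincount(inverse, minlength=uniq.shape[0])
    env_w = counts / m
    be = _ExactBackend(n, uniq, env_w) if use_exact else None

    rng = np.random.default_rng(seed)
    rep_thetas = np.empty((n_reps, theta_hat.size))
    for r in range(n_reps):
        if resample == "parametric":
            rep_states = _simulate_dataset(base.params, env_arr, kinds,
                                           settings, rng, all_binary, be,
                                           counts)
            rep_env = env_arr
        else:
            idx = rng.integers(0, m, size=m)
            rep_states = states[idx]
            rep_env = env_arr[idx]
        if use_exact:
            r_uniq, r_inv = _group_environments(rep_env)
            r_be = be if resample == "parametric" else _ExactBackend(
                n, r_uniq, np.bincount(r_inv, minlength=r_uniq.shape[0]) / m)
            obs = _suff_stats(rep_states, rep_env[:, 0], rep_env[:, 1])
            rep_thetas[r] = _fit_exact(obs, r_be, settings,
                                       theta0=theta_hat.copy(),
                                       free_mask=free)
        else:
            theta_r, _ = _fit_sa(rep_states, rep_env[:, 0], rep_env[:, 1],
                                 kinds, settings, rng,
                                 theta0=theta_hat.copy(), free_mask=free)
            rep_thetas[r] = theta_r

    frac_le = np.mean(rep_thetas <= 0, axis=0)
    frac_ge = np.mean(rep_thetas >= 0, axis=0)
    p = 2.0 * np.minimum(frac_le, frac_ge)
    p = np.clip(p, 1.0 / (n_reps + 1), 1.0)
    p[~free] = 1.0
    p_params = MaxEntParams.from_vector(p, n, names)
    return FitResult(params=base.params, seed=seed, trace=base.trace,
                     n_reps=n_reps, p_values=p_params, settings=settings,
                     replicate_params=rep_thetas)
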