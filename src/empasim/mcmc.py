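"""Hamiltonian Monte Carlo with the No-U-Turn sampler (NUTS).

A compact, dependency-free NUTS implementation for smooth low-dimensional
posteriors: multinomial sampling over the trajectory, dual-averaging step
size adaptation toward a target acceptance statistic, and diagonal mass
matrix estimation from a warm-up window.  The target density is supplied
as a callable returning ``(log p(x), d log p(x)/dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSResult", "nuts", "sample_chains"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NUTSResult:
    draws: np.ndarray          # (n_draws, dim) post-warm-up draws
    logp: np.ndarray           # (n_draws,) log density at each draw
    n_divergent: int           # post-warm-up divergent transitions
    step_size: float
    inv_mass: np.ndarray       # diagonal of the inverse mass matrix
    mean_accept: float         # mean acceptance statistic post-warm-up
    max_treedepth_hits: int


class _State:
    __slots__ = ("q", "p", "grad", "logp")

    def __init__(self, q, p, grad, logp):
        self.q, self.p, self.grad, self.logp = q, p, grad, logp


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _leapfrog(logp_grad, state: _State, eps: float, inv_mass: np.ndarray) -> _State:
    p_half = state.p + 0.5 * eps * state.grad
    q_new = state.q + eps * inv_mass * p_half
    logp_new, grad_new = logp_grad(q_new)
    if not np.isfinite(logp_new):
        logp_new, grad_new = -np.inf, np.zeros_like(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return _State(q_new, p_new, grad_new, logp_new)


class _Tree:
    """One NUTS trajectory tree (recursive doubling)."""

    def __init__(self, logp_grad, inv_mass, eps, h0, rng):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.eps = eps
        self.h0 = h0  # Hamiltonian at the initial point
        self.rng = rng
        self.sum_alpha = 0.0
        self.n_alpha = 0
        self.divergent = False

    def _log_w(self, state: _State) -> float:
        if not np.isfinite(state.logp):
            return -np.inf
        return self.h0 - (-state.logp + _kinetic(state.p, self.inv_mass))

    def build(self, state: _State, direction: int, depth: int):
        """Return (minus, plus, proposal, log_sum_w, turning)."""
        if depth == 0:
            new = _leapfrog(self.logp_grad, state, direction * self.eps, self.inv_mass)
            log_w = self._log_w(new)
            if -log_w > _DIVERGENCE_THRESHOLD:
                self.divergent = True
            self.sum_alpha += float(np.exp(min(0.0, log_w)))
            self.n_alpha += 1
            return new, new, new, log_w, False
        minus, plus, prop, log_w, turning = self.build(state, direction, depth - 1)
        if self.divergent or turning:
            return minus, plus, prop, log_w, turning
        edge = plus if direction == 1 else minus
        minus2, plus2, prop2, log_w2, turning2 = self.build(edge, direction, depth - 1)
        if direction == 1:
            plus = plus2
        else:
            minus = minus2
        total = np.logaddexp(log_w, log_w2)
        if not self.divergent and np.isfinite(log_w2):
            if np.log(self.rng.uniform()) < log_w2 - total:
                prop = prop2
        turning = turning2 or self._uturn(minus, plus)
        return minus, plus, prop, total, turning

    def _uturn(self, minus: _State, plus: _State) -> bool:
        dq = plus.q - minus.q
        return (np.dot(dq, self.inv_mass * minus.p) < 0
                or np.dot(dq, self.inv_mass * plus.p) < 0)


def _transition(logp_grad, state: _State, eps, inv_mass, rng, max_treedepth):
    p0 = rng.normal(size=state.q.size) / np.sqrt(inv_mass)
    state = _State(state.q, p0, state.grad, state.logp)
    h0 = -state.logp + _kinetic(p0, inv_mass)
    tree = _Tree(logp_grad, inv_mass, eps, h0, rng)
    minus = plus = prop = state
    log_sum_w = 0.0  # weight of the initial point
    depth = 0
    hit_max = False
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = plus if direction == 1 else minus
        minus2, plus2, prop2, log_w2, turning = tree.build(edge, direction, depth)
        if tree.divergent:
            break
        if direction == 1:
            plus = plus2
        else:
            minus = minus2
        if not turning and np.isfinite(log_w2):
            if np.log(rng.uniform()) < log_w2 - log_sum_w:
                prop = prop2
            log_sum_w = np.logaddexp(log_sum_w, log_w2)
        if turning or tree._uturn(minus, plus):
            break
        depth += 1
    else:
        hit_max = True
    accept = tree.sum_alpha / max(tree.n_alpha, 1)
    return prop, accept, tree.divergent, hit_max


def _find_initial_step(logp_grad, state: _State, inv_mass, rng) -> float:
    eps = 0.1
    p0 = rng.normal(size=state.q.size) / np.sqrt(inv_mass)
    h0 = -state.logp + _kinetic(p0, inv_mass)
    new = _leapfrog(logp_grad, _State(state.q, p0, state.grad, state.logp), eps, inv_mass)
    log_ratio = h0 - (-new.logp + _kinetic(new.p, inv_mass))
    direction = 1 if log_ratio > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        new = _leapfrog(logp_grad, _State(state.q, p0, state.grad, state.logp), eps, inv_mass)
        log_ratio = h0 - (-new.logp + _kinetic(new.p, inv_mass))
        if not np.isfinite(log_ratio):
            log_ratio = -np.inf
        if (direction == 1) != (log_ratio > np.log(0.5)):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.m = 0
        self.h_bar = 0.0
        self.log_eps_bar = np.log(eps0)
        self.log_eps = np.log(eps0)

    def update(self, accept: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def nuts(
    logp_and_grad,
    x0: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    init_inv_mass: np.ndarray | None = None,
) -> NUTSResult:
    """Run one NUTS chain.

    Warm-up: dual-averaging step-size adaptation throughout, with the
    diagonal inverse mass matrix re-estimated once from the draws of the
    middle warm-up window.  Post-warm-up, the averaged step size is frozen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    state = _State(q, np.zeros_like(q), grad, logp)
    inv_mass = (np.ones(q.size) if init_inv_mass is None
                else np.asarray(init_inv_mass, dtype=float).copy())

    eps = _find_initial_step(logp_and_grad, state, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    mass_window = (int(0.15 * n_warmup), int(0.75 * n_warmup))
    window_draws: list[np.ndarray] = []

    for m in range(n_warmup):
        state, accept, _, _ = _transition(logp_and_grad, state, eps, inv_mass, rng, max_treedepth)
        eps = da.update(accept)
        if mass_window[0] <= m < mass_window[1]:
            window_draws.append(state.q.copy())
        if m == mass_window[1] and len(window_draws) > 10:
            w = np.asarray(window_draws)
            var = np.var(w, axis=0, ddof=1)
            n = w.shape[0]
            inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
            eps = _find_initial_step(logp_and_grad, state, inv_mass, rng)
            da = _DualAveraging(eps, target_accept)

    eps = float(np.exp(da.log_eps_bar)) if n_warmup > 0 else eps
    draws = np.empty((n_draws, q.size))
    logps = np.empty(n_draws)
    n_div = 0
    n_maxdepth = 0
    acc = 0.0
    for i in range(n_draws):
        state, accept, div, hit = _transition(logp_and_grad, state, eps, inv_mass, rng,
                                              max_treedepth)
        draws[i] = state.q
        logps[i] = state.logp
        n_div += int(div)
        n_maxdepth += int(hit)
        acc += accept
    return NUTSResult(draws, logps, n_div, eps, inv_mass,
                      acc / max(n_draws, 1), n_maxdepth)


def sample_chains(
    logp_and_grad,
    inits,
    n_warmup: int = 500,
    n_draws: int = 1000,
    seed: int = 0,
    **kwargs,
):
    """Run several independent chains; returns (draws (C, N, d), results)."""
    inits = [np.asarray(x, dtype=float) for x in inits]
    if len(inits) < 1:
        raise ValueError("need at least one chain")
    seeds = np.random.SeedSequence(seed).spawn(len(inits))
    results = [
        nuts(logp_and_grad, x0, n_warmup, n_draws,
             seed=np.random.default_rng(s), **kwargs)
        for x0, s in zip(inits, seeds)
    ]
    return np.stack([r.draws for r in results]), results
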