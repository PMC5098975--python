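"""Hamiltonian Monte Carlo: a multinomial no-U-turn sampler.

A self-contained gradient-based sampler operating on an unconstrained
parameter vector: dynamic trajectory length via the no-U-turn
criterion, multinomial sampling of states along the trajectory,
dual-averaging step-size adaptation towards a target acceptance
statistic, and windowed estimation of a diagonal mass matrix during
warmup.  The fitting front-ends pass in the model's log-density and
analytic gradient; convergence is judged afterwards from the draws
(R-hat / effective sample size), which is the contract — not the
sampler's identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_MAX_DELTA_ENERGY = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsStats:
    """Per-chain sampler statistics."""

    step_size: float
    divergences: int
    mean_accept: float
    n_leapfrog: int
    inv_mass: np.ndarray


class _State:
    __slots__ = ("theta", "p", "logp", "grad")

    def __init__(self, theta, p, logp, grad):
        self.theta = theta
        self.p = p
        self.logp = logp
        self.grad = grad


class _Tree:
    """Accumulator for one trajectory doubling."""

    __slots__ = (
        "left", "right", "proposal", "log_sum_w", "divergent", "stop",
        "n_leapfrog", "sum_accept", "n_accept",
    )

    def __init__(self, left, right, proposal, log_sum_w, divergent, stop,
                 n_leapfrog, sum_accept, n_accept):
        self.left = left
        self.right = right
        self.proposal = proposal
        self.log_sum_w = log_sum_w
        self.divergent = divergent
        self.stop = stop
        self.n_leapfrog = n_leapfrog
        self.sum_accept = sum_accept
        self.n_accept = n_accept


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * inv_mass, p))


def _leapfrog(state: _State, eps: float, inv_mass: np.ndarray,
              logp_grad: Callable) -> _State:
    p = state.p + 0.5 * eps * state.grad
    theta = state.theta + eps * (inv_mass * p)
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return _State(theta, p, logp, grad)


def _uturn(left: _State, right: _State, inv_mass: np.ndarray) -> bool:
    dtheta = right.theta - left.theta
    return (
        float(np.dot(dtheta, inv_mass * left.p)) < 0.0
        or float(np.dot(dtheta, inv_mass * right.p)) < 0.0
    )


def _build_tree(state: _State, direction: int, depth: int, eps: float,
                h0: float, inv_mass: np.ndarray, logp_grad: Callable,
                rng: np.random.Generator) -> _Tree:
    if depth == 0:
        new = _leapfrog(state, direction * eps, inv_mass, logp_grad)
        if np.isfinite(new.logp):
            energy = -new.logp + _kinetic(new.p, inv_mass)
            d_energy = energy - h0
        else:
            d_energy = np.inf
        divergent = not np.isfinite(d_energy) or d_energy > _MAX_DELTA_ENERGY
        log_w = -np.inf if divergent else -d_energy
        accept = 0.0 if divergent else math.exp(min(0.0, -d_energy))
        return _Tree(new, new, new, log_w, divergent, False, 1, accept, 1)

    first = _build_tree(state, direction, depth - 1, eps, h0, inv_mass,
                        logp_grad, rng)
    if first.divergent or first.stop:
        return first
    outer = first.right if direction > 0 else first.left
    second = _build_tree(outer, direction, depth - 1, eps, h0, inv_mass,
                         logp_grad, rng)

    n_leap = first.n_leapfrog + second.n_leapfrog
    sum_acc = first.sum_accept + second.sum_accept
    n_acc = first.n_accept + second.n_accept
    if second.divergent or second.stop:
        return _Tree(first.left, first.right, first.proposal, first.log_sum_w,
                     second.divergent, True, n_leap, sum_acc, n_acc)

    log_sum_w = np.logaddexp(first.log_sum_w, second.log_sum_w)
    proposal = first.proposal
    if math.log(rng.uniform()) < second.log_sum_w - log_sum_w:
        proposal = second.proposal
    left = first.left if direction > 0 else second.left
    right = second.right if direction > 0 else first.right
    stop = _uturn(left, right, inv_mass)
    return _Tree(left, right, proposal, log_sum_w, False, stop, n_leap,
                 sum_acc, n_acc)


def _nuts_step(state: _State, eps: float, inv_mass: np.ndarray,
               logp_grad: Callable, rng: np.random.Generator,
               max_depth: int) -> Tuple[_State, float, bool, int]:
    p0 = rng.standard_normal(state.theta.shape) / np.sqrt(inv_mass)
    current = _State(state.theta, p0, state.logp, state.grad)
    h0 = -current.logp + _kinetic(p0, inv_mass)

    left = current
    right = current
    proposal = current
    log_sum_w = 0.0  # weight of the initial point relative to exp(-h0)
    sum_accept = 0.0
    n_accept = 0
    n_leapfrog = 0
    divergent = False

    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        start = right if direction > 0 else left
        tree = _build_tree(start, direction, depth, eps, h0, inv_mass,
                           logp_grad, rng)
        sum_accept += tree.sum_accept
        n_accept += tree.n_accept
        n_leapfrog += tree.n_leapfrog
        if tree.divergent:
            divergent = True
            break
        if tree.stop:
            # internal U-turn in the new subtree: discard it entirely
            break
        # biased progressive sampling favours the fresh subtree
        if math.log(rng.uniform()) < tree.log_sum_w - log_sum_w:
            proposal = tree.proposal
        log_sum_w = np.logaddexp(log_sum_w, tree.log_sum_w)
        if direction > 0:
            right = tree.right
        else:
            left = tree.left
        if _uturn(left, right, inv_mass):
            break

    accept_stat = sum_accept / max(n_accept, 1)
    return proposal, accept_stat, divergent, n_leapfrog


def _find_initial_step(state: _State, inv_mass: np.ndarray,
                       logp_grad: Callable, rng: np.random.Generator) -> float:
    eps = 1.0
    p0 = rng.standard_normal(state.theta.shape) / np.sqrt(inv_mass)
    s0 = _State(state.theta, p0, state.logp, state.grad)
    h0 = -s0.logp + _kinetic(p0, inv_mass)
    new = _leapfrog(s0, eps, inv_mass, logp_grad)
    h1 = (-new.logp + _kinetic(new.p, inv_mass)) if np.isfinite(new.logp) \
        else np.inf
    direction = 1 if (h0 - h1) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        new = _leapfrog(s0, eps, inv_mass, logp_grad)
        h1 = (-new.logp + _kinetic(new.p, inv_mass)) if np.isfinite(new.logp) \
            else np.inf
        crossed = (h0 - h1) > math.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return eps


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink towards unit scale as Stan does, to keep the estimate sane
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _adaptation_windows(n_warmup: int):
    """(start, end) slices of warmup used to re-estimate the mass matrix."""
    init_buffer, term_buffer, base = 75, 50, 25
    if n_warmup < init_buffer + term_buffer + base:
        init_buffer = max(5, int(0.15 * n_warmup))
        term_buffer = max(5, int(0.10 * n_warmup))
        base = max(5, n_warmup - init_buffer - term_buffer)
    windows = []
    start = init_buffer
    size = base
    while start + size < n_warmup - term_buffer:
        next_size = size * 2
        if start + size + next_size >= n_warmup - term_buffer:
            size = n_warmup - term_buffer - start
        windows.append((start, start + size))
        start += size
        size = next_size
    if not windows and n_warmup > init_buffer + term_buffer:
        windows.append((init_buffer, n_warmup - term_buffer))
    return windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
) -> Tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain and return post-warmup draws.

    Parameters
    ----------
    logp_grad : callable
        Maps an unconstrained parameter vector to
        ``(log density, gradient)``.
    theta0 : initial position.
    n_warmup, n_draws : iterations discarded / retained.
    rng : numpy Generator driving all sampler randomness.
    target_accept : dual-averaging target for the acceptance statistic.
    max_depth : maximum tree depth (2**depth leapfrog steps).
    """
    theta0 = np.asarray(theta0, dtype=float)
    dim = theta0.shape[0]
    logp, grad = logp_grad(theta0)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    state = _State(theta0, np.zeros(dim), logp, grad)
    inv_mass = np.ones(dim)

    eps = _find_initial_step(state, inv_mass, logp_grad, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    windows = _adaptation_windows(n_warmup)
    window_idx = 0
    welford = _Welford(dim)

    draws = np.empty((n_draws, dim))
    divergences = 0
    accept_sum = 0.0
    total_leapfrog = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        state, accept_stat, divergent, n_leap = _nuts_step(
            state, eps, inv_mass, logp_grad, rng, max_depth
        )
        total_leapfrog += n_leap
        if warming:
            adapt_count += 1
            h_bar = (1.0 - 1.0 / (adapt_count + t0)) * h_bar + (
                target_accept - accept_stat
            ) / (adapt_count + t0)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = math.exp(log_eps)

            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= it < w_end:
                    welford.update(state.theta)
                if it == w_end - 1:
                    inv_mass = welford.variance()
                    welford = _Welford(dim)
                    window_idx += 1
                    eps = _find_initial_step(state, inv_mass, logp_grad, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = state.theta
            accept_sum += accept_stat
            if divergent:
                divergences += 1

    stats = NutsStats(
        step_size=eps,
        divergences=divergences,
        mean_accept=accept_sum / max(n_draws, 1),
        n_leapfrog=total_leapfrog,
        inv_mass=inv_mass,
    )
    return draws, stats
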