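"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained implementation of the dynamic Hamiltonian Monte Carlo
algorithm (slice-sampling tree variant) used to fit the hierarchical dialect
model. The interface is a single function, :func:`sample_nuts`, taking a
callable ``logp_and_grad(theta) -> (float, ndarray)`` for the log target
density and its gradient.

Adaptation follows the usual windowed schedule: an initial step-size-only
phase, a sequence of doubling windows in which the diagonal inverse mass
matrix is re-estimated from the warmup draws, and a final step-size-only
phase. Post-warmup draws are produced with adaptation frozen.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_nuts"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


def _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass):
    r1 = r + (0.5 * eps) * grad
    theta1 = theta + eps * (inv_mass * r1)
    logp1, grad1 = logp_and_grad(theta1)
    r1 += (0.5 * eps) * grad1
    return theta1, r1, logp1, grad1


def _kinetic(r, inv_mass):
    rm = inv_mass * r
    return 0.5 * float(rm.dot(r))


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop",
        "n_valid", "keep_going", "alpha", "n_alpha", "diverged",
    )


def _build_tree(logp_and_grad, theta, r, grad, log_u, v, depth, eps, h0, inv_mass, rng):
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_and_grad, theta, r, grad, v * eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.n_valid = 1 if log_u <= h1 else 0
        t.diverged = (not np.isfinite(h1)) or (log_u >= h1 + _MAX_DELTA_H)
        t.keep_going = not t.diverged
        t.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t
    t = _build_tree(logp_and_grad, theta, r, grad, log_u, v, depth - 1, eps, h0, inv_mass, rng)
    if t.keep_going:
        if v == -1:
            t2 = _build_tree(
                logp_and_grad, t.theta_minus, t.r_minus, t.grad_minus,
                log_u, v, depth - 1, eps, h0, inv_mass, rng,
            )
            t.theta_minus, t.r_minus, t.grad_minus = t2.theta_minus, t2.r_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_and_grad, t.theta_plus, t.r_plus, t.grad_plus,
                log_u, v, depth - 1, eps, h0, inv_mass, rng,
            )
            t.theta_plus, t.r_plus, t.grad_plus = t2.theta_plus, t2.r_plus, t2.grad_plus
        total = t.n_valid + t2.n_valid
        if total > 0 and rng.random() < t2.n_valid / total:
            t.theta_prop, t.logp_prop, t.grad_prop = t2.theta_prop, t2.logp_prop, t2.grad_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.diverged = t.diverged or t2.diverged
        t.n_valid = total
        span = t.theta_plus - t.theta_minus
        t.keep_going = (
            t2.keep_going
            and np.dot(span, inv_mass * t.r_minus) >= 0
            and np.dot(span, inv_mass * t.r_plus) >= 0
        )
    return t


def _find_initial_step(logp_and_grad, theta, inv_mass, rng):
    eps = 1.0
    logp, grad = logp_and_grad(theta)
    r = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_and_grad, theta, r, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def sample_nuts(
    logp_and_grad,
    theta0: np.ndarray,
    n_warmup: int = 1000,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    max_depth: int = 10,
    target_accept: float = 0.8,
):
    """Run one NUTS chain; returns (draws (n_samples, dim), stats dict).

    ``stats`` holds per-draw tree depths, divergence flags, and the adapted
    step size / inverse mass for the run log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.array(theta0, dtype=float)
    dim = len(theta)
    inv_mass = np.ones(dim)
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_and_grad, theta, inv_mass, rng)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    m_da = 0  # dual-averaging iteration counter, restarted with each window

    # windowed mass adaptation: [0, init) step only; [init, warmup-term) variance
    # windows doubling from `base`; [warmup-term, warmup) step only
    init_phase, term_phase, base = 75, 50, 25
    if n_warmup < init_phase + term_phase + base:
        init_phase = max(1, n_warmup // 5)
        term_phase = max(1, n_warmup // 10)
        base = max(1, n_warmup - init_phase - term_phase)
    window_ends = []
    w_start, w_len = init_phase, base
    while w_start + w_len < n_warmup - term_phase:
        if w_start + 3 * w_len >= n_warmup - term_phase:
            w_len = (n_warmup - term_phase) - w_start
        window_ends.append(w_start + w_len)
        w_start += w_len
        w_len *= 2

    window_buf: list[np.ndarray] = []
    draws = np.empty((n_samples, dim))
    depths = np.zeros(n_samples, dtype=int)
    divergent = np.zeros(n_samples, dtype=bool)
    n_divergent_warmup = 0

    for it in range(n_warmup + n_samples):
        warmup = it < n_warmup
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - _kinetic(r, inv_mass)
        log_u = h0 - rng.exponential()
        t = _Tree()
        t.theta_minus = t.theta_plus = theta
        t.r_minus = t.r_plus = r
        t.grad_minus = t.grad_plus = grad
        t.theta_prop, t.logp_prop, t.grad_prop = theta, logp, grad
        n_valid = 1
        keep_going = True
        depth = 0
        alpha, n_alpha = 0.0, 0
        diverged = False
        while keep_going and depth < max_depth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                sub = _build_tree(
                    logp_and_grad, t.theta_minus, t.r_minus, t.grad_minus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                t.theta_minus, t.r_minus, t.grad_minus = sub.theta_minus, sub.r_minus, sub.grad_minus
            else:
                sub = _build_tree(
                    logp_and_grad, t.theta_plus, t.r_plus, t.grad_plus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                t.theta_plus, t.r_plus, t.grad_plus = sub.theta_plus, sub.r_plus, sub.grad_plus
            if sub.keep_going and sub.n_valid > 0 and rng.random() < sub.n_valid / n_valid:
                t.theta_prop, t.logp_prop, t.grad_prop = sub.theta_prop, sub.logp_prop, sub.grad_prop
            alpha += sub.alpha
            n_alpha += sub.n_alpha
            if sub.diverged:
                diverged = True
            n_valid += sub.n_valid
            span = t.theta_plus - t.theta_minus
            keep_going = (
                sub.keep_going
                and np.dot(span, inv_mass * t.r_minus) >= 0
                and np.dot(span, inv_mass * t.r_plus) >= 0
            )
            depth += 1
        theta, logp, grad = t.theta_prop, t.logp_prop, t.grad_prop

        if warmup:
            if diverged:
                n_divergent_warmup += 1
            # dual averaging
            m_da += 1
            m = m_da
            accept_stat = alpha / max(n_alpha, 1)
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
            log_eps = mu_da - np.sqrt(m) / gamma * h_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # mass windows
            if window_ends and it >= init_phase:
                window_buf.append(theta.copy())
            if window_ends and it + 1 == window_ends[0]:
                buf = np.asarray(window_buf)
                if len(buf) >= 10:
                    var = buf.var(axis=0, ddof=1)
                    n_buf = len(buf)
                    # regularize toward unit scale as Stan does
                    inv_mass = (n_buf / (n_buf + 5.0)) * var + (5.0 / (n_buf + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    eps = _find_initial_step(logp_and_grad, theta, inv_mass, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
                    m_da = 0
                window_buf = []
                window_ends.pop(0)
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - n_warmup
            draws[i] = theta
            depths[i] = depth
            divergent[i] = diverged

    stats = {
        "step_size": eps,
        "inv_mass": inv_mass,
        "tree_depth": depths,
        "divergent": divergent,
        "n_divergent_warmup": n_divergent_warmup,
    }
    return draws, stats
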