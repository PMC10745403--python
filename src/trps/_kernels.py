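"""Compiled inner loops.

All heavy propagation (Langevin steps, chain steps, shooting halves,
umbrella runs, first-passage runs) happens here.  Continuous potentials
enter as polynomial coefficients of dU/dx (lowest order first) so the
kernels never take Python callbacks; arbitrary callables are handled by
the slow pure-Python steppers in :mod:`trps.dynamics`.

Every kernel seeds numba's own RNG stream from an explicit integer, so a
given (inputs, seed) pair reproduces bit-identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CENSORED = -1
HIT_LO = 0
HIT_HI = 1


@njit(cache=True, inline="always")
def _polyval(coeffs, x):
    acc = 0.0
    for i in range(coeffs.size - 1, -1, -1):
        acc = acc * x + coeffs[i]
    return acc


@njit(cache=True, inline="always")
def _reflect(x, lo, hi):
    if x < lo:
        x = 2.0 * lo - x
    elif x > hi:
        x = 2.0 * hi - x
    return x


@njit(cache=True)
def run_overdamped(coeffs, x0, n_steps, dt, diff, kBT, x_lo, x_hi,
                   bias_k, bias_c, seed):
    """Euler-Maruyama with optional harmonic bias; returns all frames."""
    np.random.seed(seed)
    xs = np.empty(n_steps + 1)
    xs[0] = x0
    x = x0
    mob = diff / kBT
    amp = np.sqrt(2.0 * diff * dt)
    for i in range(n_steps):
        g = _polyval(coeffs, x) + bias_k * (x - bias_c)
        x = x - mob * g * dt + amp * np.random.normal()
        x = _reflect(x, x_lo, x_hi)
        xs[i + 1] = x
    return xs


@njit(cache=True)
def shoot_overdamped(coeffs, x0, dt, diff, kBT, x_lo, x_hi,
                     plane_lo, plane_hi, max_steps, seed):
    """Propagate from x0 (strictly between the planes) until a plane is
    hit; returns (code, frames up to and including the first frame on or
    beyond the plane)."""
    np.random.seed(seed)
    xs = np.empty(max_steps + 1)
    xs[0] = x0
    x = x0
    mob = diff / kBT
    amp = np.sqrt(2.0 * diff * dt)
    for i in range(max_steps):
        g = _polyval(coeffs, x)
        x = x - mob * g * dt + amp * np.random.normal()
        x = _reflect(x, x_lo, x_hi)
        xs[i + 1] = x
        if x <= plane_lo:
            return HIT_LO, xs[: i + 2].copy()
        if x >= plane_hi:
            return HIT_HI, xs[: i + 2].copy()
    return CENSORED, xs.copy()


@njit(cache=True)
def run_underdamped(coeffs, x0, v0, n_steps, dt, kBT, friction, mass,
                    x_lo, x_hi, bias_k, bias_c, seed):
    """BAOAB Langevin integrator; returns (positions, velocities)."""
    np.random.seed(seed)
    xs = np.empty(n_steps + 1)
    vs = np.empty(n_steps + 1)
    xs[0] = x0
    vs[0] = v0
    x = x0
    v = v0
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kBT / mass * (1.0 - c1 * c1))
    for i in range(n_steps):
        f = -(_polyval(coeffs, x) + bias_k * (x - bias_c))
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        if x < x_lo:
            x = 2.0 * x_lo - x
            v = -v
        elif x > x_hi:
            x = 2.0 * x_hi - x
            v = -v
        f = -(_polyval(coeffs, x) + bias_k * (x - bias_c))
        v += 0.5 * dt * f / mass
        xs[i + 1] = x
        vs[i + 1] = v
    return xs, vs


@njit(cache=True)
def shoot_underdamped(coeffs, x0, v0, dt, kBT, friction, mass,
                      x_lo, x_hi, plane_lo, plane_hi, max_steps, seed):
    """BAOAB propagation until a plane is hit; returns (code, frames, v_end)."""
    np.random.seed(seed)
    xs = np.empty(max_steps + 1)
    xs[0] = x0
    x = x0
    v = v0
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kBT / mass * (1.0 - c1 * c1))
    for i in range(max_steps):
        f = -_polyval(coeffs, x)
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        if x < x_lo:
            x = 2.0 * x_lo - x
            v = -v
        elif x > x_hi:
            x = 2.0 * x_hi - x
            v = -v
        f = -_polyval(coeffs, x)
        v += 0.5 * dt * f / mass
        xs[i + 1] = x
        if x <= plane_lo:
            return HIT_LO, xs[: i + 2].copy(), v
        if x >= plane_hi:
            return HIT_HI, xs[: i + 2].copy(), v
    return CENSORED, xs.copy(), v


@njit(cache=True)
def first_passage_overdamped(coeffs, x0, target, side, dt, diff, kBT,
                             x_lo, x_hi, max_steps, seed):
    """Steps until x crosses ``target`` (side=+1: from below; -1: from
    above); CENSORED if the budget runs out."""
    np.random.seed(seed)
    x = x0
    mob = diff / kBT
    amp = np.sqrt(2.0 * diff * dt)
    for i in range(max_steps):
        g = _polyval(coeffs, x)
        x = x - mob * g * dt + amp * np.random.normal()
        x = _reflect(x, x_lo, x_hi)
        if side > 0:
            if x >= target:
                return i + 1
        else:
            if x <= target:
                return i + 1
    return CENSORED


@njit(cache=True)
def restrained_walk(u_coeffs, beta, lo, hi, x0, n_samples, stride, burn,
                    step_sigma, seed):
    """Metropolis random walk on U restricted to [lo, hi].

    Proposals leaving the region are rejected outright (hard walls), which
    keeps the restricted Boltzmann distribution exact.  Returns
    ``n_samples`` states taken every ``stride`` accepted-or-rejected sweeps
    after ``burn`` sweeps.
    """
    np.random.seed(seed)
    out = np.empty(n_samples)
    x = x0
    u = _polyval(u_coeffs, x)
    total = burn + n_samples * stride
    k = 0
    for i in range(total):
        xp = x + step_sigma * np.random.normal()
        if lo <= xp <= hi:
            up = _polyval(u_coeffs, xp)
            if up <= u or np.random.random() < np.exp(-beta * (up - u)):
                x = xp
                u = up
        if i >= burn and (i - burn) % stride == stride - 1:
            out[k] = x
            k += 1
    return out


@njit(cache=True)
def run_chain(p_left, p_right, s0, n_steps, seed):
    """Discrete-time Metropolis chain; returns the full state sequence."""
    np.random.seed(seed)
    states = np.empty(n_steps + 1, dtype=np.int64)
    states[0] = s0
    s = s0
    for i in range(n_steps):
        r = np.random.random()
        if r < p_left[s]:
            s -= 1
        elif r < p_left[s] + p_right[s]:
            s += 1
        states[i + 1] = s
    return states


@njit(cache=True)
def run_chain_biased(energies, beta, bias_k, bias_c, s0, n_steps, seed):
    """Metropolis chain with a harmonic umbrella bias W(s)=½k(s−c)² added
    to the state energy inside the acceptance ratio."""
    np.random.seed(seed)
    n = energies.size
    states = np.empty(n_steps + 1, dtype=np.int64)
    states[0] = s0
    s = s0
    es = energies[s] + 0.5 * bias_k * (s - bias_c) ** 2
    for i in range(n_steps):
        r = np.random.random()
        sp = s
        if r < 0.5:
            sp = s - 1
        else:
            sp = s + 1
        if 0 <= sp < n:
            ep = energies[sp] + 0.5 * bias_k * (sp - bias_c) ** 2
            if ep <= es or np.random.random() < np.exp(-beta * (ep - es)):
                s = sp
                es = ep
        states[i + 1] = s
    return states


@njit(cache=True)
def shoot_chain(p_left, p_right, s0, plane_lo, plane_hi, max_steps, seed):
    """Chain propagation until reaching plane_lo or plane_hi states."""
    np.random.seed(seed)
    states = np.empty(max_steps + 1, dtype=np.int64)
    states[0] = s0
    s = s0
    for i in range(max_steps):
        r = np.random.random()
        if r < p_left[s]:
            s -= 1
        elif r < p_left[s] + p_right[s]:
            s += 1
        states[i + 1] = s
        if s <= plane_lo:
            return HIT_LO, states[: i + 2].copy()
        if s >= plane_hi:
            return HIT_HI, states[: i + 2].copy()
    return CENSORED, states.copy()


@njit(cache=True)
def first_passage_chain(p_left, p_right, s0, target, max_steps, seed):
    np.random.seed(seed)
    s = s0
    for i in range(max_steps):
        r = np.random.random()
        if r < p_left[s]:
            s -= 1
        elif r < p_left[s] + p_right[s]:
            s += 1
        if s == target:
            return i + 1
    return CENSORED


@njit(cache=True)
def restrained_chain(energies, beta, s_lo, s_hi, s0, n_samples, stride,
                     burn, seed):
    """Metropolis chain restricted to states [s_lo, s_hi] (exits rejected)."""
    np.random.seed(seed)
    out = np.empty(n_samples, dtype=np.int64)
    s = s0
    total = burn + n_samples * stride
    k = 0
    for i in range(total):
        r = np.random.random()
        sp = s - 1 if r < 0.5 else s + 1
        if s_lo <= sp <= s_hi:
            de = energies[sp] - energies[s]
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                s = sp
        if i >= burn and (i - burn) % stride == stride - 1:
            out[k] = s
            k += 1
    return out
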