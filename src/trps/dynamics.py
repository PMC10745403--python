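"""Stochastic propagators with a uniform single-step contract.

Three reversible engines are provided:

* overdamped (Brownian) dynamics, Euler-Maruyama,
* underdamped Langevin dynamics, BAOAB splitting,
* discrete-time Metropolis stepping on a birth-death chain.

``step_*`` functions advance a single :class:`Frame` and are the
reference implementation of the contract; the ``simulate_*`` helpers run
long trajectories through the compiled kernels in :mod:`trps._kernels`
when the potential carries polynomial gradient coefficients, falling back
to the per-step Python path otherwise.

Randomness: one root seed per experiment; every kernel call receives a
seed derived from (root, counter...) through ``numpy.random.SeedSequence``
so forward and backward shooting halves use independent streams and every
run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels
from .landscapes import BirthDeathChain, ParameterError, Potential1D


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite coordinate."""


@dataclass(frozen=True)
class Frame:
    """One sampled phase-space point: coordinates, optional velocities,
    and the integer time index in units of dt."""

    coordinates: np.ndarray
    velocities: Optional[np.ndarray] = None
    step_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "coordinates",
                           np.atleast_1d(np.asarray(self.coordinates, dtype=float)))
        if self.velocities is not None:
            object.__setattr__(self, "velocities",
                               np.atleast_1d(np.asarray(self.velocities, dtype=float)))
        if not np.all(np.isfinite(self.coordinates)):
            raise IntegrationError(f"non-finite coordinates at step {self.step_index}")

    @property
    def q(self) -> float:
        """Reaction coordinate of a 1D frame."""
        return float(self.coordinates[0])


@dataclass(frozen=True)
class EngineConfig:
    """Integrator parameters.

    dt: time step (the unit of all reported rates is 1/dt).
    temperature: kBT (kB = 1).
    friction: collision rate gamma, 1/time; the overdamped diffusion
        constant is D = kBT/(mass*friction).
    """

    dt: float
    temperature: float
    friction: float = 1.0
    mass: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.friction < 0:
            raise ParameterError("friction must be non-negative")

    @property
    def diffusion(self) -> float:
        if self.friction == 0:
            raise ParameterError("overdamped dynamics needs friction > 0")
        return self.temperature / (self.mass * self.friction)

    def with_temperature(self, temperature: float) -> "EngineConfig":
        return replace(self, temperature=temperature)


def kernel_seed(root: int, *counters: int) -> int:
    """Derive an independent 31-bit kernel seed from (root, counters...)."""
    state = np.random.SeedSequence((root,) + tuple(counters)).generate_state(1)
    return int(state[0]) % (2**31)


def draw_velocities(temperature: float, mass: float, rng: np.random.Generator,
                    size: int | tuple = 1) -> np.ndarray:
    """Maxwell-Boltzmann velocities: each component ~ N(0, kBT/mass)."""
    if temperature < 0:
        raise ParameterError("temperature must be non-negative")
    if temperature == 0:
        return np.zeros(size)
    return rng.normal(0.0, np.sqrt(temperature / mass), size=size)


def reverse_velocities(frame: Frame) -> Frame:
    """Negate velocities, keep coordinates; identity for velocity-free frames."""
    if frame.velocities is None:
        return frame
    return Frame(frame.coordinates, -frame.velocities, frame.step_index)


def step_overdamped(frame: Frame, potential: Potential1D, config: EngineConfig,
                    rng: np.random.Generator) -> Frame:
    """One Euler-Maruyama step: x' = x - (D/kBT) U'(x) dt + sqrt(2 D dt) xi."""
    x = frame.q
    D = config.diffusion
    drift = -(D / config.temperature) * float(potential.gradient(x)) * config.dt
    x_new = x + drift + np.sqrt(2.0 * D * config.dt) * rng.standard_normal()
    lo, hi = potential.domain
    if x_new < lo:
        x_new = 2 * lo - x_new
    elif x_new > hi:
        x_new = 2 * hi - x_new
    if not np.isfinite(x_new):
        raise IntegrationError(f"overdamped step diverged at step {frame.step_index}")
    return Frame(np.array([x_new]), None, frame.step_index + 1)


def step_underdamped(frame: Frame, potential: Potential1D, config: EngineConfig,
                     rng: np.random.Generator) -> Frame:
    """One BAOAB step (half-kick, half-drift, OU velocity refresh, half-drift,
    half-kick)."""
    if frame.velocities is None:
        raise ParameterError("underdamped stepping requires velocities")
    x = frame.q
    v = float(frame.velocities[0])
    dt, m = config.dt, config.mass
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(config.temperature / m * (1.0 - c1 * c1))
    v += 0.5 * dt * (-float(potential.gradient(x))) / m
    x += 0.5 * dt * v
    v = c1 * v + c2 * rng.standard_normal()
    x += 0.5 * dt * v
    lo, hi = potential.domain
    if x < lo:
        x, v = 2 * lo - x, -v
    elif x > hi:
        x, v = 2 * hi - x, -v
    v += 0.5 * dt * (-float(potential.gradient(x))) / m
    if not (np.isfinite(x) and np.isfinite(v)):
        raise IntegrationError(f"underdamped step diverged at step {frame.step_index}")
    return Frame(np.array([x]), np.array([v]), frame.step_index + 1)


def step_chain(state: int, chain: BirthDeathChain, rng: np.random.Generator) -> int:
    """One Metropolis move on the chain (reflecting boundaries)."""
    r = rng.random()
    if r < chain.p_left[state]:
        return state - 1
    if r < chain.p_left[state] + chain.p_right[state]:
        return state + 1
    return state


# ---------------------------------------------------------------------------
# fast trajectory runners


def _require_coeffs(potential: Potential1D) -> np.ndarray:
    if potential.grad_coeffs is None:
        raise ParameterError(
            "fast propagation needs a polynomial-gradient potential; "
            "use the step_* functions for arbitrary callables"
        )
    return np.asarray(potential.grad_coeffs, dtype=float)


def energy_coeffs(potential: Potential1D) -> np.ndarray:
    """Polynomial coefficients of U(x) (constant set to 0) obtained by
    integrating the gradient coefficients."""
    g = _require_coeffs(potential)
    u = np.zeros(g.size + 1)
    u[1:] = g / np.arange(1, g.size + 1)
    return u


def simulate_overdamped(potential: Potential1D, x0: float, n_steps: int,
                        config: EngineConfig, seed: int,
                        bias_spring: float = 0.0, bias_center: float = 0.0,
                        ) -> np.ndarray:
    """Overdamped trajectory of n_steps; returns n_steps+1 positions."""
    coeffs = _require_coeffs(potential)
    lo, hi = potential.domain
    xs = _kernels.run_overdamped(coeffs, float(x0), int(n_steps), config.dt,
                                 config.diffusion, config.temperature, lo, hi,
                                 float(bias_spring), float(bias_center),
                                 np.uint32(seed))
    if not np.isfinite(xs[-1]):
        raise IntegrationError("overdamped trajectory diverged")
    return xs


def simulate_underdamped(potential: Potential1D, x0: float, v0: float,
                         n_steps: int, config: EngineConfig, seed: int,
                         bias_spring: float = 0.0, bias_center: float = 0.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    coeffs = _require_coeffs(potential)
    lo, hi = potential.domain
    xs, vs = _kernels.run_underdamped(coeffs, float(x0), float(v0), int(n_steps),
                                      config.dt, config.temperature,
                                      config.friction, config.mass, lo, hi,
                                      float(bias_spring), float(bias_center),
                                      np.uint32(seed))
    if not np.isfinite(xs[-1]):
        raise IntegrationError("underdamped trajectory diverged")
    return xs, vs


def simulate_chain(chain: BirthDeathChain, s0: int, n_steps: int, seed: int,
                   ) -> np.ndarray:
    """Chain trajectory of n_steps; returns n_steps+1 integer states."""
    return _kernels.run_chain(chain.p_left, chain.p_right, int(s0),
                              int(n_steps), np.uint32(seed))


def write_trajectory(path, q: np.ndarray, dt: float) -> None:
    """Columnar text trajectory: step_index, reaction coordinate.

    The header records dt so times can be reconstructed.
    """
    q = np.asarray(q)
    with open(path, "w") as fh:
        fh.write(f"# dt={dt!r}\n")
        fh.write("step_index,q\n")
        for i, v in enumerate(q):
            fh.write(f"{i},{float(v)!r}\n")


def read_trajectory(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().strip()
        dt = float(header.split("=", 1)[1])
        fh.readline()
        q = np.array([float(line.split(",")[1]) for line in fh if line.strip()])
    return q, dt
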