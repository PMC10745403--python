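"""Pluggable dynamics backends.

A *system* bundles what the samplers need to know: how to propagate, how
to shoot a half-trajectory until it reaches a cutting plane, how to draw
equilibrium-restricted configurations inside an interval, and what the
exact free-energy profile over the reaction coordinate looks like (known
in closed form for every bundled synthetic system).

Two backends exist: :class:`ContinuousSystem` (1D potential, overdamped
or underdamped Langevin) and :class:`ChainSystem` (discrete birth-death
chain; one step = one dt, so chain configs use dt = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import EngineConfig, energy_coeffs
from .landscapes import (
    BirthDeathChain,
    ParameterError,
    Potential1D,
    make_chain_from_profile,
    stationary_distribution,
)


class SeedingError(RuntimeError):
    """The restricted-region sampler could not produce seeds."""


@dataclass
class ContinuousSystem:
    """1D continuous potential under Langevin dynamics.

    engine: "overdamped" (Brownian, velocity-free) or "underdamped"
    (BAOAB; shooting reverses the seed velocity for the backward half).
    """

    potential: Potential1D
    engine: str = "overdamped"

    def __post_init__(self):
        if self.engine not in ("overdamped", "underdamped"):
            raise ParameterError(f"unknown engine {self.engine!r}")

    @property
    def discrete(self) -> bool:
        return False

    @property
    def has_velocities(self) -> bool:
        return self.engine == "underdamped"

    def run(self, q0, n_steps, config: EngineConfig, seed,
            bias_spring=0.0, bias_center=0.0, v0=0.0):
        coeffs = np.asarray(self.potential.grad_coeffs, dtype=float)
        lo, hi = self.potential.domain
        if self.engine == "overdamped":
            return _kernels.run_overdamped(
                coeffs, float(q0), int(n_steps), config.dt, config.diffusion,
                config.temperature, lo, hi, float(bias_spring),
                float(bias_center), np.uint32(seed))
        xs, _ = _kernels.run_underdamped(
            coeffs, float(q0), float(v0), int(n_steps), config.dt,
            config.temperature, config.friction, config.mass, lo, hi,
            float(bias_spring), float(bias_center), np.uint32(seed))
        return xs

    def shoot_half(self, q0, v0, plane_lo, plane_hi, config: EngineConfig,
                   max_steps, seed):
        """Propagate until a plane is hit; returns (code, frames, v_end).

        Overdamped engines ignore v0 (the backward half is then an
        independent relaxation from the same seed with fresh noise).
        """
        coeffs = np.asarray(self.potential.grad_coeffs, dtype=float)
        lo, hi = self.potential.domain
        if self.engine == "overdamped":
            code, xs = _kernels.shoot_overdamped(
                coeffs, float(q0), config.dt, config.diffusion,
                config.temperature, lo, hi, float(plane_lo), float(plane_hi),
                int(max_steps), np.uint32(seed))
            return code, xs, None
        code, xs, v_end = _kernels.shoot_underdamped(
            coeffs, float(q0), float(v0), config.dt, config.temperature,
            config.friction, config.mass, lo, hi, float(plane_lo),
            float(plane_hi), int(max_steps), np.uint32(seed))
        return code, xs, v_end

    def first_passage(self, q0, target, side, config: EngineConfig,
                      max_steps, seed) -> int:
        coeffs = np.asarray(self.potential.grad_coeffs, dtype=float)
        lo, hi = self.potential.domain
        return int(_kernels.first_passage_overdamped(
            coeffs, float(q0), float(target), int(side), config.dt,
            config.diffusion, config.temperature, lo, hi, int(max_steps),
            np.uint32(seed)))

    def restrained_seeds(self, lo, hi, n_seeds, config: EngineConfig, seed,
                         stride: int = 10, burn: int = 2000,
                         step_sigma: float | None = None) -> np.ndarray:
        """Exact Boltzmann sampling restricted to [lo, hi] (Metropolis
        random walk with hard-wall rejection of exits)."""
        if not (lo < hi):
            raise SeedingError("empty restraint interval")
        if step_sigma is None:
            step_sigma = 0.3 * (hi - lo)
        u = energy_coeffs(self.potential)
        return _kernels.restrained_walk(
            u, 1.0 / config.temperature, float(lo), float(hi),
            0.5 * (lo + hi), int(n_seeds), int(stride), int(burn),
            float(step_sigma), np.uint32(seed))

    def profile(self, temperature: float, n_bins: int = 2001):
        """Exact free-energy profile: F(q) = U(q) up to an offset for
        overdamped/underdamped 1D dynamics."""
        from .equilibrium import FreeEnergyProfile

        lo, hi = self.potential.domain
        edges = np.linspace(lo, hi, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        F = self.potential.energy(centers)
        return FreeEnergyProfile(grid=centers, F=F - F.min(),
                                 temperature=temperature)


@dataclass
class ChainSystem:
    """Birth-death chain; the reaction coordinate is the state index."""

    energies: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)

    @property
    def discrete(self) -> bool:
        return True

    @property
    def has_velocities(self) -> bool:
        return False

    @property
    def n_states(self) -> int:
        return self.energies.size

    def chain(self, kBT: float) -> BirthDeathChain:
        key = float(kBT)
        if key not in self._cache:
            self._cache[key] = make_chain_from_profile(self.energies, key)
        return self._cache[key]

    def run(self, q0, n_steps, config: EngineConfig, seed,
            bias_spring=0.0, bias_center=0.0, v0=None):
        if bias_spring:
            return _kernels.run_chain_biased(
                self.energies, 1.0 / config.temperature, float(bias_spring),
                float(bias_center), int(round(q0)), int(n_steps),
                np.uint32(seed))
        ch = self.chain(config.temperature)
        return _kernels.run_chain(ch.p_left, ch.p_right, int(round(q0)),
                                  int(n_steps), np.uint32(seed))

    def shoot_half(self, q0, v0, plane_lo, plane_hi, config: EngineConfig,
                   max_steps, seed):
        ch = self.chain(config.temperature)
        code, states = _kernels.shoot_chain(
            ch.p_left, ch.p_right, int(round(q0)), int(round(plane_lo)),
            int(round(plane_hi)), int(max_steps), np.uint32(seed))
        return code, states, None

    def first_passage(self, q0, target, side, config: EngineConfig,
                      max_steps, seed) -> int:
        ch = self.chain(config.temperature)
        return int(_kernels.first_passage_chain(
            ch.p_left, ch.p_right, int(round(q0)), int(round(target)),
            int(max_steps), np.uint32(seed)))

    def restrained_seeds(self, lo, hi, n_seeds, config: EngineConfig, seed,
                         stride: int | None = None, burn: int = 1000,
                         step_sigma=None) -> np.ndarray:
        s_lo = int(np.ceil(lo))
        s_hi = int(np.floor(hi))
        s_lo = max(s_lo, 0)
        s_hi = min(s_hi, self.n_states - 1)
        if s_hi < s_lo:
            raise SeedingError("restraint interval contains no states")
        if stride is None:
            stride = max(4, (s_hi - s_lo + 1) ** 2)
        sub = self.energies[s_lo:s_hi + 1]
        s0 = s_lo + int(np.argmin(sub))
        return _kernels.restrained_chain(
            self.energies, 1.0 / config.temperature, s_lo, s_hi, s0,
            int(n_seeds), int(stride), int(burn), np.uint32(seed))

    def profile(self, temperature: float, n_bins=None):
        """Exact per-state profile: F_s = E_s up to an offset (unit-width
        bins at integer states)."""
        from .equilibrium import FreeEnergyProfile

        F = self.energies - self.energies.min()
        return FreeEnergyProfile(grid=np.arange(self.n_states, dtype=float),
                                 F=F, temperature=temperature)

    def stationary(self, kBT: float) -> np.ndarray:
        return stationary_distribution(self.chain(kBT))
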