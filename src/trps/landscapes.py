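"""Synthetic test systems and exact rate oracles.

Two families of systems are provided as ground truth for the rate
estimators:

* one-dimensional continuous potentials (:class:`Potential1D`) evolved by
  Langevin dynamics, and
* discrete birth--death chains (:class:`BirthDeathChain`) evolved by a
  nearest-neighbour Metropolis kernel.

Both admit exact or near-exact reference kinetics: the stationary
distribution is Boltzmann, and the mean first passage time (MFPT) between
basins is available in closed form (double quadrature for overdamped 1D
diffusion, a linear solve for the chain).  The reciprocal MFPT serves as
the reference rate ``k_ref`` for deep-barrier two-state systems, where
relaxation is single-exponential.

Units: ``kB = 1`` throughout; energies in units of the thermal/contact
energy scale, time in units of the integrator step ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid


class ParameterError(ValueError):
    """Invalid landscape/system parameters."""


class NumericalError(RuntimeError):
    """A quadrature or linear solve failed to converge."""


class ModelError(RuntimeError):
    """Structurally invalid model (e.g. unreachable target state)."""


@dataclass
class Potential1D:
    """A 1D potential on a closed interval with analytic gradient.

    Parameters
    ----------
    energy_fn : callable
        Potential energy U(x) (units of kBT at the reference temperature).
    gradient_fn : callable
        dU/dx, the negative of the force.
    domain : tuple of float
        Closed interval [x_lo, x_hi]; the dynamics reflect at the edges.
    params : dict
        Named scalar parameters (barrier height, well separation, ...).
    grad_coeffs : ndarray, optional
        Polynomial coefficients of dU/dx in increasing order; when present
        the fast compiled propagators are used.
    """

    energy_fn: Callable[[np.ndarray], np.ndarray]
    gradient_fn: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    params: dict = field(default_factory=dict)
    grad_coeffs: np.ndarray | None = None

    def energy(self, x):
        return self.energy_fn(np.asarray(x, dtype=float))

    def gradient(self, x):
        return self.gradient_fn(np.asarray(x, dtype=float))


@dataclass
class BirthDeathChain:
    """Nearest-neighbour Metropolis chain on energies E_s.

    The move kernel is discrete-time: propose s -> s±1 with probability 1/2
    each, accept with min(1, exp(-(E' - E)/kBT)); a move past either end is
    rejected (reflecting boundaries), and the stay-probability absorbs the
    remainder.  Detailed balance with pi_s ∝ exp(-E_s/kBT) holds by
    construction.
    """

    energies: np.ndarray
    kBT: float
    p_left: np.ndarray = field(init=False)
    p_right: np.ndarray = field(init=False)
    p_stay: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 3:
            raise ParameterError("a birth-death chain needs >= 3 states")
        if not np.all(np.isfinite(e)):
            raise ParameterError("state energies must be finite")
        if self.kBT <= 0:
            raise ParameterError("kBT must be positive")
        self.energies = e
        n = e.size
        self.p_left = np.zeros(n)
        self.p_right = np.zeros(n)
        beta = 1.0 / self.kBT
        self.p_right[:-1] = 0.5 * np.minimum(1.0, np.exp(-beta * (e[1:] - e[:-1])))
        self.p_left[1:] = 0.5 * np.minimum(1.0, np.exp(-beta * (e[:-1] - e[1:])))
        self.p_stay = 1.0 - self.p_left - self.p_right

    @property
    def n_states(self) -> int:
        return self.energies.size

    def transition_matrix(self) -> np.ndarray:
        n = self.n_states
        P = np.zeros((n, n))
        idx = np.arange(n)
        P[idx, idx] = self.p_stay
        P[idx[:-1], idx[:-1] + 1] = self.p_right[:-1]
        P[idx[1:], idx[1:] - 1] = self.p_left[1:]
        return P


def make_double_well(
    barrier: float,
    x_min_sep: float,
    tilt: float = 0.0,
    domain: tuple[float, float] | None = None,
) -> Potential1D:
    """Quartic double well U(x) = barrier·[(x/a)² − 1]² + tilt·x/(2a).

    ``a = x_min_sep / 2``; for ``tilt = 0`` the two minima at ±a sit at
    U = 0 and the barrier top at x = 0 has U = barrier.  A positive tilt
    lowers the left well relative to the right one.
    """
    if barrier <= 0:
        raise ParameterError("barrier must be positive")
    if x_min_sep <= 0:
        raise ParameterError("x_min_sep must be positive")
    a = x_min_sep / 2.0
    b = float(barrier)
    t = float(tilt)
    if domain is None:
        domain = (-2.5 * a, 2.5 * a)

    def energy(x):
        return b * ((x / a) ** 2 - 1.0) ** 2 + t * x / (2.0 * a)

    def gradient(x):
        return 4.0 * b * x * ((x / a) ** 2 - 1.0) / a**2 + t / (2.0 * a)

    # dU/dx = (4b/a^4) x^3 - (4b/a^2) x + t/(2a), lowest order first
    coeffs = np.array([t / (2.0 * a), -4.0 * b / a**2, 0.0, 4.0 * b / a**4])
    return Potential1D(
        energy_fn=energy,
        gradient_fn=gradient,
        domain=domain,
        params={"barrier": b, "x_min_sep": x_min_sep, "tilt": t, "a": a},
        grad_coeffs=coeffs,
    )


def make_harmonic(kappa: float, domain: tuple[float, float] = (-10.0, 10.0)) -> Potential1D:
    """Harmonic well U(x) = ½·kappa·x² (test/calibration system)."""
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    k = float(kappa)
    return Potential1D(
        energy_fn=lambda x: 0.5 * k * x**2,
        gradient_fn=lambda x: k * x,
        domain=domain,
        params={"kappa": k},
        grad_coeffs=np.array([0.0, k]),
    )


def make_chain_from_profile(energies: Sequence[float], kBT: float) -> BirthDeathChain:
    """Build the nearest-neighbour Metropolis chain for per-state energies."""
    return BirthDeathChain(energies=np.asarray(energies, dtype=float), kBT=kBT)


def discretize_potential(
    potential: Potential1D, n_states: int, kBT: float,
    lo: float | None = None, hi: float | None = None,
) -> tuple[BirthDeathChain, np.ndarray]:
    """Sample a continuous potential on a uniform grid as a chain.

    Returns the chain and the grid of state positions.
    """
    if lo is None:
        lo = potential.domain[0]
    if hi is None:
        hi = potential.domain[1]
    xs = np.linspace(lo, hi, n_states)
    return make_chain_from_profile(potential.energy(xs), kBT), xs


def stationary_distribution(chain: BirthDeathChain) -> np.ndarray:
    """Boltzmann stationary distribution pi_s ∝ exp(-E_s/kBT), normalised."""
    e = chain.energies
    w = np.exp(-(e - e.min()) / chain.kBT)
    return w / w.sum()


def mfpt_continuous(
    potential: Potential1D,
    diffusion: float,
    kBT: float,
    start: float,
    absorb: float,
    reflect: float,
    n_grid: int = 8193,
    rtol: float = 1e-6,
) -> float:
    """Mean first passage time for overdamped 1D diffusion.

    Closed form for a reflecting boundary at ``reflect`` and an absorbing
    one at ``absorb``:

        tau = (1/D) ∫_start^absorb dy e^{U(y)/kBT} ∫_reflect^y dx e^{-U(x)/kBT}

    evaluated on a dense grid with Richardson-style refinement; raises
    :class:`NumericalError` if doubling the grid still changes the result
    by more than ``rtol`` (relative).
    """
    if diffusion <= 0 or kBT <= 0:
        raise ParameterError("diffusion and kBT must be positive")
    flip = absorb < start
    if flip:
        # mirror the problem so reflect <= start < absorb
        pot = Potential1D(
            energy_fn=lambda x: potential.energy(-x),
            gradient_fn=lambda x: -potential.gradient(-x),
            domain=(-potential.domain[1], -potential.domain[0]),
        )
        return mfpt_continuous(pot, diffusion, kBT, -start, -absorb, -reflect,
                               n_grid=n_grid, rtol=rtol)
    if not (reflect <= start < absorb):
        raise ParameterError("need reflect <= start < absorb (or mirrored)")

    beta = 1.0 / kBT

    def _tau(n: int) -> float:
        x = np.linspace(reflect, absorb, n)
        u = potential.energy(x)
        offset = u.min()  # shared offset avoids overflow; cancels exactly
        inner = cumulative_trapezoid(np.exp(-beta * (u - offset)), x, initial=0.0)
        y = np.linspace(start, absorb, n)
        inner_y = np.interp(y, x, inner)
        integrand_y = np.exp(beta * (potential.energy(y) - offset)) * inner_y
        return float(np.trapezoid(integrand_y, y)) / diffusion

    t1 = _tau(n_grid)
    t2 = _tau(2 * n_grid - 1)
    if not np.isfinite(t2) or (abs(t2 - t1) > rtol * abs(t2) + 1e-300):
        t3 = _tau(4 * n_grid - 3)
        if not np.isfinite(t3) or abs(t3 - t2) > rtol * abs(t3) + 1e-300:
            raise NumericalError(
                f"MFPT quadrature did not converge: {t1!r}, {t2!r}, {t3!r}"
            )
        return t3
    return t2


def mfpt_chain(chain: BirthDeathChain, start: int, target: int) -> float:
    """Exact mean first passage time (in steps) by a linear solve.

    Solves (I - P_restricted) tau = 1 over the non-target states.
    """
    n = chain.n_states
    if not (0 <= start < n and 0 <= target < n):
        raise ParameterError("start/target out of range")
    if start == target:
        raise ParameterError("start must differ from target")
    P = chain.transition_matrix()
    keep = np.arange(n) != target
    A = np.eye(n - 1) - P[np.ix_(keep, keep)]
    try:
        tau = np.linalg.solve(A, np.ones(n - 1))
    except np.linalg.LinAlgError as err:
        raise ModelError(f"first-passage system is singular: {err}") from err
    if not np.all(np.isfinite(tau)):
        raise ModelError("first-passage system has no finite solution")
    return float(tau[int(np.searchsorted(np.flatnonzero(keep), start))])
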