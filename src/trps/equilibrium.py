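"""Equilibrium machinery: umbrella sampling, WHAM, population ratios.

The tRPS rate formula needs one equilibrium quantity, the population
ratio N_TS/N_A between a transition-state (TS) region of the reaction
coordinate and the source basin.  That ratio comes from a free-energy
profile F(q), reconstructed here from harmonically biased umbrella
windows by the weighted histogram analysis method (WHAM), or supplied in
closed form for the synthetic landscapes.

Conventions: kB = 1, F in units of kBT with min(F) = 0; the TS region
[TS-, TS+] is inclusive on both ends (so integer reaction coordinates
such as a native-contact count can use intervals like [50, 51]); basin A
for N_A extends over every grid point on the A side of the nearest TS
edge, since the Boltzmann weight makes the near-barrier bins negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import EngineConfig, kernel_seed
from .landscapes import ParameterError


class CoverageError(RuntimeError):
    """Adjacent umbrella windows do not overlap."""


class ConvergenceError(RuntimeError):
    """WHAM self-consistency iteration did not converge."""


class RegionError(ValueError):
    """An empty or uncovered reaction-coordinate region was requested."""


class TopologyError(RuntimeError):
    """A profile does not have the expected two-basin topology."""


@dataclass(frozen=True)
class TSRegion:
    """Inclusive interval [lower, upper] of the reaction coordinate that
    separates the two basins.  It need not be the true transition state;
    any dividing region that every transition path must cross works."""

    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ParameterError("TS region needs lower <= upper")

    def contains(self, q) -> np.ndarray:
        q = np.asarray(q)
        return (q >= self.lower) & (q <= self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint ½·spring·(q − center)² and the
    histogram of reaction-coordinate samples collected under it."""

    center: float
    spring: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ParameterError("histogram counts must be non-negative")

    @property
    def n_samples(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FreeEnergyProfile:
    """F over reaction-coordinate bin centers at one temperature, in kBT
    units, offset so the sampled minimum is 0; unsampled bins are +inf."""

    grid: np.ndarray
    F: np.ndarray
    temperature: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.grid.ndim != 1 or self.grid.size != self.F.size:
            raise ParameterError("grid and F must be 1D and equally sized")
        if np.any(np.diff(self.grid) <= 0):
            raise ParameterError("grid must be strictly increasing")
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - self.F[finite].min()

    def bin_widths(self) -> np.ndarray:
        g = self.grid
        if g.size == 1:
            return np.ones(1)
        w = np.empty_like(g)
        w[1:-1] = 0.5 * (g[2:] - g[:-2])
        w[0] = g[1] - g[0]
        w[-1] = g[-1] - g[-2]
        return w

    def boltzmann_weights(self) -> np.ndarray:
        w = np.zeros_like(self.F)
        finite = np.isfinite(self.F)
        w[finite] = np.exp(-self.F[finite] / self.temperature) \
            * self.bin_widths()[finite]
        return w

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temperature={self.temperature!r} offset=min0\n")
            fh.write("bin_center,F\n")
            for g, f in zip(self.grid, self.F):
                fh.write(f"{g!r},{f!r}\n")

    @classmethod
    def from_csv(cls, path) -> "FreeEnergyProfile":
        with open(path) as fh:
            header = fh.readline()
            temperature = float(header.split("temperature=")[1].split()[0])
            fh.readline()
            rows = [line.strip().split(",") for line in fh if line.strip()]
        grid = np.array([float(r[0]) for r in rows])
        F = np.array([float(r[1]) for r in rows])
        return cls(grid=grid, F=F, temperature=temperature)


def run_umbrella(system, centers, springs, steps_per_window: int,
                 config: EngineConfig, bin_edges: np.ndarray | None = None,
                 burn_fraction: float = 0.1, seed: int | None = None,
                 starts=None) -> list[UmbrellaWindow]:
    """Run one biased simulation per window and histogram the coordinate.

    Each window starts at its own center (or ``starts[i]``), discards the
    first ``burn_fraction`` of its samples, and bins the rest.  Raises
    :class:`CoverageError` when adjacent windows share no occupied bin.
    """
    centers = np.asarray(centers, dtype=float)
    springs = np.broadcast_to(np.asarray(springs, dtype=float), centers.shape)
    if seed is None:
        seed = config.seed
    if bin_edges is None:
        if system.discrete:
            bin_edges = np.arange(-0.5, system.n_states + 0.5)
        else:
            lo, hi = system.potential.domain
            bin_edges = np.linspace(lo, hi, 201)
    bin_edges = np.asarray(bin_edges, dtype=float)
    burn = int(burn_fraction * steps_per_window)
    windows = []
    for i, (c, k) in enumerate(zip(centers, springs)):
        q0 = c if starts is None else starts[i]
        if system.discrete:
            q0 = int(np.clip(round(q0), 0, system.n_states - 1))
        traj = system.run(q0, steps_per_window, config,
                          kernel_seed(seed, 101, i),
                          bias_spring=k, bias_center=c)
        counts, _ = np.histogram(traj[burn:], bins=bin_edges)
        windows.append(UmbrellaWindow(center=c, spring=k,
                                      bin_edges=bin_edges,
                                      counts=counts.astype(float)))
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((windows[a].counts > 0) & (windows[b].counts > 0)):
            raise CoverageError(
                f"no histogram overlap between windows centered at "
                f"{windows[a].center} and {windows[b].center}")
    return windows


def wham(windows: list[UmbrellaWindow], temperature: float,
         tol: float = 1e-7, max_iter: int = 100_000,
         bias_matrix: np.ndarray | None = None) -> FreeEnergyProfile:
    """Standard WHAM self-consistency iteration.

    Iterates the unbiased probability estimate

        P(q) = sum_i n_i(q) / sum_i N_i exp[-(b_i(q) - f_i)/kBT],
        f_i  = -kBT ln sum_q P(q) exp[-b_i(q)/kBT],

    until the largest change in the window free energies f_i is below
    ``tol`` (kBT units), then returns F = -kBT ln P shifted to min 0.
    """
    if not windows:
        raise ParameterError("wham needs at least one window")
    edges = windows[0].bin_edges
    for w in windows:
        if not np.array_equal(w.bin_edges, edges):
            raise ParameterError("all windows must share one binning")
    centers = windows[0].bin_centers
    counts = np.stack([w.counts for w in windows])          # (W, B)
    N = counts.sum(axis=1)                                  # (W,)
    if bias_matrix is None:
        bias = np.stack([0.5 * w.spring * (centers - w.center) ** 2
                         for w in windows])                 # (W, B)
    else:
        bias = np.asarray(bias_matrix, dtype=float)
        if bias.shape != (len(windows), centers.size):
            raise ParameterError("bias_matrix must be (n_windows, n_bins)")
    beta = 1.0 / temperature
    # subtract each window's minimal bias for numerical headroom
    expb = np.exp(-beta * (bias - bias.min(axis=1, keepdims=True)))
    scale = np.exp(-beta * bias.min(axis=1))
    total = counts.sum(axis=0)                              # (B,)
    f = np.zeros(len(windows))
    history = []
    for _ in range(max_iter):
        denom = (N * np.exp(beta * f) * scale)[:, None] * expb  # (W, B)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(total > 0, total / denom.sum(axis=0), 0.0)
        Z = (expb * scale[:, None] * P).sum(axis=1)
        f_new = -temperature * np.log(Z)
        f_new = f_new - f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        history.append(delta)
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations; "
            f"last residuals {history[-5:]}")
    denom = (N * np.exp(beta * f) * scale)[:, None] * expb
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(total > 0, total / denom.sum(axis=0), 0.0)
        F = np.where(P > 0, -temperature * np.log(np.where(P > 0, P, 1.0)),
                     np.inf)
    return FreeEnergyProfile(grid=centers, F=F, temperature=temperature)


def population_ratio(profile: FreeEnergyProfile, ts: TSRegion,
                     basin: tuple[float, float]) -> float:
    """N_TS/N_A: equilibrium population of the TS region over that of the
    basin interval (both inclusive), with bin-width weighting."""
    b_lo, b_hi = min(basin), max(basin)
    if not (b_hi < ts.lower or b_lo > ts.upper):
        raise RegionError("TS region and basin interval must be disjoint")
    w = profile.boltzmann_weights()
    in_ts = ts.contains(profile.grid)
    in_basin = (profile.grid >= b_lo) & (profile.grid <= b_hi)
    if not in_ts.any():
        raise RegionError("TS region covers no grid points")
    if not in_basin.any():
        raise RegionError("basin interval covers no grid points")
    num = w[in_ts].sum()
    den = w[in_basin].sum()
    if den == 0:
        raise RegionError("basin has zero equilibrium weight")
    return float(num / den)


def basin_interval(profile_grid, ts: TSRegion, side: str) -> tuple[float, float]:
    """Everything on one side of the TS region's nearest edge ('A' = below
    TS-, 'B' = above TS+)."""
    g = np.asarray(profile_grid)
    if side == "A":
        return float(g.min()), float(np.nextafter(ts.lower, -np.inf))
    if side == "B":
        return float(np.nextafter(ts.upper, np.inf)), float(g.max())
    raise ParameterError("side must be 'A' or 'B'")


@dataclass(frozen=True)
class Landmarks:
    qa: float
    qb: float
    q_top: float
    barrier_from_a: float
    barrier_from_b: float


def locate_landmarks(profile: FreeEnergyProfile,
                     smooth_window: int = 1) -> Landmarks:
    """Find the two basin minima and the interior barrier top.

    A short moving-average smoothing (``smooth_window`` bins) may be
    applied before extremum detection on noisy profiles.  Raises
    :class:`TopologyError` unless exactly two minima bracket one maximum.
    """
    F = profile.F.copy()
    finite = np.isfinite(F)
    g = profile.grid[finite]
    F = F[finite]
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        F = np.convolve(F, k, mode="same")
    minima = [i for i in range(1, F.size - 1)
              if F[i] < F[i - 1] and F[i] <= F[i + 1]]
    maxima = [i for i in range(1, F.size - 1)
              if F[i] > F[i - 1] and F[i] >= F[i + 1]]
    if len(minima) != 2:
        raise TopologyError(
            f"expected exactly two minima, found {len(minima)} at "
            f"{[g[i] for i in minima]} (maxima at {[g[i] for i in maxima]})")
    i_a, i_b = minima
    between = [i for i in maxima if i_a < i < i_b]
    if len(between) != 1:
        raise TopologyError(
            f"expected one interior maximum, found {len(between)} "
            f"at {[g[i] for i in between]}")
    i_top = between[0]
    return Landmarks(qa=float(g[i_a]), qb=float(g[i_b]), q_top=float(g[i_top]),
                     barrier_from_a=float(F[i_top] - F[i_a]),
                     barrier_from_b=float(F[i_top] - F[i_b]))


def basin_free_energy_difference(profile: FreeEnergyProfile,
                                 basin_a: tuple[float, float],
                                 basin_b: tuple[float, float]) -> float:
    """Delta F = F_B - F_A = -kBT ln (N_B/N_A) in kBT-of-profile units."""
    w = profile.boltzmann_weights()
    g = profile.grid
    in_a = (g >= min(basin_a)) & (g <= max(basin_a))
    in_b = (g >= min(basin_b)) & (g <= max(basin_b))
    if not in_a.any() or not in_b.any():
        raise RegionError("basin intervals must cover grid points")
    return float(-profile.temperature
                 * (np.log(w[in_b].sum()) - np.log(w[in_a].sum())))


class BracketError(ValueError):
    """The basin stability difference does not change sign on the bracket."""


def midpoint_temperature(system, t_lo: float, t_hi: float,
                         basin_a: tuple[float, float],
                         basin_b: tuple[float, float],
                         tol: float = 1e-3,
                         profile_fn=None) -> float:
    """Temperature at which the two basins are equally stable.

    Bisects Delta F(T) between ``basin_a`` and ``basin_b`` computed from
    ``profile_fn(T)`` (default: the system's exact profile) until
    |Delta F| < 0.05 kBT or the bracket is narrower than ``tol``.
    """
    if profile_fn is None:
        profile_fn = system.profile

    def df(T):
        return basin_free_energy_difference(profile_fn(T), basin_a, basin_b)

    d_lo, d_hi = df(t_lo), df(t_hi)
    if abs(d_lo) < 0.05:
        return t_lo
    if abs(d_hi) < 0.05:
        return t_hi
    if np.sign(d_lo) == np.sign(d_hi):
        raise BracketError(
            f"Delta F does not change sign on [{t_lo}, {t_hi}] "
            f"({d_lo:.3g} vs {d_hi:.3g})")
    while t_hi - t_lo > tol:
        t_mid = 0.5 * (t_lo + t_hi)
        d_mid = df(t_mid)
        if abs(d_mid) < 0.05:
            return t_mid
        if np.sign(d_mid) == np.sign(d_lo):
            t_lo, d_lo = t_mid, d_mid
        else:
            t_hi, d_hi = t_mid, d_mid
    return 0.5 * (t_lo + t_hi)
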