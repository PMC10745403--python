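"""Desk-scale benchmark workflows on the bundled synthetic systems.

Each function runs one end-to-end validation study at the conditions the
method is meant for (two-state landscapes with ~5 kBT barriers, ~4000
shoots per rate, direct trajectories long enough for hundreds of
transition events) and returns the computed quantities.  The test suite
asserts the statistical agreements; the reproduction script reports the
numbers.

Problem sizes: the 30-state chain and the 1D quartic well run in seconds
on one core, which is enough for the few-percent statistical resolution
these checks need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import EngineConfig, kernel_seed, simulate_overdamped
from .equilibrium import TSRegion, basin_interval, population_ratio, \
    run_umbrella, wham
from .estimator import reweighted_ts_histogram, shoot_ensemble, trps_rate
from .landscapes import make_double_well, mfpt_chain, mfpt_continuous
from .path_ensemble import CutPlanes, cut_trajectory, direct_rate
from .systems import ChainSystem, ContinuousSystem


def chain_double_well_system(barrier: float = 5.0, n_states: int = 30,
                             tilt: float = 0.0):
    """The bundled discrete benchmark: a quartic double well sampled on
    30 states (barrier ~5 kBT), with its planes and TS region."""
    pot = make_double_well(barrier, 2.0, tilt=tilt)
    xs = np.linspace(-1.5, 1.5, n_states)
    system = ChainSystem(pot.energy(xs))
    E = system.energies
    half = n_states // 2
    planes = CutPlanes(qa=int(np.argmin(E[:half])),
                       qb=half + int(np.argmin(E[half:])))
    top = int(np.argmax(E[int(planes.qa):int(planes.qb)]) + planes.qa)
    ts = TSRegion(top, top + 1)
    return system, planes, ts


def chain_rate_oracle(seed: int, n_shoots: int = 4000):
    """tRPS on the 30-state chain vs the exact linear-solve MFPT rate."""
    system, planes, ts = chain_double_well_system()
    cfg = EngineConfig(dt=1.0, temperature=1.0, seed=seed)
    prof = system.profile(1.0)
    ratio = population_ratio(prof, ts, basin_interval(prof.grid, ts, "A"))
    shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                            max_steps=500_000, seed=kernel_seed(seed, 1))
    est = trps_rate(shoots, ratio, 1.0, seed=kernel_seed(seed, 2))
    k_ref = 1.0 / mfpt_chain(system.chain(1.0), int(planes.qa),
                             int(planes.qb))
    return {"trps": est, "k_ref": k_ref, "shoots": shoots,
            "system": system, "planes": planes, "ts": ts}


def continuous_rate_oracle(seed: int, n_shoots: int = 4000,
                           traj_steps: int = 10_000_000):
    """tRPS vs direct-trajectory rate vs MFPT quadrature on the quartic
    double well (barrier 5 kBT, overdamped, dt = 1e-3)."""
    pot = make_double_well(5.0, 2.0)
    system = ContinuousSystem(pot)
    cfg = EngineConfig(dt=1e-3, temperature=1.0, friction=1.0, seed=seed)
    planes = CutPlanes(-1.0, 1.0)
    ts = TSRegion(-0.2, 0.2)
    prof = system.profile(1.0)
    ratio = population_ratio(prof, ts, basin_interval(prof.grid, ts, "A"))
    shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                            max_steps=1_000_000, seed=kernel_seed(seed, 3))
    est = trps_rate(shoots, ratio, cfg.dt, seed=kernel_seed(seed, 4))
    traj = simulate_overdamped(pot, -1.0, traj_steps, cfg,
                               seed=kernel_seed(seed, 5))
    paths = cut_trajectory(traj, planes, ts=ts)
    est_direct = direct_rate(paths, cfg.dt, planes=planes,
                             seed=kernel_seed(seed, 6))
    k_ref = 1.0 / mfpt_continuous(pot, cfg.diffusion, cfg.temperature,
                                  -1.0, 1.0, pot.domain[0])
    return {"trps": est, "direct": est_direct, "k_ref": k_ref,
            "shoots": shoots, "paths": paths, "system": system,
            "planes": planes, "ts": ts, "config": cfg}


def ts_placement_invariance(seed: int, n_shoots: int = 4000):
    """Rates from two disjoint TS regions (barrier top vs shifted toward
    basin B) on the continuous double well."""
    pot = make_double_well(5.0, 2.0)
    system = ContinuousSystem(pot)
    cfg = EngineConfig(dt=1e-3, temperature=1.0, friction=1.0, seed=seed)
    planes = CutPlanes(-1.0, 1.0)
    prof = system.profile(1.0)
    out = {}
    for j, ts in enumerate((TSRegion(-0.1, 0.1), TSRegion(0.35, 0.55))):
        ratio = population_ratio(prof, ts, basin_interval(prof.grid, ts, "A"))
        shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                                max_steps=1_000_000,
                                seed=kernel_seed(seed, 7, j))
        out[f"k_{j}"] = trps_rate(shoots, ratio, cfg.dt,
                                  seed=kernel_seed(seed, 8, j))
    return out


def reweighting_pvalue(seed: int, n_shoots: int = 4000) -> float:
    """Chi-square p-value of the 1/n_TS-weighted TS-occupancy histogram
    against the equilibrium law restricted to the TS region (discrete
    four-state TS region for exact bin probabilities)."""
    system, planes, _ = chain_double_well_system()
    ts = TSRegion(13, 16)
    cfg = EngineConfig(dt=1.0, temperature=1.0, seed=seed)
    shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                            max_steps=500_000, seed=kernel_seed(seed, 9))
    edges = np.arange(12.5, 17.0)
    hist, _ = reweighted_ts_histogram(shoots, edges)
    E = system.energies[13:17]
    p = np.exp(-E) / np.exp(-E).sum()
    n = hist.sum()
    chi2 = float(np.sum((hist - n * p) ** 2 / (n * p)))
    return float(1 - stats.chi2.cdf(chi2, p.size - 1))


def crossing_count_fit(seed: int, n_shoots: int = 4000):
    """Geometric/memoryless law for TS-crossing counts: linear fit of the
    log-survival function of per-path crossing numbers."""
    res = chain_rate_oracle(seed, n_shoots=n_shoots)
    counts = np.array([s.n_crossings for s in res["shoots"]
                       if s.is_transition])
    values = np.arange(1, counts.max() + 1)
    survival = np.array([(counts >= v).mean() for v in values])
    keep = survival * counts.size >= 10
    x, y = values[keep], np.log(survival[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
    return {"slope": float(slope), "r_squared": float(r2),
            "mean_crossings": float(counts.mean()), "n_paths": counts.size}


def detailed_balance_ratio(seed: int, n_shoots: int = 4000):
    """On a tilted double-well chain, k_AB/k_BA vs the equilibrium
    population ratio N_B/N_A (detailed-balance consistency)."""
    system, planes, ts = chain_double_well_system(tilt=0.8)
    cfg = EngineConfig(dt=1.0, temperature=1.0, seed=seed)
    prof = system.profile(1.0)
    basin_a = basin_interval(prof.grid, ts, "A")
    basin_b = basin_interval(prof.grid, ts, "B")
    ratio_a = population_ratio(prof, ts, basin_a)
    ratio_b = population_ratio(prof, ts, basin_b)
    shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                            max_steps=500_000, seed=kernel_seed(seed, 10))
    ab = trps_rate(shoots, ratio_a, 1.0, "A->B", seed=kernel_seed(seed, 11))
    ba = trps_rate(shoots, ratio_b, 1.0, "B->A", seed=kernel_seed(seed, 12))
    keq = ratio_a / ratio_b          # (N_TS/N_A)/(N_TS/N_B) = N_B/N_A
    rate_ratio = ab.k / ba.k
    rel_se = np.hypot(ab.stderr / ab.k, ba.stderr / ba.k)
    return {"k_ab": ab, "k_ba": ba, "rate_ratio": float(rate_ratio),
            "keq": float(keq), "rel_se": float(rel_se)}


@dataclass
class WhamFidelity:
    max_abs_error: float
    n_bins_checked: int


def wham_fidelity(seed: int, steps_per_window: int = 800_000) -> WhamFidelity:
    """Umbrella (BAOAB) + WHAM reconstruction error against the
    bin-integrated analytic profile.

    Well-sampled means >= 1000 samples in a bin: umbrella samples are
    autocorrelated over several steps, so 1000 raw counts corresponds to
    a free-energy noise floor of roughly 0.1 kBT."""
    pot = make_double_well(5.0, 2.0)
    system = ContinuousSystem(pot, engine="underdamped")
    cfg = EngineConfig(dt=5e-3, temperature=1.0, friction=1.0, seed=seed)
    centers = np.linspace(-1.6, 1.6, 17)
    edges = np.linspace(-1.8, 1.8, 121)
    windows = run_umbrella(system, centers, 40.0, steps_per_window, cfg,
                           bin_edges=edges, seed=kernel_seed(seed, 13))
    prof = wham(windows, temperature=1.0)
    fine = np.linspace(edges[0], edges[-1], 40 * (edges.size - 1) + 1)
    wgt = np.exp(-pot.energy(fine))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (wgt[1:] + wgt[:-1])
                                           * np.diff(fine))])
    p = np.diff(np.interp(edges, fine, cdf))
    F_ana = -np.log(p / p.max())
    total = np.sum([w.counts for w in windows], axis=0)
    mask = total >= 1000
    diff = prof.F[mask] - F_ana[mask]
    diff -= np.average(diff, weights=total[mask])
    return WhamFidelity(max_abs_error=float(np.max(np.abs(diff))),
                        n_bins_checked=int(mask.sum()))
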