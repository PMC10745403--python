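"""The time-reversal path sampling (tRPS) rate estimator.

Direct simulation of barrier crossing wastes almost all of its time
oscillating in the reactant basin.  tRPS sidesteps this by exploiting
microscopic reversibility: seed configurations are drawn from the
equilibrium distribution *restricted to a transition-state (TS) region*
between the basins, and from each seed a forward and a backward
trajectory are shot until they reach one of the two cutting planes at
the basin minima.  Reversing the backward half and concatenating it with
the forward half yields a full plane-to-plane path through the TS
region — the difficult uphill half (basin to TS) is replaced by the
statistically equivalent time-reverse of an easy downhill one.

A path containing n_TS frames inside the TS region could have been
generated from any of those frames, so each assembled path is weighted
by 1/n_TS to undo the multiplicity.  Writing t_TS = n_TS * dt, the
transition rate is

    k(A->B) = (N_TS / N_A) * (1/M) * sum_{i in S} H_AB(P_i) / t_TS(P_i),

where S is the set of M uncensored assembled paths, H_AB selects those
running from plane A to plane B, and N_TS/N_A is the equilibrium
population ratio between the TS region and the source basin (from the
free-energy profile).  Both directions come from the same shoot
ensemble, each with its own population ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import EngineConfig, draw_velocities, kernel_seed
from .equilibrium import TSRegion, basin_interval, population_ratio
from .landscapes import ParameterError
from .path_ensemble import CutPlanes, RateEstimate


class EstimatorError(RuntimeError):
    """The shoot ensemble cannot support a rate estimate."""


@dataclass
class ShootingPath:
    """A forward+reversed-backward path assembled from one TS-region seed.

    The seed frame is stored once; ``q`` holds the full assembled
    reaction-coordinate sequence when frames are kept, while
    ``ts_frames_q`` always retains the coordinates of the n_TS frames
    inside the TS region (needed for the reweighting diagnostics).
    """

    start_label: str                    # plane hit by the (reversed) backward half
    end_label: str                      # plane hit by the forward half
    n_ts: int
    t_ts: float                         # n_ts * dt
    duration_steps: int
    q_min: float
    q_max: float
    n_crossings: int
    seed_frame_index: int
    censored: bool = False
    ts_frames_q: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    start_q: float = np.nan             # terminal frame values, for extensions
    end_q: float = np.nan

    @property
    def weight(self) -> float:
        return 1.0 / self.n_ts

    @property
    def type(self) -> str:
        return f"{self.start_label}-{self.end_label}"

    @property
    def is_transition(self) -> bool:
        return self.start_label != self.end_label and not self.censored


def count_nts(path_q, ts: TSRegion) -> int:
    """Number of frames with reaction coordinate in [TS-, TS+] inclusive."""
    q = path_q.q if hasattr(path_q, "q") else np.asarray(path_q)
    return int(np.count_nonzero(ts.contains(q)))


def count_ts_crossings(path_q, ts: TSRegion) -> int:
    """Number of maximal contiguous runs of frames inside the TS region."""
    q = path_q.q if hasattr(path_q, "q") else np.asarray(path_q)
    inside = ts.contains(q).astype(np.int8)
    if inside.size == 0:
        return 0
    starts = int(inside[0]) + int(np.count_nonzero(np.diff(inside) == 1))
    return starts


def sample_ts_seeds(system, ts: TSRegion, n_seeds: int, config: EngineConfig,
                    seed: int | None = None, stride: int | None = None,
                    burn: int | None = None) -> np.ndarray:
    """Equilibrium-restricted seed configurations inside [TS-, TS+].

    A Metropolis sampler confined to the region (proposed exits rejected
    outright) leaves the restricted Boltzmann distribution exactly
    invariant; samples are taken every ``stride`` sweeps.  Velocities are
    *not* sampled here — they are drawn fresh from Maxwell-Boltzmann at
    shoot time, which is exact because momenta are independent of
    configurations at equilibrium.
    """
    if n_seeds < 1:
        raise ParameterError("n_seeds must be >= 1")
    if seed is None:
        seed = config.seed
    kwargs = {}
    if stride is not None:
        kwargs["stride"] = stride
    if burn is not None:
        kwargs["burn"] = burn
    return system.restrained_seeds(ts.lower, ts.upper, n_seeds, config,
                                   kernel_seed(seed, 307), **kwargs)


def shoot(seed_q, system, planes: CutPlanes, ts: TSRegion,
          config: EngineConfig, max_steps: int, seed: int,
          keep_frames: bool = False) -> ShootingPath:
    """One forward/backward shot from a TS-region seed, assembled.

    Underdamped engines draw one Maxwell-Boltzmann velocity and use +v
    for the forward half and -v for the backward one; velocity-free
    engines run two independent relaxations from the seed (the backward
    one standing in for the time-reverse of an incoming path, which is
    statistically equivalent at equilibrium).  The two halves always use
    independent noise streams.
    """
    if not bool(ts.contains(seed_q)):
        raise ParameterError(f"seed q={seed_q} lies outside the TS region")
    v0 = 0.0
    if system.has_velocities:
        rng = np.random.default_rng(kernel_seed(seed, 1))
        v0 = float(draw_velocities(config.temperature, config.mass, rng, 1)[0])
    code_f, q_fwd, _ = system.shoot_half(seed_q, v0, planes.lo, planes.hi,
                                         config, max_steps,
                                         kernel_seed(seed, 2))
    code_b, q_bwd, _ = system.shoot_half(seed_q, -v0, planes.lo, planes.hi,
                                         config, max_steps,
                                         kernel_seed(seed, 3))
    censored = (code_f == _kernels.CENSORED) or (code_b == _kernels.CENSORED)
    # assembled path: reversed backward half + seed + forward half,
    # with the shared seed frame kept once (q_bwd[0] == q_fwd[0] == seed)
    q = np.concatenate([q_bwd[::-1][:-1], q_fwd])
    seed_index = q_bwd.size - 1
    in_ts = ts.contains(q)
    n_ts = int(np.count_nonzero(in_ts))
    labels = {_kernels.HIT_LO: planes.label_of(planes.lo),
              _kernels.HIT_HI: planes.label_of(planes.hi),
              _kernels.CENSORED: "?"}
    return ShootingPath(
        start_label=labels[code_b],
        end_label=labels[code_f],
        n_ts=max(n_ts, 1),
        t_ts=max(n_ts, 1) * config.dt,
        duration_steps=q.size - 1,
        q_min=float(q.min()),
        q_max=float(q.max()),
        n_crossings=count_ts_crossings(q, ts),
        seed_frame_index=seed_index,
        censored=censored,
        ts_frames_q=np.asarray(q[in_ts], dtype=float),
        q=q if keep_frames else None,
        start_q=float(q[0]),
        end_q=float(q[-1]),
    )


def shoot_ensemble(system, ts: TSRegion, planes: CutPlanes, n_shoots: int,
                   config: EngineConfig, max_steps: int = 1_000_000,
                   seed: int | None = None, keep_frames: bool = False,
                   ) -> list[ShootingPath]:
    """Draw ``n_shoots`` restricted-equilibrium seeds and shoot from each."""
    if seed is None:
        seed = config.seed
    seeds = sample_ts_seeds(system, ts, n_shoots, config, seed=seed)
    return [shoot(seeds[i], system, planes, ts, config, max_steps,
                  kernel_seed(seed, 401, i), keep_frames=keep_frames)
            for i in range(n_shoots)]


def trps_rate(shoots: Sequence[ShootingPath], nts_na: float, dt: float,
              direction: str = "A->B", n_boot: int = 1000,
              seed: int = 0) -> RateEstimate:
    """The tRPS rate: k = nts_na * (1/M) * sum_i H_dir(P_i)/t_TS(P_i).

    ``nts_na`` must be the population ratio N_TS/N_source for the source
    basin of ``direction``.  Censored shoots are excluded from M and
    reported.  stderr is a bootstrap (``n_boot`` resamples) over shoots.
    """
    src, dst = direction.split("->")
    wanted = f"{src}-{dst}"
    live = [s for s in shoots if not s.censored]
    M = len(live)
    if M == 0:
        raise EstimatorError("no uncensored shoots")
    contrib = np.array([(1.0 / s.t_ts) if s.type == wanted else 0.0
                        for s in live])
    n_events = int(np.count_nonzero(contrib))
    k = float(nts_na * contrib.mean())
    if n_events == 0:
        return RateEstimate(k=0.0, stderr=0.0, n_events=0, n_paths=M,
                            method="trps", low_statistics=True,
                            metadata={"direction": direction, "dt": dt,
                                      "nts_na": nts_na,
                                      "n_censored": len(shoots) - M})
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, M, size=(n_boot, M))
    boot = nts_na * contrib[idx].mean(axis=1)
    stderr = float(np.std(boot, ddof=1))
    trans = [s for s in live if s.type == wanted]
    return RateEstimate(
        k=k, stderr=stderr, n_events=n_events, n_paths=M, method="trps",
        metadata={
            "direction": direction, "dt": dt, "nts_na": float(nts_na),
            "n_censored": len(shoots) - M,
            "transition_fraction": n_events / M,
            "mean_t_ts": float(np.mean([s.t_ts for s in trans])),
            "mean_t_tpath": float(np.mean([s.duration_steps for s in trans]) * dt),
        })


def reweighted_ts_histogram(shoots: Sequence[ShootingPath],
                            bin_edges: np.ndarray,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """TS-occupancy histogram over assembled paths, each frame carrying
    its path's 1/n_TS weight.

    At equilibrium this reproduces the Boltzmann distribution restricted
    to the TS region: a shoot generates a path with probability
    proportional to n_TS times its dynamical weight (any of its TS frames
    could have been the seed), and 1/n_TS undoes exactly that
    multiplicity.
    """
    vals = []
    weights = []
    for s in shoots:
        if s.censored or s.ts_frames_q is None:
            continue
        vals.append(s.ts_frames_q)
        weights.append(np.full(s.ts_frames_q.size, 1.0 / s.n_ts))
    if not vals:
        raise EstimatorError("no uncensored shoots with TS frames")
    hist, edges = np.histogram(np.concatenate(vals), bins=bin_edges,
                               weights=np.concatenate(weights))
    return hist, edges


def preequilibrium_check(shoots: Sequence[ShootingPath], system,
                         extension_steps: int, config: EngineConfig,
                         planes: CutPlanes, seed: int | None = None) -> float:
    """Fraction of shoot endpoints that re-cross the barrier when extended.

    Each terminal frame (which sits at a cutting plane) is continued for
    ``extension_steps``; an endpoint counts as a re-crossing when the
    continuation reaches the *opposite* plane.  A fraction <= 0.05 means
    the pre-equilibrium assumption behind plane-to-plane path counting is
    safe at this barrier height.
    """
    if seed is None:
        seed = config.seed
    if extension_steps == 0:
        return 0.0
    n_ext = 0
    n_recross = 0
    for i, s in enumerate(shoots):
        if s.censored:
            continue
        for j, (q_end, label) in enumerate(((s.start_q, s.start_label),
                                            (s.end_q, s.end_label))):
            opposite = planes.qb if label == "A" else planes.qa
            side = 1 if opposite > q_end else -1
            steps = system.first_passage(q_end, opposite, side, config,
                                         extension_steps,
                                         kernel_seed(seed, 503, i, j))
            n_ext += 1
            if steps >= 0:
                n_recross += 1
    if n_ext == 0:
        raise EstimatorError("no uncensored shoots to extend")
    return n_recross / n_ext


def chevron_scan(system, temperatures: Sequence[float], ts: TSRegion,
                 planes: CutPlanes, config: EngineConfig, n_shoots: int,
                 max_steps: int = 1_000_000, seed: int | None = None,
                 profile_fn=None) -> pd.DataFrame:
    """Rates in both directions across temperatures (chevron table).

    For each temperature the equilibrium profile gives N_TS/N_A and
    N_TS/N_B, one shoot ensemble gives both directed rates, and the
    transition-path statistics are summarised alongside.
    ``profile_fn(T)`` defaults to the system's exact profile; pass a
    WHAM-based closure to use reconstructed profiles instead.
    """
    if seed is None:
        seed = config.seed
    if profile_fn is None:
        profile_fn = system.profile
    rows = []
    for j, T in enumerate(temperatures):
        cfg = config.with_temperature(T)
        prof = profile_fn(T)
        ratio_a = population_ratio(prof, ts, basin_interval(prof.grid, ts, "A"))
        ratio_b = population_ratio(prof, ts, basin_interval(prof.grid, ts, "B"))
        shoots = shoot_ensemble(system, ts, planes, n_shoots, cfg,
                                max_steps=max_steps,
                                seed=kernel_seed(seed, 601, j))
        ab = trps_rate(shoots, ratio_a, cfg.dt, "A->B",
                       seed=kernel_seed(seed, 602, j))
        ba = trps_rate(shoots, ratio_b, cfg.dt, "B->A",
                       seed=kernel_seed(seed, 603, j))
        trans = [s for s in shoots if s.is_transition]
        rows.append({
            "temperature": T,
            "k_AB": ab.k, "stderr_AB": ab.stderr, "n_AB": ab.n_events,
            "k_BA": ba.k, "stderr_BA": ba.stderr, "n_BA": ba.n_events,
            "nts_na": ratio_a, "nts_nb": ratio_b,
            "n_shoots": len(shoots),
            "n_censored": sum(s.censored for s in shoots),
            "mean_t_tpath": (np.mean([s.duration_steps for s in trans]) * cfg.dt
                             if trans else np.nan),
            "mean_t_ts": (np.mean([s.t_ts for s in trans])
                          if trans else np.nan),
            "mean_crossings": (np.mean([s.n_crossings for s in trans])
                               if trans else np.nan),
        })
    return pd.DataFrame(rows)


def shoots_to_frame(shoots: Sequence[ShootingPath]) -> pd.DataFrame:
    """Flat per-shoot record table for CSV export and reanalysis."""
    return pd.DataFrame({
        "type": [s.type for s in shoots],
        "censored": [s.censored for s in shoots],
        "n_ts": [s.n_ts for s in shoots],
        "t_ts": [s.t_ts for s in shoots],
        "duration_steps": [s.duration_steps for s in shoots],
        "n_crossings": [s.n_crossings for s in shoots],
        "q_min": [s.q_min for s in shoots],
        "q_max": [s.q_max for s in shoots],
    })
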