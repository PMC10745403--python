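"""The tRPS estimator: seeding, shooting, reweighting, rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trps import (ChainSystem, ContinuousSystem, CutPlanes, EngineConfig,
                  TSRegion, count_nts, count_ts_crossings, make_double_well,
                  mfpt_chain, population_ratio, preequilibrium_check,
                  reweighted_ts_histogram, sample_ts_seeds, shoot,
                  shoot_ensemble, trps_rate)
from trps.equilibrium import basin_interval
from trps.estimator import EstimatorError, ShootingPath, shoots_to_frame
from trps.landscapes import ParameterError


class TestCountNts:
    def test_inclusive_membership(self):
        q = np.array([48, 50, 51, 50, 52], dtype=float)
        assert count_nts(q, TSRegion(50, 51)) == 3

    def test_seed_only(self):
        q = np.array([40, 50.5, 60], dtype=float)
        assert count_nts(q, TSRegion(50, 51)) == 1

    @given(st.lists(st.integers(40, 60), min_size=1, max_size=1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_scan(self, seq):
        q = np.array(seq, dtype=float)
        ts = TSRegion(50, 51)
        assert count_nts(q, ts) == sum(1 for v in seq if 50 <= v <= 51)


class TestCountTsCrossings:
    def test_two_visits(self):
        q = np.array([49, 50, 52, 51, 50, 49], dtype=float)
        assert count_ts_crossings(q, TSRegion(50, 51)) == 2

    def test_single_stay(self):
        q = np.array([49, 50, 50.5, 51, 52], dtype=float)
        assert count_ts_crossings(q, TSRegion(50, 51)) == 1

    @given(st.lists(st.integers(48, 53), min_size=1, max_size=500))
    @settings(max_examples=30, deadline=None)
    def test_matches_run_length_scan(self, seq):
        ts = TSRegion(50, 51)
        q = np.array(seq, dtype=float)
        inside = [50 <= v <= 51 for v in seq]
        runs = sum(1 for i, b in enumerate(inside)
                   if b and (i == 0 or not inside[i - 1]))
        assert count_ts_crossings(q, ts) == runs


class TestSampleTsSeeds:
    def test_single_state_region_all_identical(self, chain30, chain_config):
        seeds = sample_ts_seeds(chain30, TSRegion(14, 14), 50, chain_config,
                                seed=1)
        assert np.all(seeds == 14)

    def test_two_state_boltzmann_ratio(self, chain_config):
        """Two states differing by ln 2 kBT populate 2:1."""
        system = ChainSystem(np.array([0.0, np.log(2.0), 5.0]))
        seeds = sample_ts_seeds(system, TSRegion(0, 1), 10_000, chain_config,
                                seed=3)
        frac = np.mean(seeds == 0)
        p = 2.0 / 3.0
        se = np.sqrt(p * (1 - p) / seeds.size)
        assert abs(frac - p) < 3 * se

    def test_continuous_restricted_boltzmann(self, dw_system, dw_config,
                                             dw_ts):
        seeds = sample_ts_seeds(dw_system, dw_ts, 8000, dw_config, seed=5)
        assert np.all((seeds >= dw_ts.lower) & (seeds <= dw_ts.upper))
        edges = np.linspace(dw_ts.lower, dw_ts.upper, 9)
        counts, _ = np.histogram(seeds, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = np.exp(-dw_system.potential.energy(centers))
        p = w / w.sum()
        chi2 = np.sum((counts - seeds.size * p) ** 2 / (seeds.size * p))
        assert 1 - stats.chi2.cdf(chi2, len(p) - 1) > 0.01


class TestShoot:
    def test_assembly_arithmetic(self, dw_system, dw_config, dw_ts,
                                 dw_planes):
        sp = shoot(0.0, dw_system, dw_planes, dw_ts, dw_config,
                   max_steps=100_000, seed=7, keep_frames=True)
        assert sp.q is not None
        assert sp.duration_steps == sp.q.size - 1
        assert sp.n_ts == count_nts(sp.q, dw_ts)
        assert sp.t_ts == sp.n_ts * dw_config.dt
        # terminal frames on/beyond the planes
        assert sp.q[0] <= dw_planes.lo or sp.q[0] >= dw_planes.hi
        assert sp.q[-1] <= dw_planes.lo or sp.q[-1] >= dw_planes.hi
        # seed frame kept once, in the TS region
        assert dw_ts.contains(sp.q[sp.seed_frame_index])

    def test_seed_outside_region_rejected(self, dw_system, dw_config, dw_ts,
                                          dw_planes):
        with pytest.raises(ParameterError):
            shoot(0.9, dw_system, dw_planes, dw_ts, dw_config, 1000, seed=0)

    def test_ballistic_limit_connects_planes(self):
        """Underdamped, frictionless, near-zero temperature, seeded at
        the barrier top: the +v and -v halves roll down opposite slopes,
        so the assembled path connects the two planes."""
        pot = make_double_well(5.0, 2.0)
        system = ContinuousSystem(pot, engine="underdamped")
        cfg = EngineConfig(dt=1e-3, temperature=1e-18, friction=0.0)
        sp = shoot(0.0, system, CutPlanes(-1.0, 1.0), TSRegion(-0.2, 0.2),
                   cfg, max_steps=200_000, seed=9)
        assert not sp.censored
        assert {sp.start_label, sp.end_label} == {"A", "B"}

    def test_ballistic_downhill_side_by_seed(self):
        """Off-top seeds with negligible kinetic energy relax to the
        downhill plane on their side for both halves."""
        pot = make_double_well(5.0, 2.0)
        system = ContinuousSystem(pot, engine="underdamped")
        cfg = EngineConfig(dt=1e-3, temperature=1e-18, friction=0.0)
        sp = shoot(0.15, system, CutPlanes(-1.0, 1.0), TSRegion(-0.2, 0.2),
                   cfg, max_steps=200_000, seed=9)
        assert sp.type == "B-B"

    def test_symmetric_well_direction_balance(self, dw_system, dw_config,
                                              dw_ts, dw_planes):
        shoots = shoot_ensemble(dw_system, dw_ts, dw_planes, 2000, dw_config,
                                seed=11)
        n_ab = sum(s.type == "A-B" for s in shoots)
        n_ba = sum(s.type == "B-A" for s in shoots)
        n = n_ab + n_ba
        se = np.sqrt(0.25 * n)
        assert abs(n_ab - n_ba) < 3 * 2 * se

    def test_underdamped_velocity_reversal_used(self):
        """With friction 0 and tiny temperature the backward half is the
        deterministic mirror: assembled path is monotone across the well."""
        pot = make_double_well(3.0, 2.0, tilt=0.0)
        system = ContinuousSystem(pot, engine="underdamped")
        cfg = EngineConfig(dt=1e-3, temperature=1e-18, friction=0.0)
        sp = shoot(0.0, system, CutPlanes(-1.0, 1.0), TSRegion(-0.1, 0.1),
                   cfg, max_steps=200_000, seed=13, keep_frames=True)
        # the seed sits at the barrier top with some velocity; the halves
        # depart in opposite directions
        assert sp.start_label != sp.end_label


class TestTrpsRate:
    def test_rate_arithmetic(self):
        """Worked example: 10 shoots, two A-B with t_TS = 4 and 8,
        ratio 0.02 -> k = 0.02*(1/10)*(1/4+1/8) = 7.5e-4."""
        shoots = []
        for t_ts in (4, 8):
            shoots.append(ShootingPath(
                start_label="A", end_label="B", n_ts=t_ts, t_ts=float(t_ts),
                duration_steps=100, q_min=-1, q_max=1, n_crossings=1,
                seed_frame_index=50))
        for _ in range(8):
            shoots.append(ShootingPath(
                start_label="A", end_label="A", n_ts=2, t_ts=2.0,
                duration_steps=50, q_min=-1, q_max=0.5, n_crossings=1,
                seed_frame_index=25))
        est = trps_rate(shoots, nts_na=0.02, dt=1.0)
        assert est.k == pytest.approx(7.5e-4, rel=1e-12)
        assert est.n_events == 2 and est.n_paths == 10

    def test_no_transitions_gives_zero(self):
        shoots = [ShootingPath(start_label="A", end_label="A", n_ts=3,
                               t_ts=3.0, duration_steps=10, q_min=-1,
                               q_max=0, n_crossings=1, seed_frame_index=5)]
        est = trps_rate(shoots, 0.05, 1.0)
        assert est.k == 0.0 and est.low_statistics

    def test_all_censored_raises(self):
        shoots = [ShootingPath(start_label="?", end_label="?", n_ts=1,
                               t_ts=1.0, duration_steps=10, q_min=0, q_max=0,
                               n_crossings=1, seed_frame_index=0,
                               censored=True)]
        with pytest.raises(EstimatorError):
            trps_rate(shoots, 0.05, 1.0)

    def test_chain_oracle_agreement(self, chain30, chain30_planes,
                                    chain30_ts, chain_config):
        """tRPS vs the exact linear-solve MFPT on the 30-state chain."""
        prof = chain30.profile(1.0)
        ratio = population_ratio(prof, chain30_ts,
                                 basin_interval(prof.grid, chain30_ts, "A"))
        shoots = shoot_ensemble(chain30, chain30_ts, chain30_planes, 2000,
                                chain_config, max_steps=500_000, seed=17)
        est = trps_rate(shoots, ratio, 1.0)
        k_ref = 1.0 / mfpt_chain(chain30.chain(1.0), int(chain30_planes.qa),
                                 int(chain30_planes.qb))
        assert abs(est.k - k_ref) < 3 * est.stderr + 0.05 * k_ref


class TestReweighting:
    def test_weighted_histogram_matches_restricted_equilibrium(
            self, chain30, chain30_planes, chain_config):
        """The operational content of the 1/n_TS rule: the weighted
        TS-occupancy histogram equals the restricted Boltzmann law."""
        ts = TSRegion(13, 16)
        shoots = shoot_ensemble(chain30, ts, chain30_planes, 3000,
                                chain_config, max_steps=500_000, seed=19)
        edges = np.arange(12.5, 17.0)
        hist, _ = reweighted_ts_histogram(shoots, edges)
        E = chain30.energies[13:17]
        p = np.exp(-E) / np.exp(-E).sum()
        n = hist.sum()
        chi2 = np.sum((hist - n * p) ** 2 / (n * p))
        assert 1 - stats.chi2.cdf(chi2, len(p) - 1) > 0.01


class TestPreequilibriumCheck:
    def test_zero_extension_is_zero(self, chain30, chain30_planes,
                                    chain30_ts, chain_config):
        shoots = shoot_ensemble(chain30, chain30_ts, chain30_planes, 50,
                                chain_config, seed=23)
        frac = preequilibrium_check(shoots, chain30, 0, chain_config,
                                    chain30_planes)
        assert frac == 0.0

    def test_deep_wells_rarely_recross(self, chain_config):
        """8 kBT barrier: short extensions almost never re-cross."""
        pot = make_double_well(8.0, 2.0)
        system = ChainSystem(pot.energy(np.linspace(-1.5, 1.5, 30)))
        E = system.energies
        planes = CutPlanes(int(np.argmin(E[:15])), 15 + int(np.argmin(E[15:])))
        shoots = shoot_ensemble(system, TSRegion(14, 15), planes, 200,
                                chain_config, max_steps=500_000, seed=29)
        frac = preequilibrium_check(shoots, system, 2000, chain_config,
                                    planes)
        assert frac < 0.05

    def test_vanishing_barrier_recrosses_often(self, chain_config):
        """Near-flat landscape: extensions frequently wander across."""
        system = ChainSystem(np.full(30, 0.0) + 0.05)
        planes = CutPlanes(5, 24)
        shoots = shoot_ensemble(system, TSRegion(14, 15), planes, 100,
                                chain_config, max_steps=500_000, seed=31)
        frac = preequilibrium_check(shoots, system, 5000, chain_config,
                                    planes)
        assert frac > 0.2


def test_shoot_records_roundtrip(chain30, chain30_planes, chain30_ts,
                                 chain_config):
    shoots = shoot_ensemble(chain30, chain30_ts, chain30_planes, 20,
                            chain_config, seed=37)
    frame = shoots_to_frame(shoots)
    assert len(frame) == 20
    assert set(frame["type"]).issubset({"A-A", "A-B", "B-A", "B-B"})
    assert (frame["t_ts"] == frame["n_ts"] * chain_config.dt).all()
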