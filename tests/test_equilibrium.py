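"""Umbrella sampling, WHAM reconstruction, population ratios, landmarks."""

import numpy as np
import pytest
from scipy import stats

from trps import (ChainSystem, ContinuousSystem, EngineConfig,
                  FreeEnergyProfile, TSRegion, locate_landmarks,
                  make_double_well, make_harmonic, midpoint_temperature,
                  population_ratio, run_umbrella, wham)
from trps.equilibrium import (BracketError, CoverageError, Landmarks,
                              RegionError, TopologyError, UmbrellaWindow,
                              basin_interval)


def _analytic_bin_profile(pot, edges, kBT=1.0):
    """Bin-integrated Boltzmann reference (the correct oracle where F
    varies within a bin)."""
    fine = np.linspace(edges[0], edges[-1], 40 * (len(edges) - 1) + 1)
    w = np.exp(-pot.energy(fine) / kBT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(fine))])
    p = np.diff(np.interp(edges, fine, cdf))
    return -kBT * np.log(p / p.max())


@pytest.fixture(scope="module")
def baoab_windows(double_well):
    """The bundled umbrella protocol: BAOAB-sampled harmonic windows
    spanning both basins of the 5 kBT double well."""
    system = ContinuousSystem(double_well, engine="underdamped")
    cfg = EngineConfig(dt=5e-3, temperature=1.0, friction=1.0)
    centers = np.linspace(-1.6, 1.6, 17)
    edges = np.linspace(-1.8, 1.8, 121)
    return run_umbrella(system, centers, 40.0, 400_000, cfg,
                        bin_edges=edges, seed=9), edges


class TestRunUmbrella:
    def test_zero_spring_matches_unbiased_sampling(self):
        """A spring-0 'window' is plain equilibrium sampling: its
        histogram agrees with a direct unbiased run."""
        pot = make_double_well(2.0, 2.0)
        system = ContinuousSystem(pot, engine="underdamped")
        cfg = EngineConfig(dt=5e-3, temperature=1.0, friction=1.0)
        edges = np.linspace(-2.0, 2.0, 9)
        wins = run_umbrella(system, [0.0], [0.0], 400_000, cfg,
                            bin_edges=edges, seed=3, starts=[-1.0])
        counts = wins[0].counts
        ana = _analytic_bin_profile(pot, edges)
        p = np.exp(-ana) / np.exp(-ana).sum()
        sub = counts / counts.sum()
        # decorrelation-aware: effective sample count ~ steps / mixing time
        n_eff = 400
        chi2 = np.sum((sub - p) ** 2 / p) * n_eff
        assert 1 - stats.chi2.cdf(chi2, len(p) - 1) > 0.01

    def test_biased_harmonic_mean_closed_form(self):
        """Harmonic U + harmonic bias is Gaussian with mean
        k c / (kappa + k)."""
        kappa, k, c = 4.0, 10.0, 0.8
        system = ContinuousSystem(make_harmonic(kappa), engine="underdamped")
        cfg = EngineConfig(dt=5e-3, temperature=1.0, friction=1.0)
        wins = run_umbrella(system, [c], [k], 400_000, cfg,
                            bin_edges=np.linspace(-2, 2, 401), seed=5)
        w = wins[0]
        mean = np.average(w.bin_centers, weights=w.counts)
        var = 1.0 / (kappa + k)
        n_eff = w.n_samples * cfg.dt * min(cfg.friction, kappa + k) / 2
        se = np.sqrt(var / n_eff)
        assert abs(mean - k * c / (kappa + k)) < 3 * se

    def test_bundled_protocol_overlaps(self, baoab_windows):
        wins, _ = baoab_windows
        order = np.argsort([w.center for w in wins])
        for a, b in zip(order[:-1], order[1:]):
            assert np.any((wins[a].counts > 0) & (wins[b].counts > 0))

    def test_gap_raises_coverage_error(self, double_well):
        system = ContinuousSystem(double_well, engine="underdamped")
        cfg = EngineConfig(dt=5e-3, temperature=1.0, friction=1.0)
        with pytest.raises(CoverageError):
            run_umbrella(system, [-1.5, 1.5], 400.0, 20_000, cfg,
                         bin_edges=np.linspace(-1.8, 1.8, 361), seed=7)


class TestWham:
    def test_single_unbiased_window_degenerate_case(self):
        """With one spring-0 window WHAM reduces to -kBT ln(histogram)."""
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 5000, size=30).astype(float)
        edges = np.linspace(0, 1, 31)
        win = UmbrellaWindow(center=0.5, spring=0.0, bin_edges=edges,
                             counts=counts)
        prof = wham([win], temperature=0.8)
        expect = -0.8 * np.log(counts)
        expect -= expect.min()
        assert np.max(np.abs(prof.F - expect)) < 1e-10

    def test_double_well_reconstruction(self, double_well, baoab_windows):
        """Full protocol recovers the analytic profile to < 0.2 kBT over
        well-sampled bins (>= 1000 correlated samples, i.e. a noise
        floor of roughly 0.1 kBT)."""
        wins, edges = baoab_windows
        prof = wham(wins, temperature=1.0)
        total = np.sum([w.counts for w in wins], axis=0)
        mask = total >= 1000
        ana = _analytic_bin_profile(double_well, edges)
        diff = prof.F[mask] - ana[mask]
        diff -= np.average(diff, weights=total[mask])
        assert np.max(np.abs(diff)) < 0.2

    def test_window_order_invariance(self, baoab_windows):
        wins, _ = baoab_windows
        a = wham(wins, 1.0)
        b = wham(wins[::-1], 1.0)
        finite = np.isfinite(a.F) & np.isfinite(b.F)
        assert np.array_equal(np.isfinite(a.F), np.isfinite(b.F))
        assert np.max(np.abs(a.F[finite] - b.F[finite])) < 1e-10

    def test_bias_constant_invariance(self, baoab_windows):
        """Adding any constant to every window's bias leaves the profile
        unchanged."""
        wins, _ = baoab_windows
        centers = wins[0].bin_centers
        bias = np.stack([0.5 * w.spring * (centers - w.center) ** 2
                         for w in wins])
        a = wham(wins, 1.0, bias_matrix=bias)
        b = wham(wins, 1.0, bias_matrix=bias + 3.7)
        finite = np.isfinite(a.F) & np.isfinite(b.F)
        assert np.max(np.abs(a.F[finite] - b.F[finite])) < 1e-10


class TestPopulationRatio:
    def test_flat_profile_counts_bins(self):
        grid = np.arange(103, dtype=float)
        prof = FreeEnergyProfile(grid=grid, F=np.zeros(103), temperature=1.0)
        ratio = population_ratio(prof, TSRegion(101, 102), (0, 99))
        assert ratio == pytest.approx(0.02, rel=1e-12)

    def test_boltzmann_factor_single_bins(self):
        prof = FreeEnergyProfile(grid=np.array([0.0, 5.0]),
                                 F=np.array([0.0, 3.0]), temperature=1.0)
        ratio = population_ratio(prof, TSRegion(5, 5), (0, 0))
        assert ratio == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_quadrature_oracle_double_well(self, double_well):
        from scipy.integrate import quad

        system = ContinuousSystem(double_well)
        prof = system.profile(1.0, n_bins=4001)
        ts = TSRegion(-0.2, 0.2)
        ratio = population_ratio(prof, ts,
                                 basin_interval(prof.grid, ts, "A"))
        num = quad(lambda x: np.exp(-double_well.energy(x)), -0.2, 0.2)[0]
        den = quad(lambda x: np.exp(-double_well.energy(x)),
                   double_well.domain[0], -0.2)[0]
        assert ratio == pytest.approx(num / den, rel=1e-2)

    def test_reciprocal_invariant(self):
        rng = np.random.default_rng(2)
        grid = np.arange(50, dtype=float)
        prof = FreeEnergyProfile(grid=grid, F=rng.uniform(0, 4, 50),
                                 temperature=1.0)
        fwd = population_ratio(prof, TSRegion(40, 45), (0, 10))
        rev = population_ratio(prof, TSRegion(0, 10), (40, 45))
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_overlapping_regions_rejected(self):
        prof = FreeEnergyProfile(grid=np.arange(10, dtype=float),
                                 F=np.zeros(10), temperature=1.0)
        with pytest.raises(RegionError):
            population_ratio(prof, TSRegion(3, 6), (5, 9))

    def test_log_ratio_linear_in_inverse_temperature(self, double_well):
        """-kBT ln(N_TS/N_A) is nearly linear in 1/T across a 20%
        temperature range on the 5 kBT double well."""
        system = ContinuousSystem(double_well)
        ts = TSRegion(-0.2, 0.2)
        temps = np.linspace(0.9, 1.1, 9)
        y = []
        for T in temps:
            prof = system.profile(T)
            r = population_ratio(prof, ts, basin_interval(prof.grid, ts, "A"))
            y.append(-T * np.log(r))
        x = 1.0 / temps
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid @ resid / np.sum((y - np.mean(y)) ** 2)
        assert r2 > 0.99


class TestLocateLandmarks:
    def test_quartic_closed_form(self, double_well):
        prof = ContinuousSystem(double_well).profile(1.0, n_bins=1001)
        lm = locate_landmarks(prof)
        width = prof.grid[1] - prof.grid[0]
        assert lm.qa == pytest.approx(-1.0, abs=width)
        assert lm.qb == pytest.approx(1.0, abs=width)
        assert lm.q_top == pytest.approx(0.0, abs=width)
        assert lm.barrier_from_a == pytest.approx(5.0, abs=0.01)
        assert lm.barrier_from_b == pytest.approx(5.0, abs=0.01)

    def test_tilt_orders_barrier_heights(self):
        pot = make_double_well(5.0, 2.0, tilt=0.6)
        lm = locate_landmarks(ContinuousSystem(pot).profile(1.0))
        # positive tilt stabilises the left basin: climbing out of it is
        # harder than out of the shallow right basin
        assert lm.barrier_from_a > lm.barrier_from_b

    def test_discrete_chain_matches_exhaustive_scan(self, chain30):
        prof = chain30.profile(1.0)
        lm = locate_landmarks(prof)
        E = chain30.energies
        assert lm.qa == float(np.argmin(E[:15]))
        assert lm.qb == float(15 + np.argmin(E[15:]))
        assert lm.q_top == float(np.argmax(E[int(lm.qa):int(lm.qb)]) + lm.qa)

    def test_monostable_profile_rejected(self):
        prof = ContinuousSystem(make_harmonic(2.0)).profile(1.0)
        with pytest.raises(TopologyError):
            locate_landmarks(prof)


class TestMidpointTemperature:
    def test_symmetric_well_any_temperature(self, chain30):
        # symmetric discretisation: Delta F = 0, bracket edge returned
        T = midpoint_temperature(chain30, 0.8, 1.2,
                                 basin_a=(0, 13), basin_b=(16, 29))
        assert T == pytest.approx(0.8)

    def test_energy_entropy_toy_chain(self):
        """Basin A: 8 degenerate states at E=0; basin B: 2 states at
        E=-1.  Equal stability at T* = 1/ln 4."""
        energies = [0.0] * 8 + [5.0] + [-1.0] * 2
        system = ChainSystem(energies)
        t_star = 1.0 / np.log(4.0)
        T = midpoint_temperature(system, 0.4, 1.2,
                                 basin_a=(0, 7), basin_b=(9, 10), tol=1e-4)
        # |Delta F| < 0.05 stops within 0.05/ln4 of the true crossing
        assert abs(T - t_star) < 0.05 / np.log(4.0) + 1e-4

    def test_bracket_choice_does_not_matter(self):
        energies = [0.0] * 8 + [5.0] + [-1.0] * 2
        system = ChainSystem(energies)
        t1 = midpoint_temperature(system, 0.4, 1.2, (0, 7), (9, 10), tol=1e-4)
        t2 = midpoint_temperature(system, 0.6, 0.9, (0, 7), (9, 10), tol=1e-4)
        assert abs(t1 - t2) < 2 * (0.05 / np.log(4.0))

    def test_no_sign_change_raises(self):
        energies = [0.0] * 8 + [5.0] + [-1.0] * 2
        system = ChainSystem(energies)
        with pytest.raises(BracketError):
            midpoint_temperature(system, 1.5, 2.0, (0, 7), (9, 10))
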