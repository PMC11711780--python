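import itertools

import numpy as np
import pytest

from flowtwin.derivation import FlowWaveform
from flowtwin.stats import (
    PairedSeries,
    bland_altman,
    cov_pairwise,
    cov_repeatability,
    net_flow,
    rank_test,
    run_variability_study,
    summarize_pairs,
    waveform_rmse,
)
from flowtwin.synthetic import ZERO_NOISE, build_cohort


def _pairs(a, b, name="x", units="-"):
    return PairedSeries(name, units, np.asarray(a, float), np.asarray(b, float))


# --------------------------------------------------------------------------
# independent brute-force oracles
# --------------------------------------------------------------------------

def ranksum_exact_oracle(a, b):
    """Two-sided exact rank-sum p by enumeration of all C(n+m, n) labelings."""
    a, b = list(a), list(b)
    combined = sorted(a + b)
    ranks = {}
    for v in set(combined):
        idx = [i + 1 for i, x in enumerate(combined) if x == v]
        ranks[v] = sum(idx) / len(idx)
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    stats = [sum(ranks[combined[i]] for i in comb)
             for comb in itertools.combinations(range(len(combined)), n)]
    mu = np.mean(stats)
    tail = sum(abs(s - mu) >= abs(w_obs - mu) - 1e-12 for s in stats)
    return tail / len(stats)


class TestBlandAltman:
    def test_hand_example(self):
        """Pairs (1,2),(2,2),(3,5): diffs (-1,0,-2), bias -1, SD 1."""
        bias, (lo, hi) = bland_altman(_pairs([1, 2, 3], [2, 2, 5]))
        assert bias == pytest.approx(-1.0)
        assert lo == pytest.approx(-2.96)
        assert hi == pytest.approx(0.96)

    def test_identical_occasions(self):
        bias, (lo, hi) = bland_altman(_pairs([4, 5, 6], [4, 5, 6]))
        assert bias == lo == hi == 0.0

    def test_antisymmetry(self):
        p, q = _pairs([1, 4, 2], [3, 1, 5]), _pairs([3, 1, 5], [1, 4, 2])
        b1, (lo1, hi1) = bland_altman(p)
        b2, (lo2, hi2) = bland_altman(q)
        assert b2 == pytest.approx(-b1)
        assert (lo2, hi2) == pytest.approx((-hi1, -lo1))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            _pairs([1], [2])


class TestCov:
    def test_hand_example(self):
        """(10,12),(20,20): within-SD^2 {2,0}/..., RMS-SD 1, mean 15.5."""
        assert cov_repeatability(_pairs([10, 20], [12, 20])) == pytest.approx(
            6.451612903225806)

    def test_identical_pairs_zero(self):
        assert cov_repeatability(_pairs([3, 7, 9], [3, 7, 9])) == 0.0

    def test_scale_invariance(self):
        p = _pairs([10, 20, 15], [12, 19, 16])
        q = _pairs([30, 60, 45], [36, 57, 48])
        assert cov_repeatability(q) == pytest.approx(cov_repeatability(p))
        assert cov_pairwise(q) == pytest.approx(cov_pairwise(p))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cov_repeatability(_pairs([-5, 5], [5, -5]))


class TestRankTest:
    def test_identical_samples(self):
        assert rank_test(_pairs([2, 2, 2], [2, 2, 2])) == 1.0

    def test_fully_separated_samples_exact(self):
        """{1,2,3} vs {10,11,12} is the extreme assignment: p = 2/C(6,3)."""
        p = rank_test(_pairs([1, 2, 3], [10, 11, 12]))
        assert p == pytest.approx(ranksum_exact_oracle([1, 2, 3], [10, 11, 12]))
        assert p == pytest.approx(0.1)

    def test_shift_invariance(self):
        a, b = [1.2, 3.4, 2.2, 5.0], [2.0, 4.1, 0.5, 6.6]
        assert rank_test(_pairs(a, b)) == pytest.approx(
            rank_test(_pairs(np.array(a) + 37.0, np.array(b) + 37.0)))

    def test_matches_enumeration_on_random_inputs(self, rng):
        """Exact path vs the brute-force enumeration oracle, 60 draws."""
        for _ in range(60):
            n = int(rng.integers(2, 7))
            a = np.round(rng.normal(size=n), 6)
            b = np.round(rng.normal(0.5, size=n), 6)
            assert rank_test(_pairs(a, b)) == pytest.approx(
                ranksum_exact_oracle(a, b), abs=1e-10)


class TestWaveformTools:
    def _wave(self, flow, T=1.0, site="mitral_valve"):
        t = np.linspace(0, T, len(flow), endpoint=False)
        return FlowWaveform(site=site, time=t, flow=np.asarray(flow, float), T=T)

    def test_rmse_identical_zero(self):
        w = self._wave(np.sin(np.linspace(0, 2 * np.pi, 50, endpoint=False)))
        assert waveform_rmse(w, w) == 0.0

    def test_rmse_constant_offset(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))
        w1, w2 = self._wave(base), self._wave(base + 3.7)
        assert waveform_rmse(w1, w2) == pytest.approx(3.7)

    def test_rmse_half_sine_closed_form(self):
        """Half-sine of amplitude A over fraction f vs zero: A*sqrt(f/2)."""
        A, f, n = 250.0, 0.32, 400
        t = np.linspace(0, 1, n, endpoint=False)
        q = np.where(t < f, A * np.sin(np.pi * t / f), 0.0)
        w1 = self._wave(q)
        w2 = self._wave(np.zeros(n))
        assert waveform_rmse(w1, w2) == pytest.approx(A * np.sqrt(f / 2), rel=5e-3)

    def test_rmse_unequal_cycle_lengths_aligned_by_fraction(self):
        f = lambda x: 100 * np.abs(x - 0.5)  # piecewise linear in fraction
        t1 = np.linspace(0, 1.0, 40, endpoint=False)
        t2 = np.linspace(0, 0.8, 32, endpoint=False)
        w1 = FlowWaveform(site="mitral_valve", time=t1, flow=f(t1), T=1.0)
        w2 = FlowWaveform(site="mitral_valve", time=t2, flow=f(t2 / 0.8), T=0.8)
        assert waveform_rmse(w1, w2) < 1e-9

    def test_rmse_site_mismatch_rejected(self):
        w1 = self._wave(np.ones(30), site="mitral_valve")
        w2 = self._wave(np.ones(30), site="aortic_valve")
        with pytest.raises(ValueError, match="site"):
            waveform_rmse(w1, w2)

    def test_net_flow_constant(self):
        assert net_flow(self._wave(np.full(25, 100.0))) == pytest.approx(100.0)

    def test_net_flow_antisymmetric_waveform(self):
        q = np.sin(2 * np.pi * np.linspace(0, 1, 60, endpoint=False))
        assert net_flow(self._wave(q)) == pytest.approx(0.0, abs=1e-12)

    def test_net_flow_half_sine(self):
        t = np.arange(0, 1, 0.001)
        q = np.where(t < 0.3, 300 * np.sin(np.pi * t / 0.3), 0.0)
        w = FlowWaveform(site="mitral_valve", time=t, flow=q, T=1.0)
        assert net_flow(w) == pytest.approx(57.29577951308232, rel=1e-4)


class TestBruteForceSuite:
    def test_statistics_match_direct_formulas(self, rng):
        """Bland-Altman, both CoVs and RMSE vs plain re-implementations on
        random small inputs."""
        for _ in range(100):
            n = int(rng.integers(2, 11))
            a = rng.uniform(5, 15, n)
            b = a * rng.uniform(0.9, 1.1, n)
            p = _pairs(a, b)
            d = a - b
            bias, (lo, hi) = bland_altman(p)
            assert bias == pytest.approx(d.mean())
            sd = d.std(ddof=1)
            assert (lo, hi) == pytest.approx((d.mean() - 1.96 * sd,
                                              d.mean() + 1.96 * sd))
            gm = np.concatenate([a, b]).mean()
            assert cov_repeatability(p) == pytest.approx(
                100 * np.sqrt((d**2 / 2).mean()) / gm)
            assert cov_pairwise(p) == pytest.approx(100 * sd / gm)
        for _ in range(100):
            n = int(rng.integers(20, 40))
            t = np.linspace(0, 1, n, endpoint=False)
            qa, qb = rng.normal(size=n), rng.normal(size=n)
            wa = FlowWaveform(site="ascending_aorta", time=t, flow=qa, T=1.0)
            wb = FlowWaveform(site="ascending_aorta", time=t, flow=qb, T=1.0)
            assert waveform_rmse(wa, wb) == pytest.approx(
                np.sqrt(np.mean((qa - qb) ** 2)))


class TestVariabilityStudy:
    @pytest.fixture(scope="class")
    def quiet_cohort(self):
        from flowtwin.synthetic import NoiseModel
        design = {occ: NoiseModel(dt=0.04) for occ in
                  ("observer1_a", "observer1_b", "observer2")}
        return build_cohort(n_subjects=3, design=design, seed=17)

    def test_zero_noise_biases_vanish(self, quiet_cohort):
        rep = run_variability_study(quiet_cohort, "intra")
        assert np.allclose(rep.table["bias"], 0.0)
        assert np.allclose(rep.table["cov_percent"], 0.0)
        assert np.allclose(rep.rmse["rmse_mL_s"], 0.0)

    def test_report_row_count(self, quiet_cohort):
        rep = run_variability_study(quiet_cohort, "intra")
        # 4 input scalars + 3 net flows, no model parameters without fits
        assert len(rep.table) == 7
        fits = {occ: [s.truth for s in quiet_cohort.subjects]
                for occ in ("observer1_a", "observer1_b")}
        rep2 = run_variability_study(quiet_cohort, "intra", estimates=fits)
        assert len(rep2.table) == 7 + 7  # plus the seven headline parameters

    def test_missing_occasion_named(self, quiet_cohort):
        with pytest.raises(ValueError, match="sgre"):
            run_variability_study(quiet_cohort, "sequence")

    def test_pure_function_of_inputs(self, quiet_cohort):
        r1 = run_variability_study(quiet_cohort, "intra")
        r2 = run_variability_study(quiet_cohort, "intra")
        assert r1.table.equals(r2.table)

    def test_loa_bracket_bias(self, rng):
        for _ in range(20):
            a = rng.uniform(10, 20, 6)
            b = a + rng.normal(0, 1, 6)
            row = summarize_pairs(_pairs(a, b))
            assert row["loa_low"] <= row["bias"] <= row["loa_high"]
            assert row["cov_percent"] >= 0
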