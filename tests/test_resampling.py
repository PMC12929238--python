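import numpy as np
import pytest
from scipy import stats

import vwplat as v
from vwplat.data_model import BinnedCounts, GroupCounts
from vwplat.resampling import PermutationResult


def _counts(binning, groups):
    """groups: {name: (S matrix, N matrix, conditions or None)}"""
    built = {}
    for name, (S, N, cond) in groups.items():
        S = np.asarray(S, float)
        built[name] = GroupCounts(
            participants=np.asarray([f"{name}{i}" for i in range(S.shape[0])], dtype=object),
            conditions=np.asarray(cond if cond is not None else ["c1"] * S.shape[0], dtype=object),
            S=S,
            N=np.asarray(N, float),
        )
    return BinnedCounts(binning=binning, groups=built)


@pytest.fixture
def small_binning():
    return v.BinningConfig(roi_end_ms=200.0, bin_width_ms=50.0)  # 4 bins


def count_statistic(data):
    """Simple scalar statistic: difference in pooled success fractions."""
    s1, n1 = data.pooled("shifted")
    s0, n0 = data.pooled("baseline")
    return s1.sum() / n1.sum() - s0.sum() / n0.sum()


class TestBootstrapByParticipant:
    def test_single_participant_degenerate(self, small_binning, rng):
        data = _counts(
            small_binning,
            {
                "baseline": ([[1, 2, 3, 4]], [[5, 5, 5, 5]], None),
                "shifted": ([[2, 2, 2, 2]], [[5, 5, 5, 5]], None),
            },
        )
        cfg = v.ResamplingConfig(n_bootstrap=25, n_permutation=5)
        dist = v.bootstrap_by_participant(data, cfg, count_statistic, rng=rng)
        assert np.ptp(dist.values) == 0.0

    def test_resample_preserves_slot_counts(self, small_binning, rng):
        S = np.arange(20).reshape(5, 4)
        data = _counts(
            small_binning,
            {"baseline": (S, np.full((5, 4), 9.0), None), "shifted": (S, np.full((5, 4), 9.0), None)},
        )
        seen = []

        def record_stat(d):
            seen.append({g: d.groups[g].S.shape[0] for g in d.groups})
            return 0.0

        cfg = v.ResamplingConfig(n_bootstrap=10, n_permutation=5)
        v.bootstrap_by_participant(data, cfg, record_stat, rng=rng)
        assert all(s == {"baseline": 5, "shifted": 5} for s in seen)

    def test_omission_fraction(self, small_binning, rng):
        """P(participant absent from a resample) ~ (1-1/n)^n for n=10."""
        n = 10
        data = _counts(
            small_binning,
            {
                "baseline": (np.zeros((n, 4)), np.ones((n, 4)), None),
                "shifted": (np.zeros((n, 4)), np.ones((n, 4)), None),
            },
        )
        omitted = []

        def check_stat(d):
            omitted.append("baseline0" not in d.groups["baseline"].participants)
            return 0.0

        B = 2000
        cfg = v.ResamplingConfig(n_bootstrap=B, n_permutation=5)
        v.bootstrap_by_participant(data, cfg, check_stat, rng=rng)
        expected = (1 - 1 / n) ** n
        se = np.sqrt(expected * (1 - expected) / B)
        assert abs(np.mean(omitted) - expected) < 3 * se

    def test_condition_stratified_draws(self, small_binning, rng):
        cond = ["a", "a", "b", "b"]
        data = _counts(
            small_binning,
            {
                "baseline": (np.zeros((4, 4)), np.ones((4, 4)), cond),
                "shifted": (np.zeros((4, 4)), np.ones((4, 4)), cond),
            },
        )
        seen = []

        def check_stat(d):
            seen.append(sorted(d.groups["baseline"].conditions))
            return 0.0

        cfg = v.ResamplingConfig(n_bootstrap=20, n_permutation=5, stratify_by_condition=True)
        v.bootstrap_by_participant(data, cfg, check_stat, rng=rng)
        assert all(c == ["a", "a", "b", "b"] for c in seen)

    def test_empty_group_rejected(self, small_binning, rng):
        data = _counts(
            small_binning,
            {"baseline": (np.zeros((0, 4)), np.zeros((0, 4)), []), "shifted": ([[1, 1, 1, 1]], [[2, 2, 2, 2]], None)},
        )
        with pytest.raises(v.ConfigError):
            v.bootstrap_by_participant(
                data, v.ResamplingConfig(n_bootstrap=2, n_permutation=2), count_statistic, rng=rng
            )


class TestBootstrapStratified:
    def test_singleton_strata_identical(self, small_binning, rng):
        data = _counts(
            small_binning,
            {
                "baseline": ([[1, 0, 1, 0]], [[1, 1, 1, 1]], None),
                "shifted": ([[0, 1, 0, 1]], [[1, 1, 1, 1]], None),
            },
        )
        cfg = v.ResamplingConfig(n_bootstrap=30, n_permutation=5)
        dist = v.bootstrap_stratified(data, cfg, count_statistic, rng=rng)
        assert np.ptp(dist.values) == 0.0

    def test_stratum_counts_preserved(self, small_binning, rng):
        N = np.array([[4.0, 6.0, 0.0, 3.0], [2.0, 2.0, 2.0, 2.0]])
        S = np.array([[2.0, 3.0, 0.0, 1.0], [1.0, 0.0, 2.0, 2.0]])
        data = _counts(small_binning, {"baseline": (S, N, None), "shifted": (S, N, None)})

        def check_stat(d):
            for g in d.groups:
                assert np.array_equal(d.groups[g].N, N)
                assert (d.groups[g].S <= d.groups[g].N).all()
            return 0.0

        cfg = v.ResamplingConfig(n_bootstrap=25, n_permutation=5)
        v.bootstrap_stratified(data, cfg, check_stat, rng=rng)

    def test_across_bin_identity_broken(self, small_binning, rng):
        """Adjacent bins of one participant resample independently (m = 2)."""
        S = np.array([[1.0, 1.0, 1.0, 1.0]])
        N = np.array([[2.0, 2.0, 2.0, 2.0]])
        data = _counts(small_binning, {"baseline": (S, N, None), "shifted": (S, N, None)})
        draws = []

        def check_stat(d):
            draws.append(d.groups["baseline"].S[0, :2].copy())
            return 0.0

        cfg = v.ResamplingConfig(n_bootstrap=200, n_permutation=5)
        v.bootstrap_stratified(data, cfg, check_stat, rng=rng)
        draws = np.asarray(draws)
        # with s=1 of n=2 per stratum, each bin redraws Binomial(2, 1/2)
        # independently, so bins must disagree in a sizable share of resamples
        assert (draws[:, 0] != draws[:, 1]).mean() > 0.2


class TestPermutation:
    def test_p_value_direct_count(self, small_binning, rng):
        class FakeStat:
            def __init__(self):
                self.calls = -1
                self.null = [-100.0, 0.0, 50.0, 150.0, 200.0]

            def __call__(self, data):
                if self.calls < 0:
                    self.calls += 1
                    return 150.0  # observed
                val = self.null[self.calls % 5]
                self.calls += 1
                return val

        data = _counts(
            small_binning,
            {"baseline": (np.zeros((2, 4)), np.ones((2, 4)), None), "shifted": (np.zeros((2, 4)), np.ones((2, 4)), None)},
        )
        cfg = v.ResamplingConfig(n_bootstrap=2, n_permutation=5)
        res = v.permutation_test(data, cfg, FakeStat(), rng=rng)
        assert res.p_value == pytest.approx(2 / 5)  # |null| >= 150: {150, 200}

    def test_p_zero_when_observed_extreme(self, small_binning, rng):
        data = _counts(
            small_binning,
            {
                "baseline": (np.zeros((3, 4)), np.full((3, 4), 4.0), None),
                "shifted": (np.full((3, 4), 4.0), np.full((3, 4), 4.0), None),
            },
        )

        calls = {"n": 0}

        def stat(d):
            calls["n"] += 1
            return 500.0 if calls["n"] == 1 else 0.0

        cfg = v.ResamplingConfig(n_bootstrap=2, n_permutation=10)
        res = v.permutation_test(data, cfg, stat, rng=rng)
        assert res.p_value == 0.0

    def test_p_on_grid(self, small_binning, rng):
        data = _counts(
            small_binning,
            {
                "baseline": (np.eye(4), np.full((4, 4), 3.0), None),
                "shifted": (2 * np.eye(4), np.full((4, 4), 3.0), None),
            },
        )
        P = 17
        cfg = v.ResamplingConfig(n_bootstrap=2, n_permutation=P)
        res = v.permutation_test(data, cfg, count_statistic, rng=rng)
        assert (res.p_value * P) == pytest.approx(round(res.p_value * P))

    def test_null_symmetric_for_identical_groups(self, small_binning, rng):
        S = np.tile(np.array([1.0, 2.0, 3.0, 2.0]), (6, 1)) + np.arange(6)[:, None] % 2
        N = np.full((6, 4), 6.0)
        data = _counts(small_binning, {"baseline": (S, N, None), "shifted": (S, N, None)})
        cfg = v.ResamplingConfig(n_bootstrap=2, n_permutation=400)
        res = v.permutation_test(data, cfg, count_statistic, rng=rng)
        assert abs(stats.skew(res.distribution.values)) < 0.35

    def test_whole_participants_move(self, small_binning, rng):
        """Permutation reassigns rows intact: pooled totals are conserved."""
        S = rng.integers(0, 5, size=(4, 4)).astype(float)
        N = np.full((4, 4), 5.0)
        data = _counts(small_binning, {"baseline": (S, N, None), "shifted": (S + 1, N, None)})
        total = S.sum() + (S + 1).sum()

        def check_stat(d):
            s0, _ = d.pooled("baseline")
            s1, _ = d.pooled("shifted")
            assert s0.sum() + s1.sum() == total
            assert d.groups["baseline"].S.shape == (4, 4)
            return 0.0

        cfg = v.ResamplingConfig(n_bootstrap=2, n_permutation=30)
        v.permutation_test(data, cfg, check_stat, rng=rng)


class TestBootstrapCI:
    def test_constant_distribution_all_methods(self):
        values = np.full(200, 42.0)
        jack = np.full(10, 42.0)
        for method in v.CI_METHODS:
            res = v.bootstrap_ci(values, observed=40.0, method=method, jackknife_values=jack)
            assert (res.lower_ms, res.upper_ms) == (42.0, 42.0)

    def test_symmetric_identities(self, rng):
        """Symmetry about the observed value collapses the CI family."""
        half = rng.normal(0.0, 25.0, size=1500)
        values = 100.0 + np.concatenate([half, -half])  # exactly symmetric
        obs = 100.0
        pct = v.bootstrap_ci(values, obs, "percentile")
        emp = v.bootstrap_ci(values, obs, "empirical")
        assert pct.lower_ms == pytest.approx(emp.lower_ms, abs=1e-9)
        assert pct.upper_ms == pytest.approx(emp.upper_ms, abs=1e-9)
        bc = v.bootstrap_ci(values, obs, "bc")
        assert bc.diagnostics["z0"] == pytest.approx(0.0, abs=1e-12)
        assert bc.lower_ms == pytest.approx(pct.lower_ms, abs=1e-9)
        jack = np.concatenate([np.linspace(-5, 5, 8), -np.linspace(-5, 5, 8)])
        bca = v.bootstrap_ci(values, obs, "bca", jackknife_values=jack)
        assert bca.diagnostics["a"] == pytest.approx(0.0, abs=1e-12)
        assert bca.lower_ms == pytest.approx(bc.lower_ms, abs=1e-9)

    def test_normal_closed_form(self):
        rng = np.random.default_rng(0)
        values = rng.normal(12.0, 2.0, size=100000)
        res = v.bootstrap_ci(values, observed=10.0, method="normal")
        # center = observed - bias = 8, half-width = 1.96 * 2
        assert res.lower_ms == pytest.approx(4.08, abs=0.08)
        assert res.upper_ms == pytest.approx(11.92, abs=0.08)

    def test_percentile_level_one_is_min_max(self, rng):
        values = rng.normal(size=500)
        res = v.bootstrap_ci(values, 0.0, "percentile", level=1.0 - 1e-12)
        assert res.lower_ms == pytest.approx(values.min())
        assert res.upper_ms == pytest.approx(values.max())

    def test_bc_clamps_z0_at_edges(self):
        values = np.linspace(1.0, 2.0, 100)
        res = v.bootstrap_ci(values, observed=0.5, method="bc")
        assert res.diagnostics.get("z0_clamped")
        assert res.diagnostics["z0"] == pytest.approx(stats.norm.ppf(1 / 101))

    def test_bca_requires_jackknife(self):
        with pytest.raises(v.ConfigError):
            v.bootstrap_ci(np.linspace(0, 1, 50), 0.5, "bca")

    def test_bca_skew_shifts_interval(self, rng):
        values = rng.gamma(2.0, 50.0, size=4000)
        obs = float(np.median(values))
        jack = rng.gamma(2.0, 50.0, size=20) / 10.0
        pct = v.bootstrap_ci(values, obs, "percentile")
        bca = v.bootstrap_ci(values, obs, "bca", jackknife_values=jack)
        assert bca.diagnostics["a"] != 0.0
        assert (bca.lower_ms, bca.upper_ms) != (pct.lower_ms, pct.upper_ms)


class TestWilson:
    @pytest.mark.parametrize(
        "s,n,digits,expected",
        [
            (805, 1000, 2, (0.78, 0.83)),
            (817, 1000, 2, (0.79, 0.84)),
        ],
    )
    def test_rounded_bounds(self, s, n, digits, expected):
        lo, hi = v.wilson_interval(s, n)
        assert (round(lo, digits), round(hi, digits)) == expected

    def test_percent_rounding(self):
        lo, hi = v.wilson_interval(799, 1000)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (77.3, 82.3)

    def test_zero_successes_lower_bound_zero(self):
        lo, _ = v.wilson_interval(0, 37)
        assert lo == 0.0

    def test_zero_trials_rejected(self):
        with pytest.raises(v.ConfigError):
            v.wilson_interval(0, 0)


class TestJackknife:
    def test_leave_one_out_shapes(self, small_binning):
        data = _counts(
            small_binning,
            {
                "baseline": (np.arange(12).reshape(3, 4), np.full((3, 4), 12.0), None),
                "shifted": (np.arange(8).reshape(2, 4), np.full((2, 4), 12.0), None),
            },
        )
        jk = v.jackknife_by_participant(data, count_statistic)
        assert jk.shape == (5,)
        # leaving out different participants must change the statistic
        assert np.ptp(jk) > 0
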