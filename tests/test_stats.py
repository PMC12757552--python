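import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import redoxtmt as rt
from conftest import quantify_synthetic


class TestTwoSampleT:
    def test_textbook_pooled_variance_example(self):
        t, p = rt.two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.0213, abs=5e-4)
        # cross-check against scipy's implementation
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_swapping_groups_negates_t_keeps_p(self):
        t1, p1 = rt.two_sample_t([1.0, 2.5, 3], [4, 5.5, 9])
        t2, p2 = rt.two_sample_t([4, 5.5, 9], [1.0, 2.5, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_identical_groups(self):
        assert rt.two_sample_t([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_zero_variance_distinct_groups(self):
        t, p = rt.two_sample_t([5, 5, 5], [7, 7, 7])
        assert t == -math.inf and p == 0.0

    def test_insufficient_values_gives_missing(self):
        t, p = rt.two_sample_t([1.0], [4, 5, 6])
        assert math.isnan(t) and math.isnan(p)

    def test_nan_values_are_dropped(self):
        t1, _ = rt.two_sample_t([1, 2, 3, np.nan], [4, 5, 6])
        t2, _ = rt.two_sample_t([1, 2, 3], [4, 5, 6])
        assert t1 == pytest.approx(t2)


def brute_force_q(ox: pd.DataFrame, mask_a: np.ndarray) -> pd.Series:
    """Independent exhaustive-enumeration q-values for a 2-group design.

    Scalar loops throughout; usable only on tiny tables. Same null-pool
    convention as the implementation: the observed assignment and its
    complement are excluded.
    """
    x = ox.to_numpy(dtype=float)
    n = x.shape[1]
    n_a = int(mask_a.sum())

    def tstat(row, mask):
        a, b = row[mask], row[~mask]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            return math.nan
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        d = a.mean() - b.mean()
        if se == 0:
            return 0.0 if d == 0 else math.copysign(math.inf, d)
        return d / se

    obs = np.array([abs(tstat(row, mask_a)) for row in x])
    masks = []
    for combo in combinations(range(n), n_a):
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        if (m == mask_a).all() or (m == ~mask_a).all():
            continue
        masks.append(m)
    null = []
    for m in masks:
        for row in x:
            v = abs(tstat(row, m))
            if not math.isnan(v):
                null.append(v)
    raw = {}
    defined = [i for i in range(len(x)) if not math.isnan(obs[i])]
    for i in defined:
        n_null = sum(1 for v in null if v >= obs[i])
        n_obs = sum(1 for j in defined if obs[j] >= obs[i])
        raw[i] = min(1.0, (n_null / len(masks)) / n_obs)
    q = dict(raw)
    for i in defined:  # monotone: q(site) = min over weaker-or-equal sites
        q[i] = min(raw[j] for j in defined if obs[j] <= obs[i])
    out = pd.Series(math.nan, index=ox.index)
    for i in defined:
        out.iloc[i] = q[i]
    return out


class TestPermutationFdr:
    def _labels(self, ox):
        return {s: ("A" if i < 3 else "B") for i, s in enumerate(ox.columns)}

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        ox = pd.DataFrame(rng.uniform(0, 100, size=(40, 6)),
                          index=[f"S{i}" for i in range(40)],
                          columns=[f"s{i}" for i in range(6)])
        ox.iloc[:4, 3:] += 60  # a few strong signals
        ox.iloc[5, 0] = np.nan
        q = rt.permutation_fdr(ox, self._labels(ox), n_permutations=1000,
                               seed=0)
        oracle = brute_force_q(ox, np.array([True] * 3 + [False] * 3))
        pd.testing.assert_series_equal(q, oracle, check_names=False,
                                       rtol=0, atol=0)

    def test_site_above_every_null_statistic_gets_q_zero(self):
        rng = np.random.default_rng(1)
        ox = pd.DataFrame(rng.normal(50, 1, size=(30, 6)))
        ox.iloc[0, :3] = [10.0, 10.001, 9.999]
        ox.iloc[0, 3:] = [90.0, 90.001, 89.999]
        q = rt.permutation_fdr(ox, self._labels(ox), seed=0)
        assert q.iloc[0] == 0.0

    def test_q_monotone_non_increasing_in_abs_t(self):
        rng = np.random.default_rng(2)
        ox = pd.DataFrame(rng.normal(50, 5, size=(60, 6)))
        labels = self._labels(ox)
        q = rt.permutation_fdr(ox, labels, seed=3)
        x = ox.to_numpy()
        t = np.array([rt.two_sample_t(row[:3], row[3:])[0] for row in x])
        order = np.argsort(-np.abs(t))
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()

    def test_sampled_mode_reproducible_and_calibrated(self):
        """8 vs 8 exceeds the exhaustive budget; sampled permutations are
        seed-reproducible and near-null q values stay high."""
        rng = np.random.default_rng(4)
        ox = pd.DataFrame(rng.normal(50, 5, size=(50, 16)))
        labels = {i: ("A" if i < 8 else "B") for i in range(16)}
        q1 = rt.permutation_fdr(ox, labels, n_permutations=300, seed=9)
        q2 = rt.permutation_fdr(ox, labels, n_permutations=300, seed=9)
        pd.testing.assert_series_equal(q1, q2)
        assert q1.median() > 0.5

    def test_bad_parameters(self):
        ox = pd.DataFrame(np.ones((3, 6)))
        with pytest.raises(rt.ParameterError):
            rt.permutation_fdr(ox, self._labels(ox), n_permutations=0)


class TestDifferentialOxidation:
    def test_dual_criterion_worked_examples(self):
        # large oxidation gain passing the FDR criterion
        assert rt.call_differential(21.0, p_value=0.001, q_value=0.03) == "oxidized"
        # highly significant but below the 5-point change threshold
        assert rt.call_differential(4.9, p_value=1e-4, q_value=0.001) == "ns"
        # big change failing the FDR criterion, fallback disabled
        assert rt.call_differential(12.0, p_value=0.2, q_value=0.4) == "ns"
        # reduced direction under the p fallback
        assert rt.call_differential(-12.0, p_value=0.01, q_value=0.4,
                                    criterion="p_fallback") == "reduced"

    def _planted_table(self, seed=51):
        cfg = rt.SyntheticRedoxConfig(n_peptides=400,
                                      differential_fraction=0.05,
                                      shift_size=21.0, seed=seed)
        return quantify_synthetic(cfg)

    def test_planted_oxidation_called_oxidized(self):
        ox, design, truth = self._planted_table()
        res = rt.differential_oxidation(ox, design, "control", "treated",
                                        seed=1)
        planted = truth.differential[truth.differential].index
        calls = res.loc[res.index.intersection(planted), "call"]
        assert (calls == "oxidized").mean() > 0.5
        assert (res.loc[~res.index.isin(planted), "call"] == "ns").mean() > 0.95

    def test_swapping_groups_swaps_directions(self):
        ox, design, _ = self._planted_table()
        fwd = rt.differential_oxidation(ox, design, "control", "treated",
                                        seed=1)
        rev = rt.differential_oxidation(ox, design, "treated", "control",
                                        seed=1)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])
        np.testing.assert_allclose(fwd["q_value"], rev["q_value"])
        swapped = rev["call"].map({"oxidized": "reduced",
                                   "reduced": "oxidized", "ns": "ns"})
        assert (fwd["call"] == swapped).all()

    def test_fallback_triggers_per_comparison(self):
        """When no site passes q<0.1 with |delta|>5, the comparison switches
        to p<0.05 for every site."""
        rng = np.random.default_rng(6)
        design = rt.make_design(("ctrl", "aza"), 3)
        samples = design.samples["sample_id"].tolist()
        base = rng.normal(30, 1, size=(30, 6))
        base[0, 3:] += 8.0  # moderate shift: p small, q too coarse
        ox = pd.DataFrame(base, columns=samples,
                          index=pd.Index([f"S{i}" for i in range(30)],
                                         name="site_key"))
        res = rt.differential_oxidation(ox, design, "ctrl", "aza", seed=2)
        assert (res["criterion_used"] == res["criterion_used"].iloc[0]).all()
        if res["criterion_used"].iloc[0] == "p_fallback":
            assert (res.loc[res["p_value"] < 0.05, "delta"].abs() > 5).any()

    def test_unknown_condition_raises(self):
        ox, design, _ = self._planted_table()
        with pytest.raises(rt.ParameterError):
            rt.differential_oxidation(ox, design, "control", "nope")


class TestDistributionSummary:
    def test_hand_counted_bins(self):
        ox = pd.DataFrame({"s": [0.0, 50.0, 100.0]})
        summary = rt.distribution_summary(ox, interval_edges=(0, 50, 100))
        assert summary.interval_counts["s"].tolist() == [1, 2]

    def test_all_equal_values_collapse_quartiles(self):
        ox = pd.DataFrame({"s": [42.0] * 5})
        stats = rt.distribution_summary(ox).stats
        assert stats.loc["s", "q1"] == stats.loc["s", "median"] \
            == stats.loc["s", "q3"] == 42.0

    def test_interval_counts_sum_to_n(self):
        rng = np.random.default_rng(7)
        ox = pd.DataFrame({"a": rng.uniform(0, 100, 200),
                           "b": np.r_[rng.uniform(0, 100, 150),
                                      [np.nan] * 50]})
        summary = rt.distribution_summary(ox)
        for col in ox.columns:
            assert summary.interval_counts[col].sum() == \
                summary.stats.loc[col, "n"]

    def test_high_oxidation_count(self):
        ox = pd.DataFrame({"s": [95.0, 92.0, 99.0, 10.0, 50.0]})
        summary = rt.distribution_summary(ox, interval_edges=(0, 90, 100))
        assert summary.interval_counts["s"].tolist()[-1] == 3


class TestAnovaFisherLsd:
    def test_identical_groups(self):
        f, p, pairs = rt.anova_fisher_lsd([[5, 5, 5]] * 3)
        assert f == 0.0 and p == 1.0
        assert all(pv == 1.0 for _, pv in pairs.values())

    def test_textbook_sums_of_squares(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        f, p, pairs = rt.anova_fisher_lsd(groups)
        # hand computation: SSB = 3*((2-5)^2 + 0 + (8-5)^2) = 54, MSB = 27;
        # SSW = 6, df = 6, MSW = 1 -> F = 27
        assert f == pytest.approx(27.0)
        assert p == pytest.approx(float(sps.f.sf(27.0, 2, 6)))
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        # LSD pair (0,1): t = (2-5)/sqrt(1*(2/3)) with 6 d.f.
        t01, p01 = pairs[(0, 1)]
        assert t01 == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert p01 == pytest.approx(2 * float(sps.t.sf(abs(t01), 6)))

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            f, p, pairs = rt.anova_fisher_lsd([[1, 2, 3], [9], [4, 5, 6]])
        assert set(pairs) == {(0, 2)}

    def test_single_usable_group_is_undefined(self):
        with pytest.warns(UserWarning):
            f, p, pairs = rt.anova_fisher_lsd([[1, 2, 3], [9]])
        assert math.isnan(f) and pairs == {}


class TestCorrelateSharedSites:
    def test_identical_profiles(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, n = rt.correlate_shared_sites(a, a.copy())
        assert r == pytest.approx(1.0) and n == 4

    def test_negated_profile(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        b = a.mean() - (a - a.mean())
        r, _ = rt.correlate_shared_sites(a, b)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        # cov = 11, ssx = 5, ssy = 26 -> r = 11/sqrt(130) = 0.9648
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        b = pd.Series([2.0, 4, 5, 9], index=list("abcd"))
        r, n = rt.correlate_shared_sites(a, b)
        assert r == pytest.approx(11.0 / math.sqrt(130.0))
        assert r == pytest.approx(0.9648, abs=5e-5)

    def test_intersection_and_missing_handling(self):
        a = pd.Series([1.0, 2, 3, np.nan, 9], index=list("abcde"))
        b = pd.Series([2.0, 4, 5, 9, 1], index=list("abcdf"))
        r, n = rt.correlate_shared_sites(a, b)
        assert n == 3

    def test_too_few_shared_sites_undefined(self):
        a = pd.Series([1.0, 2], index=list("ab"))
        r, n = rt.correlate_shared_sites(a, a)
        assert math.isnan(r) and n == 2
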