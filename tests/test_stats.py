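import numpy as np
import pytest
from scipy import stats as sps

from hippotrial.fixtures import poisson_record, regular_record
from hippotrial.stats import (EndpointVector, anova_tukey, count_spikes,
                              isi_and_frequency, mean_ci,
                              normality_and_variance_checks, pearson)


class TestEndpointExtraction:
    def test_spike_counting_sums_principal_cells(self):
        rec = regular_record(rate_hz=20, duration=1.0, n_cells=8,
                             region="CA1")
        assert count_spikes(rec, "CA1") == 160
        with pytest.raises(ValueError):
            count_spikes(rec, "DG")

    def test_regular_train_isi_and_frequency(self):
        rec = regular_record(rate_hz=20, duration=1.0, n_cells=4,
                             region="CA1")
        isi, freq = isi_and_frequency(rec, "CA1")
        assert isi == pytest.approx(0.05)
        assert freq == pytest.approx(20.0)
        assert freq == pytest.approx(1.0 / isi)

    def test_mixed_rate_cells_average_convention(self):
        """Two regular cells at 10 and 30 Hz: frequency is the mean rate,
        ISI the mean of the within-cell mean intervals."""
        a = regular_record(10, 1.0, 1, "CA1")
        b = regular_record(30, 1.0, 1, "CA1")
        rec = a
        rec.spike_times["CA1x"] = b.spike_times["CA1c0"]
        rec.regions["CA1x"] = "CA1"
        rec.kinds["CA1x"] = "pyramidal"
        isi, freq = isi_and_frequency(rec, "CA1")
        assert freq == pytest.approx(20.0)
        assert isi == pytest.approx((0.1 + 1 / 30) / 2, rel=1e-9)

    def test_silent_region_flags_isi(self):
        rec = regular_record(20, 1.0, 4, "CA1")
        for cid in list(rec.spike_times):
            rec.spike_times[cid] = rec.spike_times[cid][:0]
        isi, freq = isi_and_frequency(rec, "CA1")
        assert np.isnan(isi)
        assert freq == 0.0


class TestMeanCI:
    def test_constant_vector_zero_width(self):
        m, lo, hi = mean_ci([4.0, 4.0, 4.0])
        assert (m, lo, hi) == (4.0, 4.0, 4.0)

    def test_closed_form_five_points(self):
        # mean 3, s = 1.5811, t_{4,0.975} = 2.7764451052
        m, lo, hi = mean_ci([1, 2, 3, 4, 5])
        half = 2.7764451052 * np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)
        assert m == 3.0
        assert hi - m == pytest.approx(half, rel=1e-9)
        assert m - lo == pytest.approx(half, rel=1e-9)

    def test_degenerate_level(self):
        m, lo, hi = mean_ci([1.0, 2.0], level=0)
        assert lo == hi == m

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


def _groups(*arrays):
    return [EndpointVector(np.asarray(a, float), "n_spikes", "CA1",
                           arm=f"g{i}") for i, a in enumerate(arrays)]


class TestAnovaTukey:
    # fixed fixture used across the oracle checks
    DATA = ([12.1, 14.3, 11.8, 13.0, 12.6],
            [15.2, 16.1, 14.8, 15.9, 16.4],
            [11.0, 10.2, 12.3, 11.5, 10.9])

    def test_identical_groups_not_significant(self):
        tab = anova_tukey(_groups([1, 2, 3], [1, 2, 3]))
        assert tab.anova_F == pytest.approx(0.0)
        assert not tab.tukey.reject.any()

    def test_f_statistic_matches_sum_of_squares_oracle(self):
        """Brute-force one-way ANOVA from the definitional sums of
        squares."""
        tab = anova_tukey(_groups(*self.DATA))
        flat = np.concatenate(self.DATA)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2
                         for g in self.DATA)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                        for g in self.DATA)
        df_b, df_w = len(self.DATA) - 1, flat.size - len(self.DATA)
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert tab.anova_F == pytest.approx(f_oracle, rel=1e-10)
        p_oracle = float(sps.f.sf(f_oracle, df_b, df_w))
        assert tab.anova_p == pytest.approx(p_oracle, rel=1e-10)

    def test_tukey_matches_studentized_range_oracle(self):
        """Pairwise Tukey p equals the studentized-range tail
        probability computed from first principles."""
        tab = anova_tukey(_groups(*self.DATA))
        k = len(self.DATA)
        n = len(self.DATA[0])
        mse = np.mean([np.var(g, ddof=1) for g in self.DATA])
        df = k * (n - 1)
        for row in tab.tukey.itertuples():
            i = int(row.group1[1])
            j = int(row.group2[1])
            q = abs(np.mean(self.DATA[i]) - np.mean(self.DATA[j])) \
                / np.sqrt(mse / n)
            p_oracle = float(sps.studentized_range.sf(q, k, df))
            assert float(row.p_adj) == pytest.approx(p_oracle, abs=1e-4)

    def test_group_means_carry_cis(self):
        tab = anova_tukey(_groups(*self.DATA))
        for row in tab.group_means.itertuples():
            assert row.ci_lower <= row.mean <= row.ci_upper

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            anova_tukey(_groups([1, 2, 3]))


class TestAssumptionChecks:
    def test_gross_outlier_breaks_normality(self):
        rng = np.random.default_rng(0)
        clean = rng.normal(0, 1, 20)
        dirty = np.concatenate([clean, [40.0]])
        shapiro, _ = normality_and_variance_checks(
            _groups(clean, dirty))
        assert shapiro["g1"] < 0.01 < shapiro["g0"]

    def test_type_one_error_rates_are_calibrated(self):
        """Under the null (one normal population) both tests reject at
        about the nominal 5% level over many simulations."""
        rng = np.random.default_rng(2024)
        n_sim = 2000
        sw_rej = bf_rej = 0
        for _ in range(n_sim):
            x = rng.normal(0, 1, 10)
            if sps.shapiro(x).pvalue < 0.05:
                sw_rej += 1
            # median-centred Levene is visibly conservative at very
            # small n; calibration is checked at a moderate group size
            groups = rng.normal(0, 1, (3, 30))
            if sps.levene(*groups, center="median").pvalue < 0.05:
                bf_rej += 1
        band = 2 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(sw_rej / n_sim - 0.05) < band + 0.005
        assert abs(bf_rej / n_sim - 0.05) < band + 0.005


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_from_scratch_oracle(self):
        x = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 6.1, 0.8, 7.7, 3.3, 5.0])
        y = np.array([0.9, 2.8, 2.5, 4.9, 5.2, 5.9, 1.4, 6.8, 2.7, 4.1])
        r, p = pearson(x, y)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert r == pytest.approx(r_oracle, rel=1e-10)
        t = r_oracle * np.sqrt((len(x) - 2) / (1 - r_oracle ** 2))
        p_oracle = 2 * float(sps.t.sf(abs(t), len(x) - 2))
        assert p == pytest.approx(p_oracle, rel=1e-8)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


def test_poisson_fixture_obeys_poisson_law():
    counts = [sum(len(t) for t in
                  poisson_record(20.0, 1.0, 8, seed=s).spike_times.values())
              for s in range(30)]
    # 8 cells x 20 Hz x 1 s = 160 expected
    assert abs(np.mean(counts) - 160) < 4 * np.std(counts) / np.sqrt(30) + 2
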