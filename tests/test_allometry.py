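"""Ratios, scaling fits, group comparisons, and regeneration time-courses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from planaquant import (
    compare_groups,
    fit_scaling,
    make_allometry_table,
    neuron_cell_ratio,
    regeneration_timecourse,
)


class TestNeuronCellRatio:
    def test_basic_ratio(self):
        t = pd.DataFrame({"cells": [1000], "neurons": [100]})
        out = neuron_cell_ratio(t)
        assert out.iloc[0]["mean"] == pytest.approx(0.10)

    def test_equal_group_zero_sem(self):
        t = pd.DataFrame({"cells": [100, 100, 100], "neurons": [10, 10, 10]})
        out = neuron_cell_ratio(t)
        assert out.iloc[0]["sem"] == pytest.approx(0.0, abs=1e-12)

    def test_simulated_cohort_recovers_true_ratio(self):
        """50 noisy samples at true ratio 0.10: group mean within 2 SEM."""
        rng = np.random.default_rng(8)
        cells = rng.uniform(1e4, 1e6, 50)
        neurons = 0.10 * cells * np.exp(rng.normal(0, 0.05, 50))
        out = neuron_cell_ratio(pd.DataFrame({"cells": cells, "neurons": neurons}))
        assert abs(out.iloc[0]["mean"] - 0.10) <= 2 * out.iloc[0]["sem"]

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            neuron_cell_ratio(pd.DataFrame({"cells": [0], "neurons": [1]}))


class TestFitScaling:
    def test_exact_line(self):
        t = pd.DataFrame({"cells": np.arange(1, 20.0), "neurons": 0.1 * np.arange(1, 20.0)})
        fit = fit_scaling(t, segments=1)
        assert fit.slopes[0] == pytest.approx(0.1, abs=1e-10)
        assert fit.intercepts[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_segment_equals_normal_equations(self, rng):
        x = rng.uniform(0, 100, 40)
        y = 3.0 + 0.25 * x + rng.normal(0, 1, 40)
        fit = fit_scaling(pd.DataFrame({"cells": x, "neurons": y}), segments=1, weights=None)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slopes[0] == pytest.approx(slope, abs=1e-10)
        assert fit.intercepts[0] == pytest.approx(intercept, abs=1e-10)

    def test_two_segment_breakpoint_recovery(self):
        """Phantom with slopes 0.10/0.05 breaking at 5e5 cells: breakpoint
        within 10%, slopes within 15%."""
        table, truth = make_allometry_table(n_samples=100, noise_cv=0.05, seed=5)
        fit = fit_scaling(table, segments=2)
        assert fit.breakpoint == pytest.approx(truth["breakpoint"], rel=0.10)
        assert fit.slopes[0] == pytest.approx(truth["slopes"][0], rel=0.15)
        assert fit.slopes[1] == pytest.approx(truth["slopes"][1], rel=0.15)

    def test_no_breakpoint_on_truly_linear_data(self):
        table, _ = make_allometry_table(n_samples=60, breakpoint=None, noise_cv=0.05, seed=6)
        fit = fit_scaling(table, segments=2)
        assert not fit.breakpoint_supported
        assert fit.breakpoint is None

    def test_insufficient_points_rejected(self):
        t = pd.DataFrame({"cells": [1.0, 2, 3], "neurons": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            fit_scaling(t, segments=2)


class TestCompareGroups:
    def test_identical_groups(self):
        out = compare_groups([1, 2, 3], [1, 2, 3])
        assert out["t"] == 0.0
        assert out["p"] == 1.0
        assert out["stars"] == "ns"

    def test_hand_computed_t(self):
        """Pooled-variance t for (10..13) vs (20..23): mean diff 10, sample
        variance 5/3 each, pooled sd 1.291, se 0.9129 -> |t| = 10.954."""
        out = compare_groups([10, 11, 12, 13], [20, 21, 22, 23])
        assert abs(out["t"]) == pytest.approx(10.954, abs=1e-3)
        assert out["stars"] == "***"

    def test_matches_closed_form_exactly(self, rng):
        """Implementation agrees with the textbook pooled-variance formula
        to 1e-10 on fixed small arrays."""
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
            out = compare_groups(a, b)
            assert out["t"] == pytest.approx(t_ref, abs=1e-10)
            assert out["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_zero_variance(self):
        out = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert out["p"] == 1.0
        with pytest.raises(ValueError):
            compare_groups([2.0, 2.0], [3.0, 3.0])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_null_p_values_uniform(self):
        """Under the null the p distribution is uniform (KS over 200 reps)."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, 1000)
            b = rng.normal(0, 1, 1000)
            ps.append(compare_groups(a, b)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_type_one_error_calibrated(self):
        """Simulated null at alpha = 0.05 rejects at 0.05 +- 0.02 over
        2000 replicates (vectorized via the same pooled-variance path)."""
        rng = np.random.default_rng(13)
        n = 10
        a = rng.normal(0, 1, (2000, n))
        b = rng.normal(0, 1, (2000, n))
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        rate = float((p < 0.05).mean())
        # spot-check the vectorized path against compare_groups
        out = compare_groups(a[0], b[0])
        assert out["p"] == pytest.approx(p[0], abs=1e-12)
        assert abs(rate - 0.05) <= 0.02


class TestRegenerationTimecourse:
    @staticmethod
    def logistic_counts(days, rng, k=0.9, t0=5.0, top=1000.0, n_rep=4, noise=10.0):
        out = {}
        for d in days:
            mu = top / (1 + np.exp(-k * (d - t0)))
            out[d] = mu + rng.normal(0, noise, n_rep)
        return out

    def test_logistic_plateau_onset_near_saturation(self, rng):
        days = list(range(15))
        tables = self.logistic_counts(days, rng)
        out = regeneration_timecourse(tables)
        onset = out.attrs["plateau_onset_day"]
        assert onset is not None
        assert abs(onset - 10) <= 1.5

    def test_strictly_linear_no_plateau(self):
        tables = {d: np.array([100.0 * d + 5, 100.0 * d - 5]) for d in range(10)}
        out = regeneration_timecourse(tables)
        assert out.attrs["plateau_onset_day"] is None
        assert (out["phase"] == "increase").all()

    def test_constant_counts_plateau_from_day_zero(self):
        tables = {d: np.array([50.0, 50.0, 50.0]) for d in range(6)}
        out = regeneration_timecourse(tables)
        assert out.attrs["plateau_onset_day"] == 0.0
        assert (out["phase"] == "plateau").all()

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            regeneration_timecourse({0: np.array([1.0, 2.0]), 1: np.array([2.0, 3.0])})

    def test_mean_and_sem_columns(self):
        tables = {0: np.array([1.0, 3.0]), 1: np.array([2.0, 4.0]), 2: np.array([3.0, 5.0])}
        out = regeneration_timecourse(tables)
        assert out.iloc[0]["mean"] == pytest.approx(2.0)
        assert out.iloc[0]["sem"] == pytest.approx(1.0)
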