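"""Contingency statistics and the proportional-odds fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from osteomorph import (
    ContingencyTable,
    chi_square,
    collapse_classes,
    fit_ordinal_logistic,
    grouped_contrast,
    odds_ratio_2x2,
    significance_report,
)
from osteomorph.synthetic import OssificationModel, SimulationConfig, gen_ossification


def table(rows, index, columns):
    return ContingencyTable(pd.DataFrame(rows, index=index, columns=columns))


CLASSES4 = ["absent", "early", "advanced", "over"]


class TestCollapse:
    def test_zero_class_removed(self):
        t = table([[5, 10, 12, 0], [8, 9, 10, 0]], ["a", "b"], CLASSES4)
        collapsed = collapse_classes(t)
        assert collapsed.classes == CLASSES4[:3]

    def test_fully_populated_table_unchanged(self):
        t = table([[5, 10, 12, 1], [8, 9, 10, 2]], ["a", "b"], CLASSES4)
        assert collapse_classes(t).counts.equals(t.counts)

    def test_idempotent(self):
        t = table([[5, 0, 12, 0], [8, 0, 10, 0]], ["a", "b"], CLASSES4)
        once = collapse_classes(t)
        twice = collapse_classes(once)
        assert once.counts.equals(twice.counts)

    def test_fewer_than_two_classes_errors(self):
        t = table([[5, 0, 0, 0], [8, 0, 0, 0]], ["a", "b"], CLASSES4)
        with pytest.raises(ValueError, match="fewer than 2"):
            collapse_classes(t)

    def test_column_order_must_be_ordinal(self):
        with pytest.raises(ValueError, match="ordinal order"):
            table([[1, 2], [3, 4]], ["a", "b"], ["early", "absent"])


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square(table([[10, 10], [10, 10]], ["a", "b"], ["absent", "early"]))
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_matches_2x2_closed_form(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 60, size=4)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            res = chi_square(table([[a, b], [c, d]], ["g1", "g2"], ["absent", "early"]))
            assert res["chi2"] == pytest.approx(closed, abs=1e-9)

    def test_zero_margin_errors(self):
        t = table([[5, 0], [8, 0]], ["a", "b"], ["absent", "early"])
        with pytest.raises(ValueError, match="margin"):
            chi_square(t)

    def test_invariant_under_permutations(self, rng):
        counts = rng.integers(3, 30, size=(3, 4))
        t = ContingencyTable(pd.DataFrame(counts, index=list("abc"), columns=CLASSES4))
        base = chi_square(t)["chi2"]
        perm = counts[[2, 0, 1]][:, ::-1]
        t2 = ContingencyTable(
            pd.DataFrame(perm, index=list("cab"), columns=["w", "x", "y", "z"])
        )
        assert chi_square(t2)["chi2"] == pytest.approx(base, rel=1e-12)

    def test_small_expected_counts_warn_not_fail(self):
        t = table([[2, 30], [3, 28]], ["a", "b"], ["absent", "early"])
        with pytest.warns(UserWarning, match="below 5"):
            res = chi_square(t)
        assert np.isfinite(res["chi2"])


class TestOrdinalFit:
    def test_identical_distributions_or_near_one(self):
        t = table([[10, 20, 15, 5], [10, 20, 15, 5]], ["ref", "treat"], CLASSES4)
        fit = fit_ordinal_logistic(t, reference_group="ref")
        assert fit.or_ == pytest.approx(1.0, abs=1e-3)
        assert fit.p > 0.9

    def test_2x2_equals_classical_odds_ratio(self):
        t = table([[30, 10], [12, 28]], ["ref", "treat"], ["absent", "early"])
        fit = fit_ordinal_logistic(t, reference_group="ref")
        classical = (30 * 28) / (10 * 12)
        assert fit.or_ == pytest.approx(classical, abs=1e-5)

    def test_beats_brute_force_likelihood_grid(self):
        """Fitted optimum is at least as good as a dense (beta, cutpoints) grid."""
        counts = np.array([[12.0, 20.0, 8.0], [5.0, 18.0, 17.0]])
        t = table(counts, ["ref", "treat"], ["absent", "early", "advanced"])
        fit = fit_ordinal_logistic(t, reference_group="ref")

        def loglik(a1, a2, beta):
            alphas = np.array([a1, a2])
            total = 0.0
            for g, eta in enumerate([0.0, beta]):
                cum = expit(alphas - eta)
                p = np.diff(np.concatenate(([0.0], cum, [1.0])))
                total += counts[g] @ np.log(np.clip(p, 1e-300, None))
            return total

        grid = -np.inf
        for a1 in np.linspace(-3, 2, 60):
            for gap in np.linspace(0.05, 4, 50):
                for beta in np.linspace(-3, 3, 80):
                    grid = max(grid, loglik(a1, a1 + gap, beta))
        assert fit.loglik >= grid - 1e-6

    def test_matches_statsmodels_ordered_model(self):
        sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        counts = pd.DataFrame(
            [[12, 25, 40, 3], [30, 25, 20, 5]], index=["ref", "treat"], columns=CLASSES4
        )
        fit = fit_ordinal_logistic(ContingencyTable(counts), reference_group="ref")
        ys, xs = [], []
        for gi, g in enumerate(counts.index):
            for ci, c in enumerate(counts.columns):
                ys += [ci] * counts.loc[g, c]
                xs += [gi] * counts.loc[g, c]
        y = pd.Series(pd.Categorical(ys, ordered=True))
        res = sm.OrderedModel(y, np.array(xs)[:, None], distr="logit").fit(
            method="bfgs", disp=0
        )
        assert fit.beta == pytest.approx(res.params.iloc[0], abs=1e-4)
        assert fit.se == pytest.approx(res.bse.iloc[0], abs=1e-4)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)

    def test_parameter_recovery_from_latent_model(self):
        model = OssificationModel.from_latent(
            (-1.0, 0.5, 2.0), {"ref": 0.0, "treat": 1.5}, ["s"], paired=set()
        )
        betas = []
        for rep in range(60):
            recs = gen_ossification(model, SimulationConfig(200, seed=5000 + rep))
            t = ContingencyTable.from_records(recs, "s", conditions=["ref", "treat"])
            betas.append(fit_ordinal_logistic(collapse_classes(t), "ref").beta)
        assert np.mean(betas) == pytest.approx(1.5, abs=0.1)

    def test_separation_flag_and_finite_ci(self):
        t = table([[2, 25, 2], [25, 2, 0]], ["ref", "treat"],
                  ["absent", "early", "advanced"])
        fit = fit_ordinal_logistic(t, reference_group="ref")
        if fit.separation_flag:
            lo, hi = fit.ci95
            assert 0 < lo < hi < np.inf
        assert np.isfinite(fit.beta)

    def test_hard_separation_uses_penalized_fallback(self):
        t = table([[20, 0], [0, 20]], ["ref", "treat"], ["absent", "early"])
        fit = fit_ordinal_logistic(t, reference_group="ref")
        assert fit.separation_flag
        assert np.isfinite(fit.beta) and fit.or_ > 1
        lo, hi = fit.ci95
        assert lo > 1.0  # pooled evidence still excludes OR = 1

    def test_lr_p_value_available(self):
        t = table([[12, 25, 40, 3], [30, 25, 20, 5]], ["ref", "treat"], CLASSES4)
        wald = fit_ordinal_logistic(t, "ref", p_method="wald")
        lr = fit_ordinal_logistic(t, "ref", p_method="lr")
        assert lr.p == pytest.approx(wald.p, rel=0.5)
        assert lr.p_method == "lr"


class TestOddsRatio2x2:
    def test_plain_and_corrected(self):
        t = table([[30, 10], [12, 28]], ["a", "b"], ["absent", "early"])
        res = odds_ratio_2x2(t)
        assert res["or"] == pytest.approx((30 * 28) / (10 * 12))
        zero = table([[30, 0], [12, 28]], ["a", "b"], ["absent", "early"])
        res0 = odds_ratio_2x2(zero)
        assert res0["corrected"] and np.isfinite(res0["or"])


class TestGroupedContrast:
    def _records(self, shifts, n, seed):
        model = OssificationModel.from_latent(
            (-1.0, 0.5, 2.0), shifts, ["s"], paired=set()
        )
        return gen_ossification(model, SimulationConfig(n, seed=seed))

    def test_pooling_identical_groups_gives_unit_or(self):
        recs = self._records({"1g": 0.0, "3g": 0.0, "3g>1g": 0.0, "3g>axe": 0.0}, 400, 11)
        t = ContingencyTable.from_records(recs, "s")
        res = grouped_contrast(t, pool=["3g", "3g>1g", "3g>axe"], vs="1g")
        assert res["ordinal_fit"].or_ == pytest.approx(1.0, abs=0.25)

    def test_pooled_counts_are_sums(self):
        recs = self._records({"1g": 0.0, "3g": 0.7, "3g>1g": 0.7, "3g>axe": 0.7}, 50, 12)
        t = ContingencyTable.from_records(recs, "s")
        res = grouped_contrast(t, pool=["3g", "3g>1g", "3g>axe"], vs="1g")
        pooled_row = res["table"].counts.loc["3g+3g>1g+3g>axe"]
        manual = t.counts.loc[["3g", "3g>1g", "3g>axe"]].sum(axis=0)
        assert (pooled_row == manual[pooled_row.index]).all()

    def test_unknown_condition_errors(self):
        recs = self._records({"1g": 0.0, "3g": 0.5}, 30, 13)
        t = ContingencyTable.from_records(recs, "s")
        with pytest.raises(ValueError, match="unknown condition"):
            grouped_contrast(t, pool=["3g", "9g"], vs="1g")

    def test_pooling_increases_power_over_single_condition(self):
        """At equal per-group n, pooling three shifted conditions against the
        reference detects the shift more often than any single contrast."""
        shifts = {"1g": 0.0, "3g": 0.5, "3g>1g": 0.5, "3g>axe": 0.5}
        n, reps = 40, 60
        pooled_hits = single_hits = 0
        for rep in range(reps):
            recs = self._records(shifts, n, seed=9000 + rep)
            t = ContingencyTable.from_records(recs, "s")
            pooled = grouped_contrast(t, pool=["3g", "3g>1g", "3g>axe"], vs="1g")
            pooled_hits += pooled["ordinal_fit"].p < 0.05
            two = ContingencyTable(t.counts.loc[["1g", "3g"]])
            single = fit_ordinal_logistic(collapse_classes(two), "1g")
            single_hits += single.p < 0.05
        assert pooled_hits > single_hits


class TestSignificanceReport:
    def test_strict_threshold(self):
        df = pd.DataFrame({"p": [0.049, 0.05, 0.2]}, index=["a", "b", "c"])
        rep = significance_report(df)
        assert bool(rep.loc["a", "significant"])
        assert not bool(rep.loc["b", "significant"])
        assert rep.attrs["n_tests"] == 3

    def test_empty_results(self):
        rep = significance_report(pd.DataFrame(columns=["p"]))
        assert rep.empty and rep.attrs["n_tests"] == 0
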