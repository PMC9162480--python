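"""Inferential stages against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from pcw.stats_analysis import (
    ContingencyTable,
    compute_vif,
    crosstab,
    drop_sparse_levels,
    fit_lnpcw_regression,
    fit_multinomial,
    pearson_chi_square,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def chi2_bruteforce(obs: np.ndarray) -> float:
    """Two-loop Pearson statistic, independent of any library call."""
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = rows[i] * cols[j] / n
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def odds_ratio_2x2(a, b, c, d) -> float:
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# cross-tabs and chi-square
# ---------------------------------------------------------------------------

class TestCrosstab:
    def test_four_distinct_types_one_row(self):
        table = crosstab(
            ["low", "medium", "high", "very high"], ["Internal"] * 4
        )
        assert list(table.counts.loc["Internal"]) == [1, 1, 1, 1]

    def test_order_invariance(self, rng):
        labels = rng.choice(["low", "medium", "high"], size=60)
        chars = rng.choice(["A", "B"], size=60)
        perm = rng.permutation(60)
        t1 = crosstab(labels, chars)
        t2 = crosstab(labels[perm], chars[perm])
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            crosstab(["low"], ["A", "B"])


class TestPearsonChiSquare:
    def test_closed_form_2x2(self):
        res = pearson_chi_square(pd.DataFrame([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_proportional_rows_give_zero(self):
        res = pearson_chi_square(pd.DataFrame([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(100):
            shape = (rng.integers(2, 6), rng.integers(2, 6))
            obs = rng.integers(1, 60, size=shape).astype(float)
            res = pearson_chi_square(pd.DataFrame(obs))
            assert abs(res.statistic - chi2_bruteforce(obs)) < 1e-9

    def test_invariance_under_permutation_and_transpose(self, rng):
        obs = rng.integers(1, 50, size=(3, 4)).astype(float)
        base = pearson_chi_square(pd.DataFrame(obs)).statistic
        perm = obs[rng.permutation(3)][:, rng.permutation(4)]
        assert pearson_chi_square(pd.DataFrame(perm)).statistic == pytest.approx(base)
        assert pearson_chi_square(pd.DataFrame(obs.T)).statistic == pytest.approx(base)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi_square(pd.DataFrame([[0, 0], [5, 10]]))

    def test_small_expected_cells_warn(self):
        with pytest.warns(UserWarning, match="expected cell"):
            pearson_chi_square(pd.DataFrame([[1, 2], [3, 40]]))

    def test_drop_sparse_levels_removes_thin_rows(self):
        counts = pd.DataFrame(
            [[118, 595, 375, 146], [28, 83, 91, 13], [66, 184, 122, 75], [12, 18, 6, 2]],
            index=["Tertiary A", "Tertiary B", "Secondary", "First-tier"],
        )
        reduced = drop_sparse_levels(ContingencyTable(counts))
        assert list(reduced.counts.index) == ["Tertiary A", "Tertiary B", "Secondary"]


# ---------------------------------------------------------------------------
# ln(PCW) OLS and VIF
# ---------------------------------------------------------------------------

def gender_frame(n, beta, intercept=6.353, noise=None, rng=None):
    female = np.zeros(n)
    female[n // 2:] = 1.0
    y = intercept + beta * female
    if noise is not None:
        y = y + rng.normal(0, noise, size=n)
    return pd.DataFrame(
        {"gender": np.where(female == 1, "Female", "Male"), "ln_pcw": y}
    )


class TestLnPcwRegression:
    def test_noiseless_recovery_to_machine_precision(self):
        frame = gender_frame(200, beta=0.115)
        res = fit_lnpcw_regression(frame, ["gender"], {"gender": "Male"})
        assert res.intercept["beta"] == pytest.approx(6.353, abs=1e-10)
        assert res.terms.loc[0, "beta"] == pytest.approx(0.115, abs=1e-10)
        assert res.references["gender"] == "Male"

    def test_constant_shift_moves_only_intercept(self, rng):
        frame = gender_frame(300, beta=0.2, noise=0.5, rng=rng)
        res1 = fit_lnpcw_regression(frame, ["gender"], {"gender": "Male"})
        shifted = frame.assign(ln_pcw=frame["ln_pcw"] + 1.7)
        res2 = fit_lnpcw_regression(shifted, ["gender"], {"gender": "Male"})
        assert res2.intercept["beta"] - res1.intercept["beta"] == pytest.approx(1.7)
        assert res2.terms.loc[0, "beta"] == pytest.approx(res1.terms.loc[0, "beta"])

    def test_undefined_outcome_rows_excluded_with_warning(self, rng):
        frame = gender_frame(100, beta=0.1, noise=0.3, rng=rng)
        frame.loc[0, "ln_pcw"] = np.nan
        with pytest.warns(UserWarning, match="excluding 1"):
            res = fit_lnpcw_regression(frame, ["gender"], {"gender": "Male"})
        assert res.n == 99

    def test_collinear_design_identified(self, rng):
        frame = gender_frame(50, beta=0.1, noise=0.2, rng=rng)
        frame["copy"] = frame["gender"]
        with pytest.raises(ValueError, match="collinear"):
            fit_lnpcw_regression(frame, ["gender", "copy"], {"gender": "Male", "copy": "Male"})

    def test_estimates_converge_with_sample_size(self, rng):
        errs = []
        for n in (500, 2000, 8000):
            frame = gender_frame(n, beta=0.115, noise=0.7, rng=rng)
            reps = [
                abs(
                    fit_lnpcw_regression(
                        gender_frame(n, beta=0.115, noise=0.7, rng=rng),
                        ["gender"], {"gender": "Male"},
                    ).terms.loc[0, "beta"] - 0.115
                )
                for _ in range(20)
            ]
            errs.append(np.mean(reps))
        assert errs[2] < errs[0]


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        x = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        vifs = compute_vif(x)
        np.testing.assert_allclose(vifs, [1.0, 1.0], atol=1e-12)

    def test_correlation_08_closed_form(self, rng):
        # build exact sample correlation 0.8 via Gram-Schmidt
        n = 400
        a = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b0 = rng.normal(size=n)
        b0 = b0 - b0.mean() - a * (a @ b0) / (a @ a)
        b = 0.8 * a + np.sqrt(1 - 0.64) * b0 / b0.std()
        vifs = compute_vif(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(vifs, 1 / (1 - 0.64), rtol=1e-10)

    def test_duplicated_predictor_reported_infinite(self, rng):
        a = rng.normal(size=50)
        with pytest.warns(UserWarning, match="aliased"):
            vifs = compute_vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(vifs).all()


# ---------------------------------------------------------------------------
# multinomial logit
# ---------------------------------------------------------------------------

def outcome_frame(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (gender, group), k in counts.items():
        rows.extend({"gender": gender, "pcw_group": group} for _ in range(k))
    return pd.DataFrame(rows)


class TestMultinomial:
    def test_collapsed_outcome_rrr_equals_odds_ratio(self):
        counts = {
            ("Male", "very high"): 35, ("Male", "low"): 20,
            ("Female", "very high"): 15, ("Female", "low"): 30,
        }
        frame = outcome_frame(counts)
        res = fit_multinomial(frame, ["gender"], {"gender": "Male"})
        want = odds_ratio_2x2(30, 15, 20, 35)  # (low|F / vh|F) / (low|M / vh|M)
        row = res.table.iloc[0]
        assert row.outcome == "low"
        assert row.rrr == pytest.approx(want, rel=1e-4)
        assert row.ci_low < row.rrr < row.ci_high

    def test_empty_outcome_cell_reported_not_estimable(self):
        counts = {
            ("Male", "very high"): 40, ("Male", "low"): 30, ("Male", "medium"): 30,
            ("Female", "very high"): 25, ("Female", "low"): 35,
            # no Female/medium cell
        }
        frame = outcome_frame(counts)
        res = fit_multinomial(frame, ["gender"], {"gender": "Male"})
        assert res.dropped_levels == [("gender", "Female")]
        assert not res.table["estimable"].any()

    def test_null_effect_rrr_near_one(self, rng):
        """A predictor generated independently of the outcome should give
        RRR close to 1 and non-significant p for the vast majority of
        replicates, per outcome contrast."""
        hits = {"low": 0, "medium": 0, "high": 0}
        reps = 200
        for _ in range(reps):
            n = 5000
            gender = rng.choice(["Male", "Female"], size=n)
            group = rng.choice(["low", "medium", "high", "very high"], size=n)
            frame = pd.DataFrame({"gender": gender, "pcw_group": group})
            res = fit_multinomial(frame, ["gender"], {"gender": "Male"})
            for _, row in res.table.iterrows():
                if 0.85 < row.rrr < 1.18 and row.p_value > 0.05:
                    hits[row.outcome] += 1
        for outcome, k in hits.items():
            assert k / reps >= 0.9, (outcome, k)

    def test_base_outcome_must_be_present(self):
        frame = outcome_frame({("Male", "low"): 5, ("Female", "medium"): 5})
        with pytest.raises(ValueError, match="base outcome"):
            fit_multinomial(frame, ["gender"], {"gender": "Male"})
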