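"""Behavioral statistics: accuracy summaries, within-subject ANOVA,
permutation correlations, sequential ANCOVA, partial correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tmsnet.behavior import (ancova_type1, partial_correlation,
                             permutation_correlation, rm_anova,
                             summarize_behavior)


def paired_table(sham, tms):
    rows = []
    for i, (s, t) in enumerate(zip(sham, tms)):
        rows.append((f"s{i}", "sham", s))
        rows.append((f"s{i}", "tms", t))
    return pd.DataFrame(rows, columns=["subject_id", "tms_condition", "acc"])


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        table = paired_table([0.4, 0.5, 0.6], [0.5, 0.7, 0.6])
        res = rm_anova(table, "acc", "subject_id", ["tms_condition"])
        row = res["tms_condition"]
        assert row["F"] == pytest.approx(3.0, abs=1e-10)
        assert row["df"] == 1 and row["df_err"] == 2
        d = np.array([0.1, 0.2, 0.0])
        t = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert row["F"] == pytest.approx(t**2)

    def test_identical_levels_give_zero_f(self):
        table = paired_table([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        res = rm_anova(table, "acc", "subject_id", ["tms_condition"])
        assert res["tms_condition"]["F"] == pytest.approx(0.0, abs=1e-20)

    def test_dfs_match_reported_convention(self, rng):
        # stimulus(3) x tms(2) at N=20: interaction df (2, 38)
        rows = []
        for i in range(20):
            for s in ("left", "right", "bilateral"):
                for c in ("sham", "tms"):
                    rows.append((f"s{i}", s, c, rng.random()))
        table = pd.DataFrame(rows, columns=["subject_id", "stimulus",
                                            "tms_condition", "acc"])
        res = rm_anova(table, "acc", "subject_id",
                       ["stimulus", "tms_condition"])
        row = res["stimulus:tms_condition"]
        assert (row["df"], row["df_err"]) == (2, 38)

    def test_matches_statsmodels_on_four_factor_design(self, rng):
        anova_mod = pytest.importorskip("statsmodels.stats.anova")
        rows = []
        for i in range(6):
            for a in range(2):
                for b in range(4):
                    for c in range(3):
                        for d in range(2):
                            rows.append((i, a, b, c, d, rng.normal()))
        df = pd.DataFrame(rows, columns=["subj", "tms", "block", "stim",
                                         "diff", "acc"])
        ours = rm_anova(df, "acc", "subj", ["tms", "block", "stim", "diff"])
        theirs = anova_mod.AnovaRM(df, "acc", "subj",
                                   within=["tms", "block", "stim", "diff"]
                                   ).fit().anova_table
        for _, row in ours.table.iterrows():
            key = row["effect"]
            assert theirs.loc[key, "F Value"] == pytest.approx(row["F"],
                                                               rel=1e-8)
            assert theirs.loc[key, "Pr > F"] == pytest.approx(row["p"],
                                                              rel=1e-6,
                                                              abs=1e-12)

    def test_ss_decomposition_sums_to_total(self, rng):
        rows = []
        for i in range(5):
            for a in range(3):
                for b in range(2):
                    rows.append((i, a, b, rng.normal()))
        df = pd.DataFrame(rows, columns=["subj", "f1", "f2", "y"])
        res = rm_anova(df, "y", "subj", ["f1", "f2"])
        total = (res.table["ss"].sum() + res.table["ss_err"].sum()
                 + res.ss_subject)
        assert total == pytest.approx(res.ss_total, rel=1e-8)

    def test_missing_cells_reported(self):
        table = paired_table([0.4, 0.5], [0.5, 0.7]).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(table, "acc", "subject_id", ["tms_condition"])


class TestPermutationCorrelation:
    def test_identity_gives_r_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        r, _ = permutation_correlation(x, x, b=200)
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        r, p = permutation_correlation(x, y, exact=True)
        assert r == pytest.approx(0.8)
        assert p == pytest.approx(8 / 24)

    def test_sampled_mode_approaches_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        _, p_exact = permutation_correlation(x, y, exact=True)
        _, p_samp = permutation_correlation(x, y, b=4000, exact=False, seed=2)
        assert abs(p_samp - p_exact) < 0.03

    def test_exhaustive_matches_manual_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r_obs, p = permutation_correlation(x, y, exact=True)
        count = 0
        for perm in itertools.permutations(range(5)):
            r = np.corrcoef(x, y[list(perm)])[0, 1]
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = permutation_correlation(x, y, b=500, seed=rep, exact=False)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09          # binomial 95% band around 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            permutation_correlation(np.ones(5), np.arange(5.0))

    def test_one_sided_variants(self):
        x = np.arange(6.0)
        y = x + 0.1 * np.random.default_rng(0).normal(size=6)
        _, p_greater = permutation_correlation(x, y, sided="greater",
                                               exact=True)
        _, p_less = permutation_correlation(x, y, sided="less", exact=True)
        assert p_greater < 0.01
        assert p_less > 0.9


class TestAncova:
    def test_orthogonal_covariate_sequential_equals_marginal(self, rng):
        n = 40
        cov = rng.normal(size=n)
        g = rng.normal(size=n)
        cov -= cov.mean()
        g -= g.mean()
        g -= cov * (cov @ g) / (cov @ cov)   # exactly orthogonal
        y = 0.8 * g + 0.3 * rng.normal(size=n)
        res = ancova_type1(y, cov, g)
        marginal_ss = (g @ y) ** 2 / (g @ g)
        assert res["connectivity"]["ss"] == pytest.approx(marginal_ss, rel=1e-8)

    def test_matches_statsmodels_type1(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_mod = pytest.importorskip("statsmodels.stats.anova")
        n = 25
        df = pd.DataFrame({"mt": rng.normal(size=n), "g": rng.normal(size=n)})
        df["y"] = 0.5 * df["mt"] + 0.7 * df["g"] + rng.normal(size=n)
        ours = ancova_type1(df["y"], df["mt"], df["g"])
        model = smf.ols("y ~ mt + g + mt:g", data=df).fit()
        theirs = anova_mod.anova_lm(model, typ=1)
        for term, key in [("mt", "covariate"), ("g", "connectivity"),
                          ("mt:g", "covariate:connectivity")]:
            assert ours[key]["ss"] == pytest.approx(theirs.loc[term, "sum_sq"],
                                                    rel=1e-8)
            assert ours[key]["F"] == pytest.approx(theirs.loc[term, "F"],
                                                   rel=1e-8)
            assert ours[key]["p"] == pytest.approx(theirs.loc[term, "PR(>F)"],
                                                   rel=1e-6, abs=1e-12)

    def test_sequential_ss_decomposition_identity(self, rng):
        n = 12
        y = rng.normal(size=n)
        res = ancova_type1(y, rng.normal(size=n), rng.normal(size=n))
        assert (res.table["ss"].sum() + res.ss_residual
                ) == pytest.approx(res.ss_total, rel=1e-8)

    def test_connectivity_detected_over_noise_covariate(self, rng):
        """With a pure-noise covariate entered first, the connectivity term
        stays strongly significant and the covariate is non-significant in a
        majority of replicates. (The covariate's sequential SS scales with
        total response variance while its F uses the full-model residual -
        the hybrid convention is mildly anti-conservative for early terms,
        so per-replicate non-significance is only a majority property.)"""
        n = 40
        conn_sig, cov_ns = 0, 0
        n_rep = 30
        for _ in range(n_rep):
            g = rng.normal(size=n)
            y = g + 1.0 * rng.normal(size=n)
            res = ancova_type1(y, rng.normal(size=n), g)
            conn_sig += res["connectivity"]["p"] < 0.01
            cov_ns += res["covariate"]["p"] > 0.05
        assert conn_sig >= 0.9 * n_rep
        assert cov_ns > 0.5 * n_rep

    def test_categorical_covariate_accepted(self, rng):
        n = 16
        order = np.array(["tms_first", "sham_first"] * (n // 2))
        res = ancova_type1(rng.normal(size=n), order, rng.normal(size=n),
                           covariate_name="admin_order")
        assert list(res.table["term"]) == [
            "admin_order", "connectivity", "admin_order:connectivity"]

    def test_collinear_inputs_rejected(self, rng):
        g = rng.normal(size=10)
        with pytest.raises(ValueError, match="collinear"):
            ancova_type1(rng.normal(size=10), g, g)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="5"):
            ancova_type1(np.ones(4), np.ones(4), np.ones(4))

    def test_hand_case_matches_stepwise_residuals(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        cov = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        g = np.array([1.0, 2.0, 2.0, 4.0, 3.0, 5.0])
        res = ancova_type1(y, cov, g)
        def rss(cols):
            X = np.column_stack([np.ones(6)] + cols)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ coef) ** 2).sum())
        ss_total = float(((y - y.mean()) ** 2).sum())
        seq = [ss_total - rss([cov]),
               rss([cov]) - rss([cov, g]),
               rss([cov, g]) - rss([cov, g, cov * g])]
        assert np.allclose(res.table["ss"], seq, atol=1e-10)


class TestPartialCorrelation:
    def test_uncorrelated_mediator_recovers_r_xy(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.6 * x + 0.8 * rng.normal(size=n)
        z = rng.normal(size=n)
        r_partial, _ = partial_correlation(x, y, z, b=200)
        assert r_partial == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.01)

    def test_mediator_equal_to_input_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="collinear|undefined"):
            partial_correlation(x, rng.normal(size=10), x)

    def test_residual_method_equals_closed_form(self, rng):
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            z = rng.normal(size=10)
            r_res, _ = partial_correlation(x, y, z, b=200)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            closed = (r_xy - r_xz * r_yz) / math.sqrt(
                (1 - r_xz**2) * (1 - r_yz**2))
            assert abs(r_res - closed) < 1e-10

    def test_strong_partial_association_detected(self, rng):
        n = 20
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.9 * x + 0.3 * z + 0.2 * rng.normal(size=n)
        _, p = partial_correlation(x, y, z, b=2000, seed=0)
        assert p < 0.01


class TestSummarize:
    def test_all_correct(self):
        rows = [(s, c, b, st_, d, 1)
                for s in ("s0", "s1") for c in ("sham", "tms")
                for b in (1, 2) for st_ in ("left", "bilateral")
                for d in ("easy", "difficult")]
        table = pd.DataFrame(rows, columns=["subject_id", "tms_condition",
                                            "block", "stimulus", "difficulty",
                                            "correct"])
        summary = summarize_behavior(table)
        assert summary.overall_accuracy == 1.0
        assert summary.overall_sem == 0.0
        assert (summary.per_cell["accuracy"] == 1.0).all()
        assert (summary.tms_effect["tms_effect"] == 0.0).all()

    def test_hand_counts(self):
        rows = [
            ("s0", "sham", "bilateral", 1), ("s0", "sham", "bilateral", 0),
            ("s0", "tms", "bilateral", 1), ("s0", "tms", "bilateral", 1),
            ("s1", "sham", "bilateral", 0), ("s1", "sham", "bilateral", 0),
            ("s1", "tms", "bilateral", 1), ("s1", "tms", "bilateral", 0),
        ]
        table = pd.DataFrame(rows, columns=["subject_id", "tms_condition",
                                            "stimulus", "correct"])
        summary = summarize_behavior(table)
        eff = summary.effect_vector("bilateral")
        assert eff["s0"] == pytest.approx(0.5)    # 1.0 - 0.5
        assert eff["s1"] == pytest.approx(0.5)    # 0.5 - 0.0

    def test_planted_chance_accuracy_within_binomial_error(self, toy_cohort):
        summary = summarize_behavior(toy_cohort.behavior)
        means = summary.condition_means
        bil = means[means["stimulus"] == "bilateral"]["mean"].mean()
        n_trials = 64 * len(toy_cohort.subjects)
        assert abs(bil - 0.475) < 3 * math.sqrt(0.25 / n_trials) + 0.05

    def test_missing_condition_rejected(self):
        rows = [("s0", "sham", "left", 1), ("s1", "sham", "left", 0),
                ("s1", "tms", "left", 1)]
        table = pd.DataFrame(rows, columns=["subject_id", "tms_condition",
                                            "stimulus", "correct"])
        with pytest.raises(ValueError, match="s0"):
            summarize_behavior(table)

    def test_non_binary_rejected(self):
        table = pd.DataFrame([("s0", "sham", "left", 0.5),
                              ("s0", "tms", "left", 1)],
                             columns=["subject_id", "tms_condition",
                                      "stimulus", "correct"])
        with pytest.raises(ValueError, match="binary"):
            summarize_behavior(table)


@given(st.integers(0, 10_000))
def test_partial_correlation_dual_route(seed):
    """Residual-based and closed-form partial correlations agree."""
    rng = np.random.default_rng(seed)
    x, y, z = rng.normal(size=(3, 8))
    try:
        r_res, _ = partial_correlation(x, y, z, b=200)
    except ValueError:
        return
    r_xy, r_xz, r_yz = (np.corrcoef(a, b)[0, 1]
                        for a, b in ((x, y), (x, z), (y, z)))
    closed = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    assert abs(r_res - closed) < 1e-9
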