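import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glymphalps as ga
from glymphalps.cohort import CohortSpec


def make_table(groups_values, variable="y", timepoint="pre"):
    rows = []
    i = 0
    for g, vals in groups_values.items():
        for v in vals:
            i += 1
            rows.append({"subject_id": f"S{i}", "group": g, "timepoint": timepoint, variable: v})
    return pd.DataFrame(rows)


def ols_oracle(y, X):
    """Normal equations + t distribution, independent of statsmodels."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    dof = len(y) - Xd.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), dof)
    tcrit = sps.t.ppf(0.975, dof)
    return beta, beta - tcrit * se, beta + tcrit * se, p


class TestCompareGroups:
    def test_identical_groups_no_effect(self):
        t = make_table({"HC": [1, 2, 3], "true_rTMS": [1, 2, 3], "sham_rTMS": [1, 2, 3]})
        res = ga.compare_groups(t, "y")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_chi2_matches_hand_oracle(self):
        t = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(30)],
                "group": ["HC"] * 10 + ["true_rTMS"] * 12 + ["sham_rTMS"] * 8,
                "timepoint": "pre",
                "gender": ["female"] * 6 + ["male"] * 4 + ["female"] * 9 + ["male"] * 3 + ["female"] * 3 + ["male"] * 5,
            }
        )
        res = ga.compare_groups(t, "gender")
        obs = pd.crosstab(t.group, t.gender).to_numpy().astype(float)
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2_hand, abs=1e-10)
        assert res.kind == "chi2"

    def test_tukey_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(2)
        t = make_table(
            {
                "HC": rng.normal(0.3, 1, 15),
                "true_rTMS": rng.normal(0.0, 1, 15),
                "sham_rTMS": rng.normal(-0.2, 1, 15),
            }
        )
        res = ga.compare_groups(t, "y")
        sub = t[t.timepoint == "pre"]
        for (g1, g2), padj in res.pairwise.items():
            _, p_raw = sps.ttest_ind(sub[sub.group == g1]["y"], sub[sub.group == g2]["y"])
            assert padj >= p_raw - 1e-12

    def test_small_group_rejected(self):
        t = make_table({"HC": [1.0], "true_rTMS": [1, 2, 3], "sham_rTMS": [1, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 2"):
            ga.compare_groups(t, "y")

    def test_anova_null_pvalues_uniform(self):
        """ANOVA p under H0 across seeded simulations is U(0,1)."""
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(1000):
            groups = {g: rng.normal(0, 1, 12) for g in ("HC", "true_rTMS", "sham_rTMS")}
            pvals.append(sps.f_oneway(*groups.values())[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestUnivariateScreen:
    def _patients(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        alps = rng.normal(1.45, 0.16, n)
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "group": "true_rTMS",
                "timepoint": "pre",
                "alps": alps,
                "x1": alps * 1.0,  # perfect predictor
                "x2": rng.normal(0, 1, n),
                "x3": np.full(n, 3.0),  # zero variance
            }
        )

    def test_perfect_predictor(self):
        t = self._patients()
        res = ga.univariate_screen(t, candidates=["x1"])[0]
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-12
        assert res.flagged

    def test_zero_variance_skipped_with_warning(self):
        t = self._patients()
        with pytest.warns(UserWarning, match="zero variance"):
            out = ga.univariate_screen(t, candidates=["x3", "x2"])
        assert [r.variable for r in out] == ["x2"]

    def test_matches_normal_equations_oracle(self):
        t = self._patients(seed=5)
        for res in ga.univariate_screen(t, candidates=["x1", "x2"]):
            x = t[res.variable].to_numpy()
            y = t["alps"].to_numpy()
            beta, lo, hi, p = ols_oracle(y, x[:, None])
            assert res.beta == pytest.approx(beta[1], abs=1e-8)
            assert res.ci_low == pytest.approx(lo[1], abs=1e-8)
            assert res.ci_high == pytest.approx(hi[1], abs=1e-8)
            assert res.p == pytest.approx(p[1], abs=1e-8)

    def test_designed_effect_flagged_with_high_power(self):
        hits = 0
        reps = 60
        for rep in range(reps):
            t, _ = ga.simulate_cohort(CohortSpec(seed=7000 + rep), imaging=False)
            res = ga.univariate_screen(t, candidates=["n2_duration"])[0]
            hits += res.flagged
        assert hits >= 0.95 * reps


class TestBackwardSelect:
    def _table(self, seed=0, n=80, k_null=3, effects=(0.5, -0.4)):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2 + k_null))
        y = effects[0] * X[:, 0] + effects[1] * X[:, 1] + rng.normal(0, 1, n)
        cols = {f"v{i}": X[:, i] for i in range(2 + k_null)}
        return pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(n)], "group": "true_rTMS", "timepoint": "pre", "alps": y, **cols}
        )

    def test_single_strong_candidate_retained_no_trace(self):
        t = self._table(seed=1, k_null=0, effects=(0.8, 0.0))
        res = ga.backward_select(t, screened=["v0"], p_removal=0.1)
        assert res.retained == ["v0"]
        assert res.trace == []

    def test_elimination_matches_exhaustive_oracle(self):
        """On <= 5 candidates the greedy elimination endpoint equals the
        oracle that replays the same removal rule by brute force over
        refit sequences using an independent OLS."""

        def oracle_backward(y, X, names, p_removal=0.1):
            names = list(names)
            while names:
                _, _, _, p = ols_oracle(y, X[:, [int(n[1:]) for n in names]])
                pc = dict(zip(names, p[1:]))
                worst = max(pc.values())
                if worst < p_removal:
                    break
                tied = [c for c in names if worst - pc[c] <= 1e-12]
                names.remove(tied[-1])
            return names

        for seed in range(8):
            t = self._table(seed=seed, n=60, k_null=3)
            names = ["v0", "v1", "v2", "v3", "v4"]
            res = ga.backward_select(t, screened=names, p_removal=0.1)
            X = t[names].to_numpy()
            expected = oracle_backward(t["alps"].to_numpy(), t[names].to_numpy(), names)
            assert res.retained == expected

    def test_adjustment_terms_never_removed(self):
        t = self._table(seed=3)
        t["gender"] = np.where(np.arange(len(t)) % 2 == 0, "female", "male")
        t["age"] = np.random.default_rng(0).normal(45, 10, len(t))
        res = ga.backward_select(t, screened=["v2", "v3", "v4"], adjust=["gender", "age"], p_removal=0.1, model_tag="model_I")
        assert "gender" in res.params and "age" in res.params
        assert set(res.retained).issubset({"v2", "v3", "v4"})
        removed = {v for v, _ in res.trace}
        assert removed.isdisjoint({"gender", "age"})

    def test_deterministic_given_table(self):
        t = self._table(seed=4)
        names = ["v0", "v1", "v2", "v3", "v4"]
        r1 = ga.backward_select(t, screened=names)
        r2 = ga.backward_select(t, screened=names)
        assert r1.retained == r2.retained and r1.trace == r2.trace

    def test_collinear_design_rejected_with_columns(self):
        t = self._table(seed=5)
        t["v9"] = t["v0"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ga.backward_select(t, screened=["v0", "v9", "v1"])

    def test_empty_candidates_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="non-empty"):
            ga.backward_select(t, screened=[])


class TestPairedPrepost:
    def _prepost(self, pre, post, group="true_rTMS"):
        rows = []
        for i, (a, b) in enumerate(zip(pre, post)):
            rows.append({"subject_id": f"S{i}", "group": group, "timepoint": "pre", "y": a})
            rows.append({"subject_id": f"S{i}", "group": group, "timepoint": "post", "y": b})
        return pd.DataFrame(rows)

    def test_no_change_gives_null(self):
        pre = [1.0, 1.2, 1.4, 1.6, 1.8]
        res = ga.paired_prepost(self._prepost(pre, pre), "y", "true_rTMS")
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_degenerate(self):
        pre = [1.0, 1.2, 1.4, 1.6, 1.8]
        post = [x + 1.0 for x in pre]
        res = ga.paired_prepost(self._prepost(pre, post), "y", "true_rTMS")
        assert res.degenerate
        assert res.mean_diff == pytest.approx(1.0)

    def test_incomplete_subjects_excluded_and_counted(self):
        t = self._prepost([1.0, 1.2, 1.4], [1.1, 1.3, 1.5])
        t = t.drop(t[(t.subject_id == "S2") & (t.timepoint == "post")].index)
        res = ga.paired_prepost(t, "y", "true_rTMS")
        assert res.n_pairs == 2 and res.n_excluded == 1

    def test_matches_scipy_and_ci_brackets(self):
        rng = np.random.default_rng(12)
        pre = rng.normal(1.4, 0.2, 15)
        post = pre + rng.normal(0.1, 0.1, 15)
        res = ga.paired_prepost(self._prepost(pre, post), "y", "true_rTMS")
        t_ref, p_ref = sps.ttest_rel(post, pre)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_power_in_treated_arm_size_in_sham(self):
        """Designed post-treatment shift detected in >= 80% of replicates
        in the true arm; false-positive rate near nominal in sham."""
        true_hits = sham_hits = 0
        reps = 60
        for rep in range(reps):
            t, _ = ga.simulate_cohort(CohortSpec(seed=8000 + rep), imaging=False)
            true_hits += ga.paired_prepost(t, "alps", "true_rTMS").p < 0.05
            sham_hits += ga.paired_prepost(t, "alps", "sham_rTMS").p < 0.05
        assert true_hits >= 0.8 * reps
        assert sham_hits <= 0.2 * reps

    def test_paired_t_null_calibration(self):
        rng = np.random.default_rng(100)
        pvals = [sps.ttest_rel(d := rng.normal(0, 1, 20), d - rng.normal(0, 1, 20))[1] for _ in range(2000)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.02)
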