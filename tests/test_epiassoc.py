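import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oppomark.epiassoc import (
    BehaviorPCA,
    behavior_pca,
    group_diff_regression,
    paired_ttest,
    pc_association,
    two_step_drinking,
)
from oppomark.io_config import BEHAVIOR_MEASURES, RunConfig, SampleSheet
from oppomark.synth_cohorts import gen_casecontrol_cohort, gen_drinking_cohort
from tests.conftest import simple_beta


def _paired_sheet(n_subjects):
    ids = [f"s{i}_T0" for i in range(n_subjects)] + [f"s{i}_T1" for i in range(n_subjects)]
    return SampleSheet(
        pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(n_subjects)] * 2,
                cohort="exercise",
                timepoint=["baseline"] * n_subjects + ["followup"] * n_subjects,
                age=30,
                sex="F",
                race="Caucasian",
            ),
            index=pd.Index(ids, name="sample_id"),
        )
    )


def _paired_beta(baseline, followup):
    arr = np.vstack([baseline, followup])
    n = baseline.shape[0]
    ids = [f"s{i}_T0" for i in range(n)] + [f"s{i}_T1" for i in range(n)]
    cols = [f"cg{j:08d}" for j in range(arr.shape[1])]
    from oppomark.io_config import BetaMatrix

    return BetaMatrix(pd.DataFrame(arr, index=ids, columns=cols))


class TestPairedTTest:
    def test_matches_closed_form_on_random_probes(self):
        rng = np.random.default_rng(0)
        n, p = 30, 100
        base = rng.uniform(0.2, 0.8, (n, p))
        fol = np.clip(base + rng.normal(0, 0.05, (n, p)), 0, 1)
        res = paired_ttest(_paired_beta(base, fol), _paired_sheet(n))
        d = fol - base
        t_exp = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
        p_exp = 2 * stats.t.sf(np.abs(t_exp), n - 1)
        assert np.abs(res.table["statistic"].to_numpy() - t_exp).max() < 1e-12
        assert np.abs(res.table["p"].to_numpy() - p_exp).max() < 1e-12
        # independent scipy oracle
        t_sp, p_sp = stats.ttest_rel(fol, base, axis=0)
        assert np.abs(res.table["statistic"].to_numpy() - t_sp).max() < 1e-10
        assert np.abs(res.table["p"].to_numpy() - p_sp).max() < 1e-10

    def test_zero_variance_differences_degenerate(self):
        base = np.full((4, 2), 0.3)
        fol = base.copy()
        fol[:, 0] += 0.1  # constant non-zero difference
        res = paired_ttest(_paired_beta(base, fol), _paired_sheet(4))
        assert res.table["p"].iloc[0] == 0.0 and res.table["significant"].iloc[0]
        assert res.table["p"].iloc[1] == 1.0 and not res.table["significant"].iloc[1]

    def test_invariant_to_subject_ordering(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.2, 0.8, (12, 5))
        fol = np.clip(base + rng.normal(0, 0.05, (12, 5)), 0, 1)
        beta, sheet = _paired_beta(base, fol), _paired_sheet(12)
        res1 = paired_ttest(beta, sheet)
        order = list(rng.permutation(beta.sample_ids))
        res2 = paired_ttest(beta.select_samples(order), sheet.select(order))
        assert np.allclose(res1.table["statistic"], res2.table["statistic"])

    def test_bonferroni_counts_probes_actually_tested(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0.2, 0.8, (10, 6))
        fol = np.clip(base + rng.normal(0, 0.05, (10, 6)), 0, 1)
        fol[:8, 0] = np.nan  # only 2 complete pairs -> skipped
        res = paired_ttest(_paired_beta(base, fol), _paired_sheet(10))
        assert res.n_tests == 5
        assert len(res.table) == 5

    def test_type_one_error_rate_nominal(self):
        rng = np.random.default_rng(3)
        rejections = 0
        trials = 0
        for _ in range(20):
            base = rng.uniform(0.3, 0.7, (53, 50))
            fol = np.clip(base + rng.normal(0, 0.05, (53, 50)), 0, 1)
            res = paired_ttest(_paired_beta(base, fol), _paired_sheet(53))
            rejections += int((res.table["p"] < 0.05).sum())
            trials += len(res.table)
        rate = rejections / trials
        lo, hi = stats.binom.interval(0.999, trials, 0.05)
        assert lo <= rejections <= hi, f"two-sided rejection rate {rate:.3f} off nominal"


def _cc_sheet(n_per_group, races=None, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    ids = [f"c{i}" for i in range(n)]
    race = races if races is not None else rng.choice(
        ["Caucasian", "Hispanic"], size=n
    )
    return SampleSheet(
        pd.DataFrame(
            dict(
                subject_id=ids,
                cohort="case_control",
                group=["control"] * n_per_group + ["drinker"] * n_per_group,
                age=rng.integers(21, 56, n),
                sex=rng.choice(["F", "M"], n),
                race=race,
            ),
            index=pd.Index(ids, name="sample_id"),
        )
    )


class TestGroupDiffRegression:
    def test_matches_normal_equations_and_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        sheet = _cc_sheet(40, seed=4)
        vals = np.clip(0.5 + 0.07 * rng.standard_normal((80, 100)), 0, 1)
        bm = simple_beta(vals, sample_prefix="c")
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        res = group_diff_regression(bm, sheet)
        d = sheet.data
        g = (d["group"] == "drinker").astype(float).to_numpy()
        race_ref = d["race"].value_counts().index[0]
        dummies = [
            (d["race"] == lv).astype(float).to_numpy()
            for lv in d["race"].value_counts().index[1:]
        ]
        X = np.column_stack([np.ones(80), g] + dummies)
        # brute-force normal equations
        for j in [0, 17, 63, 99]:
            y = vals[:, j]
            beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta_hat
            s2 = resid @ resid / (80 - X.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta_hat[1] / se
            assert abs(res.table["estimate"].iloc[j] - beta_hat[1]) < 1e-10
            assert abs(res.table["statistic"].iloc[j] - t) < 1e-10
            fit = sm.OLS(y, X).fit()
            assert abs(res.table["p"].iloc[j] - fit.pvalues[1]) < 1e-10

    def test_balanced_design_coefficient_is_mean_difference(self):
        rng = np.random.default_rng(5)
        races = ["Caucasian"] * 20 + ["Hispanic"] * 20 + ["Caucasian"] * 20 + ["Hispanic"] * 20
        sheet = _cc_sheet(40, races=races)
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((80, 10)), 0, 1)
        vals[40:] += 0.03
        vals = np.clip(vals, 0, 1)
        bm = simple_beta(vals)
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        res = group_diff_regression(bm, sheet)
        diff = vals[40:].mean(axis=0) - vals[:40].mean(axis=0)
        assert np.abs(res.table["estimate"].to_numpy() - diff).max() < 1e-10

    def test_constant_group_rejected(self):
        sheet = _cc_sheet(5)
        d = sheet.data.copy()
        d["group"] = "drinker"
        vals = np.full((10, 2), 0.5)
        bm = simple_beta(vals)
        bm = type(bm)(bm.values.set_axis(d.index, axis=0))
        with pytest.raises(ValueError, match="both groups"):
            group_diff_regression(bm, SampleSheet(d))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        sheet = _cc_sheet(30, seed=6)
        vals = np.clip(0.35 + 0.05 * rng.standard_normal((60, 5)), 0, 1)
        bm = simple_beta(vals)
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        shifted = type(bm)(np.add(bm.values, 0.2).clip(0, 1))
        res1 = group_diff_regression(bm, sheet)
        res2 = group_diff_regression(shifted, sheet)
        assert np.allclose(res1.table["statistic"], res2.table["statistic"], atol=1e-8)
        assert np.allclose(res2.table["mean_ref"] - res1.table["mean_ref"], 0.2)

    def test_power_on_planted_shift(self):
        # race-balanced groups, planted 0.08 shift, noise 0.05: the probe
        # must clear Bonferroni over a 5153-style family in most seeds
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(10):
            races = list(rng.choice(["Caucasian", "Hispanic"], 81))
            sheet = _cc_sheet(81, races=races * 2)
            y = 0.45 + 0.05 * rng.standard_normal(162)
            y[81:] += 0.08
            bm = simple_beta(np.clip(y, 0, 1)[:, None])
            bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
            res = group_diff_regression(bm, sheet)
            hits += int(res.table["p"].iloc[0] < 0.05 / 5153)
        assert hits >= 9


class TestBehaviorPCA:
    def test_isotropic_measures_need_twelve_pcs(self):
        rng = np.random.default_rng(8)
        B = pd.DataFrame(rng.standard_normal((600, 13)), columns=BEHAVIOR_MEASURES)
        pca = behavior_pca(B, 0.90)
        # uncorrelated measures: each PC explains ~1/13, so ceil(0.9*13)=12
        assert pca.k_ == 12

    def test_single_dominant_factor_needs_few_pcs(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal(500)
        B = pd.DataFrame(
            0.9 * f[:, None] + 0.25 * rng.standard_normal((500, 13)),
            columns=BEHAVIOR_MEASURES,
        )
        pca = behavior_pca(B, 0.90)
        assert pca.k_ <= 3
        assert pca.explained_variance_ratio_[0] > 0.7

    def test_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(10)
        B = pd.DataFrame(rng.standard_normal((100, 13)), columns=BEHAVIOR_MEASURES)
        pca = behavior_pca(B)
        assert abs(pca.explained_variance_ratio_.sum() - 1) < 1e-10
        assert (np.diff(pca.explained_variance_ratio_) <= 1e-12).all()

    def test_constant_measure_rejected(self):
        B = pd.DataFrame(
            np.random.default_rng(11).standard_normal((50, 13)),
            columns=BEHAVIOR_MEASURES,
        )
        B["ICS-total"] = 3.0
        with pytest.raises(ValueError, match="ICS-total"):
            behavior_pca(B)

    def test_cumulative_variance_contract(self):
        rng = np.random.default_rng(12)
        f = rng.standard_normal((300, 3))
        B = pd.DataFrame(
            f[:, [0, 0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]] * 0.7
            + 0.5 * rng.standard_normal((300, 13)),
            columns=BEHAVIOR_MEASURES,
        )
        pca = behavior_pca(B, 0.90)
        cum = np.cumsum(pca.explained_variance_ratio_)
        assert cum[pca.k_ - 1] >= 0.90
        assert pca.k_ == 1 or cum[pca.k_ - 2] < 0.90


def _drinker_sheet_with_behavior(n, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"d{i}" for i in range(n)]
    cols = dict(
        subject_id=ids,
        cohort="drinking",
        group="drinker",
        age=rng.integers(21, 56, n),
        sex=rng.choice(["F", "M"], n),
        race=rng.choice(["Caucasian", "Hispanic", "Native"], n),
    )
    for m in BEHAVIOR_MEASURES:
        cols[m] = rng.standard_normal(n)
    return SampleSheet(pd.DataFrame(cols, index=pd.Index(ids, name="sample_id")))


class TestPcAssociation:
    def test_linked_probe_passes(self):
        rng = np.random.default_rng(13)
        n = 281
        sheet = _drinker_sheet_with_behavior(n, seed=13)
        pca = behavior_pca(sheet.behavior())
        pc1 = pca.scores_["PC1"].to_numpy()
        pc1z = (pc1 - pc1.mean()) / pc1.std()
        y = np.clip(0.5 + 0.05 * (0.25 * pc1z + np.sqrt(1 - 0.0625) * rng.standard_normal(n)), 0, 1)
        bm = simple_beta(y[:, None])
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        out = pc_association(bm, pca.scores_, sheet)
        assert bool(out["passed"].iloc[0])

    def test_null_pass_rate_matches_union_bound(self):
        # independent probe vs k PCs: pass rate ~ 1 - 0.95^k
        rng = np.random.default_rng(14)
        n = 281
        sheet = _drinker_sheet_with_behavior(n, seed=14)
        pca = behavior_pca(sheet.behavior())
        k = pca.k_
        p_probes = 400
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((n, p_probes)), 0, 1)
        bm = simple_beta(vals)
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        out = pc_association(bm, pca.scores_, sheet)
        expected = 1 - 0.95**k
        rate = out["passed"].mean()
        assert abs(rate - expected) < 0.10

    def test_zero_variance_pc_rejected(self):
        sheet = _drinker_sheet_with_behavior(20, seed=15)
        scores = pd.DataFrame(
            {"PC1": np.zeros(20)}, index=sheet.sample_ids
        )
        bm = simple_beta(np.full((20, 2), 0.5))
        bm = type(bm)(bm.values.set_axis(sheet.sample_ids, axis=0))
        with pytest.raises(ValueError, match="zero-variance"):
            pc_association(bm, scores, sheet)


class TestTwoStep:
    def test_final_set_is_subset_of_step1(self, manifest_small, panel_small):
        beta_cc, sheet_cc = gen_casecontrol_cohort(81, manifest_small, panel_small, seed=21)
        beta_dr, sheet_dr = gen_drinking_cohort(200, manifest_small, panel_small, seed=21)
        res = two_step_drinking(beta_cc, sheet_cc, beta_dr, sheet_dr, RunConfig())
        assert set(res.probes) <= set(res.step1.hits)

    def test_planted_probes_recovered_with_direction(self, manifest_small, panel_small):
        beta_cc, sheet_cc = gen_casecontrol_cohort(81, manifest_small, panel_small, seed=22)
        beta_dr, sheet_dr = gen_drinking_cohort(281, manifest_small, panel_small, seed=22)
        res = two_step_drinking(beta_cc, sheet_cc, beta_dr, sheet_dr, RunConfig())
        planted = set(manifest_small.drinking_affected)
        found = set(res.probes)
        assert len(planted & found) / len(planted) >= 0.8
        dirs = res.direction()
        for probe in planted & found:
            assert np.sign(dirs[probe]) == np.sign(
                manifest_small.drinking_delta[probe]
            )

    def test_empty_step1_yields_empty_result(self, manifest_small, panel_small):
        beta_cc, sheet_cc = gen_casecontrol_cohort(20, manifest_small, panel_small, seed=23)
        beta_dr, sheet_dr = gen_drinking_cohort(50, manifest_small, panel_small, seed=23)
        cfg = RunConfig(family_alpha=1e-300)
        res = two_step_drinking(beta_cc, sheet_cc, beta_dr, sheet_dr, cfg)
        assert res.probes == ()
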