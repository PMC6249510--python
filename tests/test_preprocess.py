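import numpy as np
import pandas as pd
import pytest

from oppomark.epiassoc import group_diff_regression
from oppomark.io_config import RunConfig, SampleSheet
from oppomark.preprocess import (
    CellTypeDeconvolution,
    adjust_batch,
    estimate_cell_props,
    estimate_error_sd,
    filter_missing,
    mask_detection,
    preprocess_cohort,
    screen_age_probes,
    sd_filter,
)
from oppomark.synth_cohorts import ReplicatePairs, gen_reference_panel
from tests.conftest import simple_beta


class TestMaskDetection:
    def test_strict_inequality_at_boundary(self):
        vals = np.full((1, 3), 0.5)
        det = np.array([[0.06, 0.05, 0.01]])
        out = mask_detection(simple_beta(vals, detection_p=det), 0.05)
        got = out.values.to_numpy()[0]
        assert np.isnan(got[0]), "p=0.06 must be masked"
        assert got[1] == 0.5, "p exactly 0.05 must be retained"
        assert got[2] == 0.5

    def test_all_good_is_identity(self):
        vals = np.random.default_rng(0).random((4, 5))
        det = np.full((4, 5), 0.01)
        bm = simple_beta(vals, detection_p=det)
        out = mask_detection(bm, 0.05)
        assert np.allclose(out.values, bm.values)

    def test_no_detection_p_noop_with_warning(self, caplog):
        bm = simple_beta([[0.5, 0.5]])
        with caplog.at_level("WARNING", logger="oppomark"):
            out = mask_detection(bm, 0.05)
        assert np.allclose(out.values, bm.values)
        assert any("no-op" in r.message for r in caplog.records)


class TestFilterMissing:
    def test_probe_above_rate_removed(self):
        vals = np.random.default_rng(1).random((100, 2))
        vals[:6, 0] = np.nan  # 6% missing
        out, removed = filter_missing(simple_beta(vals), 0.05, "probes")
        assert removed == ["cg00000000"]
        assert out.n_probes == 1

    def test_exactly_at_rate_retained(self):
        vals = np.random.default_rng(1).random((100, 2))
        vals[:5, 0] = np.nan  # exactly 5%
        out, removed = filter_missing(simple_beta(vals), 0.05, "probes")
        assert removed == []

    def test_no_missing_identity_and_order(self):
        bm = simple_beta(np.random.default_rng(2).random((5, 7)))
        out, removed = filter_missing(bm, 0.05, "samples")
        assert removed == []
        assert out.sample_ids == bm.sample_ids
        assert out.probe_ids == bm.probe_ids

    def test_everything_removed_is_hard_error(self):
        vals = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="every"):
            filter_missing(simple_beta(vals), 0.05, "probes")


def _batch_series(beta, labels):
    return pd.Series(labels, index=beta.sample_ids)


class TestAdjustBatch:
    def test_single_batch_identity(self):
        bm = simple_beta(np.random.default_rng(0).random((6, 4)))
        out = adjust_batch(bm, _batch_series(bm, ["B1"] * 6))
        assert np.allclose(out.values, bm.values)

    def test_planted_offset_removed(self):
        rng = np.random.default_rng(3)
        vals = 0.4 + 0.02 * rng.standard_normal((40, 10))
        vals[20:] += 0.05  # batch B2 offset
        bm = simple_beta(np.clip(vals, 0, 1))
        batch = _batch_series(bm, ["B1"] * 20 + ["B2"] * 20)
        out = adjust_batch(bm, batch)
        m1 = out.values.iloc[:20].mean()
        m2 = out.values.iloc[20:].mean()
        assert np.abs(m1 - m2).max() < 1e-10

    def test_probe_mean_preserved(self):
        rng = np.random.default_rng(4)
        bm = simple_beta(0.3 + 0.05 * rng.standard_normal((30, 8)))
        batch = _batch_series(bm, ["B1", "B2"] * 15)
        out = adjust_batch(bm, batch)
        assert np.abs(out.values.mean() - bm.values.mean()).max() < 1e-10

    def test_missing_entries_stay_missing(self):
        rng = np.random.default_rng(5)
        vals = rng.random((10, 3))
        vals[0, 0] = np.nan
        bm = simple_beta(vals)
        out = adjust_batch(bm, _batch_series(bm, ["B1"] * 5 + ["B2"] * 5))
        assert np.isnan(out.values.iloc[0, 0])

    def test_orthogonality_with_group_regression(self):
        # batch balanced within groups: adjustment must not change the
        # group test beyond numerical noise
        rng = np.random.default_rng(6)
        n = 40
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((n, 6)), 0, 1)
        bm = simple_beta(vals)
        batch = _batch_series(bm, ["B1", "B2"] * (n // 2))
        sheet = SampleSheet(
            pd.DataFrame(
                dict(
                    subject_id=bm.sample_ids,
                    cohort="case_control",
                    group=["control"] * (n // 2) + ["drinker"] * (n // 2),
                    age=30,
                    sex="F",
                    race="Caucasian",
                    batch=batch.to_numpy(),
                ),
                index=pd.Index(bm.sample_ids, name="sample_id"),
            )
        )
        raw = group_diff_regression(bm, sheet, covariates=())
        adj = group_diff_regression(adjust_batch(bm, batch), sheet, covariates=())
        # the group contrast is orthogonal to balanced batch dummies, so the
        # coefficient is untouched by the adjustment
        assert np.abs(raw.table["estimate"] - adj.table["estimate"]).max() < 1e-10


class TestErrorSd:
    def test_identical_replicates_give_zero(self):
        df = pd.DataFrame(np.full((3, 4), 0.5))
        assert estimate_error_sd(ReplicatePairs(df, df.copy())) == 0.0

    def test_single_pair_rejected(self):
        df = pd.DataFrame(np.full((1, 4), 0.5))
        with pytest.raises(ValueError):
            estimate_error_sd(ReplicatePairs(df, df.copy()))

    def test_known_error_recovered(self):
        rng = np.random.default_rng(7)
        base = pd.DataFrame(rng.uniform(0.3, 0.7, (10, 500)))
        sd = 0.05
        a = base + rng.normal(0, sd, base.shape)
        b = base + rng.normal(0, sd, base.shape)
        est = estimate_error_sd(ReplicatePairs(a, b))
        assert abs(est - sd) / sd < 0.05


class TestSdFilter:
    def test_constant_probe_dropped(self):
        vals = np.column_stack([np.full(20, 0.5), np.linspace(0, 1, 20)])
        retained = sd_filter(simple_beta(vals), 0.06)
        assert retained == ["cg00000001"]

    def test_zero_threshold_keeps_nonconstant(self):
        vals = np.random.default_rng(8).random((10, 5))
        assert len(sd_filter(simple_beta(vals), 0.0)) == 5

    def test_planted_sd_above_threshold_retained(self):
        rng = np.random.default_rng(9)
        vals = np.clip(0.5 + 0.08 * rng.standard_normal((200, 1)), 0, 1)
        assert sd_filter(simple_beta(vals), 0.06) == ["cg00000000"]


def _age_sheet(ages, ids):
    return SampleSheet(
        pd.DataFrame(
            dict(
                subject_id=ids,
                cohort="exercise",
                age=ages,
                sex=["F", "M"] * (len(ids) // 2),
                race="Caucasian",
            ),
            index=pd.Index(ids, name="sample_id"),
        )
    )


class TestAgeScreen:
    def test_planted_age_slope_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(10):
            ages = rng.uniform(18, 60, 100)
            y = 0.4 + 0.004 * (ages - 39) + rng.normal(0, 0.03, 100)
            bm = simple_beta(np.clip(y, 0, 1)[:, None])
            sheet = _age_sheet(ages, bm.sample_ids)
            hits += "cg00000000" in screen_age_probes(bm, sheet, 0.01)
        assert hits >= 9

    def test_null_exclusion_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        n, p = 100, 400
        ages = rng.uniform(18, 60, n)
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((n, p)), 0, 1)
        bm = simple_beta(vals)
        excluded = screen_age_probes(bm, _age_sheet(ages, bm.sample_ids), 0.01)
        # nominal 1% exclusion of null probes, binomial slack
        assert len(excluded) <= p * 0.03


class TestDeconvolution:
    def test_pure_sample_hits_vertex(self):
        panel = gen_reference_panel(2, 100, seed=1)
        bm = simple_beta(panel.profiles.iloc[[0]].to_numpy())
        props = estimate_cell_props(bm, panel)
        assert props.proportions.iloc[0, 0] > 0.99

    def test_mixture_recovered_within_0_05(self):
        panel = gen_reference_panel(2, 200, seed=2)
        rng = np.random.default_rng(12)
        w = np.array([0.7, 0.3])
        x = w @ panel.profiles.to_numpy() + rng.normal(0, 0.02, 200)
        props = estimate_cell_props(simple_beta(np.clip(x, 0, 1)[None, :]), panel)
        assert np.abs(props.proportions.to_numpy()[0] - w).max() < 0.05

    def test_output_on_simplex(self):
        panel = gen_reference_panel(3, 150, seed=3)
        rng = np.random.default_rng(13)
        X = np.clip(rng.dirichlet((2, 2, 2), 10) @ panel.profiles.to_numpy()
                    + rng.normal(0, 0.02, (10, 150)), 0, 1)
        props = estimate_cell_props(simple_beta(X), panel)
        arr = props.proportions.to_numpy()
        assert (arr >= 0).all()
        assert np.abs(arr.sum(axis=1) - 1).max() < 1e-8

    def test_degenerate_panel_rejected(self):
        panel = gen_reference_panel(2, 100, seed=4)
        flat = panel.profiles.copy()
        flat.iloc[1] = flat.iloc[0]
        from oppomark.synth_cohorts import ReferencePanel

        bad = ReferencePanel(profiles=flat, discriminating=())
        bm = simple_beta(flat.iloc[[0]].to_numpy())
        with pytest.raises(ValueError, match="identifiab"):
            estimate_cell_props(bm, bad)

    def test_too_few_overlapping_probes_rejected(self):
        panel = gen_reference_panel(2, 100, seed=5)
        bm = simple_beta(np.full((1, 5), 0.5), probe_prefix="xx")
        with pytest.raises(ValueError, match="overlap"):
            estimate_cell_props(bm, panel)

    def test_residual_monotone_along_iterations(self):
        panel = gen_reference_panel(2, 120, seed=6)
        rng = np.random.default_rng(14)
        x = np.clip(
            np.array([0.55, 0.45]) @ panel.profiles.to_numpy()
            + rng.normal(0, 0.03, 120),
            0,
            1,
        )
        solver = CellTypeDeconvolution(panel).fit(
            simple_beta(x[None, :]), record_path=True
        )
        path = np.array(solver.residual_path_[0])
        assert (np.diff(path) <= 1e-12).all()


class TestPipelineChain:
    def test_stage_order_and_counts(self, exercise_small, manifest_small):
        beta, sheet = exercise_small
        out, rep = preprocess_cohort(
            beta,
            sheet,
            RunConfig(),
            age_screen=True,
            sd_threshold=0.06,
        )
        stages = [s["stage"] for s in rep.stages]
        assert stages.index("mask_detection") < stages.index("filter_samples")
        assert stages.index("filter_probes_missing") < stages.index("adjust_batch")
        assert stages.index("adjust_batch") < stages.index("sd_filter")
        assert stages.index("sd_filter") < stages.index("age_screen")
        assert out.n_probes == len(rep.retained_probes)

    def test_age_list_union_with_regression_screen(self, exercise_small):
        beta, sheet = exercise_small
        prior = set(beta.probe_ids[:10])
        out, rep = preprocess_cohort(
            beta,
            sheet,
            RunConfig(),
            age_probe_list=prior,
            age_screen=True,
            sd_threshold=0.0,
        )
        assert prior & set(beta.probe_ids) <= set(rep.age_excluded) | set()
        assert not prior & set(out.probe_ids)
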