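"""Opposite-direction marker calling and its post-hoc confirmations.

A probe is an opposite-direction marker when it is significant in both the
longitudinal exercise analysis and the two-step drinking analysis, and the
exercise-induced shift has the opposite sign to the drinker-vs-control
difference.  Exactly equal means classify as "none" and can never be
opposite — the conservative tie rule.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from ._linalg import ols_by_pattern, race_dummies
from .epiassoc import AssocResult, group_diff_regression, paired_ttest
from .io_config import BetaMatrix, SampleSheet
from .preprocess import CellProportions

log = logging.getLogger("oppomark")

MARKER_COLUMNS = [
    "gene",
    "mean_control",
    "mean_drinker",
    "p_drinking",
    "mean_baseline",
    "mean_followup",
    "p_exercise",
    "drinking_direction",
    "exercise_direction",
    "opposite",
]


def load_table3() -> pd.DataFrame:
    """The packaged 15-row opposite-marker worked example (probe, gene,
    four group/timepoint means, two p-values)."""
    with resources.files("oppomark.data").joinpath("table3.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="CpG_site")


def load_table4_ipa() -> pd.DataFrame:
    """Static pathway-enrichment fixture (documentation only, not computed)."""
    with resources.files("oppomark.data").joinpath("table4_ipa.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# direction logic
# ---------------------------------------------------------------------------


def intersect_hits(exercise_hits, drinking_hits) -> list[str]:
    """Sorted intersection of the two hit sets (warning when disjoint)."""
    inter = sorted(set(exercise_hits) & set(drinking_hits))
    if not inter:
        log.warning("hit sets are disjoint: no overlapping markers")
    return inter


def classify_direction(mean_a: float, mean_b: float) -> str:
    """Sign of (mean_b - mean_a): 'hyper', 'hypo' or 'none' on exact tie."""
    if mean_a is None or mean_b is None or np.isnan(mean_a) or np.isnan(mean_b):
        raise ValueError("cannot classify direction with a missing mean")
    if mean_b > mean_a:
        return "hyper"
    if mean_b < mean_a:
        return "hypo"
    return "none"


def _suffix(direction: str, suffix: str) -> str:
    return direction if direction == "none" else f"{direction}_{suffix}"


def drinking_direction(mean_control: float, mean_drinker: float) -> str:
    return _suffix(classify_direction(mean_control, mean_drinker), "in_drinkers")


def exercise_direction(mean_baseline: float, mean_followup: float) -> str:
    return _suffix(classify_direction(mean_baseline, mean_followup), "after_exercise")


def _is_opposite(drink_dir: str, ex_dir: str) -> bool:
    return (drink_dir, ex_dir) in {
        ("hypo_in_drinkers", "hyper_after_exercise"),
        ("hyper_in_drinkers", "hypo_after_exercise"),
    }


def marker_calls_from_means(df: pd.DataFrame) -> pd.DataFrame:
    """Direction-classify a table carrying the four mean columns.

    Accepts the packaged worked-example layout (Mean_control, Mean_drinker,
    Mean_baseline, Mean_followup, plus p-value columns) and returns one
    MarkerCall row per probe.
    """
    out = pd.DataFrame(index=df.index)
    out["gene"] = df.get("Gene", "")
    out["mean_control"] = df["Mean_control"]
    out["mean_drinker"] = df["Mean_drinker"]
    out["p_drinking"] = df.get("P_drinking", np.nan)
    out["mean_baseline"] = df["Mean_baseline"]
    out["mean_followup"] = df["Mean_followup"]
    out["p_exercise"] = df.get("P_exercise", np.nan)
    out["drinking_direction"] = [
        drinking_direction(a, b) for a, b in zip(df["Mean_control"], df["Mean_drinker"])
    ]
    out["exercise_direction"] = [
        exercise_direction(a, b) for a, b in zip(df["Mean_baseline"], df["Mean_followup"])
    ]
    out["opposite"] = [
        _is_opposite(d, e) for d, e in zip(out["drinking_direction"], out["exercise_direction"])
    ]
    return out


def build_marker_calls(
    overlap: list[str],
    exercise: AssocResult,
    drinking_step1: AssocResult,
) -> pd.DataFrame:
    """Join the two association tables into per-probe MarkerCall records.

    Directions come from the test statistics' signs; when a regression
    coefficient disagrees with the raw mean difference (confounding), the
    coefficient wins and the row is flagged (``sign_conflict``).
    """
    ex = exercise.table.loc[overlap]
    dr = drinking_step1.table.loc[overlap]
    out = pd.DataFrame(index=pd.Index(overlap, name="probe_id"))
    out["gene"] = ""
    out["mean_control"] = dr["mean_ref"]
    out["mean_drinker"] = dr["mean_alt"]
    out["p_drinking"] = dr["p"]
    out["mean_baseline"] = ex["mean_ref"]
    out["mean_followup"] = ex["mean_alt"]
    out["p_exercise"] = ex["p"]

    coef_dir = np.sign(dr["estimate"])
    mean_dir = np.sign(dr["mean_alt"] - dr["mean_ref"])
    conflict = (coef_dir != mean_dir) & (coef_dir != 0) & (mean_dir != 0)
    if conflict.any():
        log.warning(
            "%d markers: group-coefficient sign disagrees with raw mean difference; "
            "using the coefficient",
            int(conflict.sum()),
        )
    out["sign_conflict"] = conflict
    out["drinking_direction"] = [
        "hyper_in_drinkers" if c > 0 else "hypo_in_drinkers" if c < 0 else "none"
        for c in coef_dir
    ]
    ex_dir = np.sign(ex["estimate"])
    out["exercise_direction"] = [
        "hyper_after_exercise" if c > 0 else "hypo_after_exercise" if c < 0 else "none"
        for c in ex_dir
    ]
    out["opposite"] = [
        _is_opposite(d, e)
        for d, e in zip(out["drinking_direction"], out["exercise_direction"])
    ]
    return out


def find_opposite(markers: pd.DataFrame) -> pd.DataFrame:
    """Subset of opposite-direction marker calls, sorted by drinking p."""
    opp = markers[markers["opposite"].astype(bool)].copy()
    return opp.sort_values("p_drinking")


# ---------------------------------------------------------------------------
# post-hoc confirmations
# ---------------------------------------------------------------------------


def posthoc_cellprops(
    beta: BetaMatrix,
    sheet: SampleSheet,
    props: CellProportions,
    analysis: str,
    markers: list[str],
    family_alpha: float = 0.05,
) -> AssocResult:
    """Re-test the markers with cell-type proportions as covariates.

    For the longitudinal cohort the paired design is replaced by a
    regression on the timepoint factor plus proportions; for the
    case-control cohort the group model gains proportion covariates.  The
    last cell-type column is dropped to break the simplex collinearity.
    """
    sub = beta.select_probes(markers)
    ids = sub.sample_ids
    P = props.proportions.loc[ids].to_numpy()[:, :-1]  # drop last type
    pnames = [f"prop[{c}]" for c in props.proportions.columns[:-1]]
    d = sheet.data.loc[ids]
    if analysis == "exercise":
        factor = (d["timepoint"] == "followup").to_numpy(dtype=float)
        labels = ("baseline", "followup")
        names = ["intercept", "timepoint[followup]"] + pnames
        X = np.column_stack([np.ones(len(d)), factor, P])
        is_alt = factor.astype(bool)
        analysis_name = "exercise_posthoc"
    elif analysis == "drinking":
        factor = (d["group"] == "drinker").to_numpy(dtype=float)
        labels = ("control", "drinker")
        R, rnames, _ = race_dummies(d["race"])
        names = ["intercept", "group[drinker]"] + rnames + pnames
        X = np.column_stack([np.ones(len(d)), factor, R, P])
        is_alt = factor.astype(bool)
        analysis_name = "drinking_posthoc"
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    fit = ols_by_pattern(sub.values.to_numpy(dtype=float), X, names=names)
    p = fit.pvalue(1)
    n_tests = int(np.isfinite(p).sum())
    thr = family_alpha / max(n_tests, 1)
    table = pd.DataFrame(
        {
            "estimate": fit.coef[1],
            "statistic": fit.tstat(1),
            "p": p,
            "significant": p < thr,
            "mean_ref": sub.values.loc[~is_alt].mean(axis=0).to_numpy(),
            "mean_alt": sub.values.loc[is_alt].mean(axis=0).to_numpy(),
            "n_used": fit.n_used,
        },
        index=sub.probe_ids,
    )
    return AssocResult(table, n_tests, family_alpha, analysis_name, labels)


def match_by_race(sheet: SampleSheet, seed: int = 0) -> list[str]:
    """Greedy exact race matching (nearest age within race) of drinkers to
    controls; returns the matched sample ids."""
    d = sheet.data
    matched: list[str] = []
    for race in sorted(d["race"].dropna().unique()):
        dr = d[(d["race"] == race) & (d["group"] == "drinker")].sort_values("age")
        ct = d[(d["race"] == race) & (d["group"] == "control")].sort_values("age")
        remaining = list(ct.index)
        for sid, row in dr.iterrows():
            if not remaining:
                break
            ages = d.loc[remaining, "age"]
            best = (ages - row["age"]).abs().idxmin()
            matched += [sid, best]
            remaining.remove(best)
    return matched


def subgroup_confirm(
    beta: BetaMatrix,
    sheet: SampleSheet,
    markers: list[str],
    subset: str,
    primary_direction: pd.Series | None = None,
    family_alpha: float = 0.05,
) -> tuple[AssocResult, pd.Series]:
    """Re-run the primary test on a confirmation subsample of the cohort.

    ``subset='vo2_increased'`` keeps the longitudinal participants whose
    maximal oxygen uptake rose (objective exercise evidence);
    ``subset='race_matched'`` keeps a greedily race-matched case-control
    subsample.  Returns the subset association table and a per-marker
    direction-consistency flag against ``primary_direction`` (signs).
    """
    d = sheet.data
    if subset == "vo2_increased":
        keep = list(d.index[d["vo2_increased"].astype(bool)])
        if not keep:
            raise ValueError("empty vo2-increased subset")
        n_units = d.loc[keep, "subject_id"].nunique()
        if n_units < 10:
            raise ValueError(f"vo2 subset has only {n_units} subjects (need >= 10)")
        res = paired_ttest(
            beta.select_probes(markers).select_samples(keep),
            sheet.select(keep),
            family_alpha,
        )
    elif subset == "race_matched":
        keep = match_by_race(sheet)
        if not keep:
            raise ValueError("empty race-matched subset")
        if len(keep) < 10:
            raise ValueError(f"race-matched subset has only {len(keep)} samples")
        res = group_diff_regression(
            beta.select_probes(markers).select_samples(keep),
            sheet.select(keep),
            family_alpha,
        )
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if primary_direction is not None:
        consistent = pd.Series(
            np.sign(res.table["estimate"]).reindex(primary_direction.index)
            == np.sign(primary_direction),
            name="direction_consistent",
        )
    else:
        consistent = pd.Series(True, index=res.table.index, name="direction_consistent")
    return res, consistent
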