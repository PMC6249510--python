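"""Association engines: paired longitudinal testing and the two-step
case-control + behavioral-PC procedure, each under Bonferroni control.

The Bonferroni denominator is always the number of probes actually tested in
the analysis at hand — discovery counts are data-dependent outputs, never
constants.  All tests are two-sided and run on the beta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._linalg import ols_by_pattern, race_dummies
from .io_config import BEHAVIOR_MEASURES, BetaMatrix, RunConfig, SampleSheet

log = logging.getLogger("oppomark")


@dataclass
class AssocResult:
    """Per-probe association table with its multiplicity bookkeeping.

    ``table`` is indexed by probe id with columns ``estimate`` (paired mean
    difference or group coefficient), ``statistic``, ``p``, ``significant``
    (Bonferroni at ``alpha`` over ``n_tests``), unadjusted ``mean_ref`` /
    ``mean_alt`` and ``n_used``.  ``labels`` names the two conditions,
    reference first (e.g. baseline/followup or control/drinker).
    """

    table: pd.DataFrame
    n_tests: int
    alpha: float
    analysis: str
    labels: tuple[str, str]

    @property
    def hits(self) -> list[str]:
        return sorted(self.table.index[self.table["significant"]])

    def direction(self) -> pd.Series:
        """Signed direction of the alt condition relative to the reference."""
        return pd.Series(
            np.sign(self.table["estimate"]), index=self.table.index, name="direction"
        )

    def hyper_hypo_counts(self, hits_only: bool = True) -> tuple[int, int]:
        t = self.table[self.table["significant"]] if hits_only else self.table
        return int((t["estimate"] > 0).sum()), int((t["estimate"] < 0).sum())


# ---------------------------------------------------------------------------
# paired longitudinal test
# ---------------------------------------------------------------------------


def paired_ttest(
    beta: BetaMatrix,
    sheet: SampleSheet,
    family_alpha: float = 0.05,
    min_pairs: int = 3,
) -> AssocResult:
    """Per-probe paired t-test of follow-up minus baseline.

    Differences are formed on complete pairs only; probes with fewer than
    ``min_pairs`` complete pairs are skipped (logged).  Zero-variance
    differences are degenerate: p := 0 when the mean difference is non-zero,
    p := 1 when it is exactly zero.
    """
    pairs = sheet.pairs()
    if pairs.isna().any().any():
        bad = pairs.index[pairs.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing a timepoint: {bad[:5]}")
    base_ids = pairs["baseline"].tolist()
    fol_ids = pairs["followup"].tolist()
    B = beta.values.loc[base_ids].to_numpy(dtype=float)
    F = beta.values.loc[fol_ids].to_numpy(dtype=float)
    D = F - B

    n = (~np.isnan(D)).sum(axis=0)
    tested = n >= min_pairs
    skipped = int((~tested).sum())
    if skipped:
        log.info("paired t-test: %d probes skipped (<%d complete pairs)", skipped, min_pairs)

    mean_d = np.full(D.shape[1], np.nan)
    sd_d = np.full(D.shape[1], np.nan)
    if tested.any():
        mean_d[tested] = np.nanmean(D[:, tested], axis=0)
        sd_d[tested] = np.nanstd(D[:, tested], axis=0, ddof=1)
    tstat = np.full(D.shape[1], np.nan)
    p = np.full(D.shape[1], np.nan)
    ok = tested & (sd_d > 0)
    se = sd_d[ok] / np.sqrt(n[ok])
    tstat[ok] = mean_d[ok] / se
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), n[ok] - 1)
    degen = tested & (sd_d == 0)
    if degen.any():
        log.info("paired t-test: %d probes with zero-variance differences", int(degen.sum()))
        nz = degen & (mean_d != 0)
        tstat[nz] = np.sign(mean_d[nz]) * np.inf
        p[nz] = 0.0
        z = degen & (mean_d == 0)
        tstat[z] = 0.0
        p[z] = 1.0

    n_tests = int(tested.sum())
    thr = family_alpha / max(n_tests, 1)
    table = pd.DataFrame(
        {
            "estimate": mean_d,
            "statistic": tstat,
            "p": p,
            "significant": (p < thr) & tested,
            "mean_ref": beta.values.loc[base_ids].mean(axis=0).to_numpy(),
            "mean_alt": beta.values.loc[fol_ids].mean(axis=0).to_numpy(),
            "n_used": n,
        },
        index=beta.probe_ids,
    )
    table = table[tested]
    return AssocResult(table, n_tests, family_alpha, "exercise", ("baseline", "followup"))


# ---------------------------------------------------------------------------
# case-control group regression
# ---------------------------------------------------------------------------


def _group_design(sheet: SampleSheet, sample_ids, covariates):
    d = sheet.data.loc[list(sample_ids)]
    if d["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    g = (d["group"] == "drinker").to_numpy(dtype=float)
    cols = [np.ones(len(d)), g]
    names = ["intercept", "group[drinker]"]
    if "race" in covariates:
        R, rnames, ref = race_dummies(d["race"])
        cols.append(R)
        names += rnames
    if "age" in covariates:
        cols.append(d["age"].to_numpy(dtype=float)[:, None])
        names.append("age")
    if "sex" in covariates:
        cols.append((d["sex"] == "M").to_numpy(dtype=float)[:, None])
        names.append("sex[M]")
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return X, names, g.astype(bool)


def group_diff_regression(
    beta: BetaMatrix,
    sheet: SampleSheet,
    family_alpha: float = 0.05,
    covariates: tuple[str, ...] = ("race",),
) -> AssocResult:
    """Per-probe OLS of beta on drinker/control status, covariate-adjusted.

    Race is dummy-coded with the most frequent level in the analyzed set as
    reference.  Group means are reported unadjusted.  Rank-deficient designs
    raise, naming the aliased column.
    """
    X, names, is_drinker = _group_design(sheet, beta.sample_ids, covariates)
    Y = beta.values.to_numpy(dtype=float)
    fit = ols_by_pattern(Y, X, names=names)
    tstat = fit.tstat(1)
    p = fit.pvalue(1)
    tested = np.isfinite(p)
    n_tests = int(tested.sum())
    thr = family_alpha / max(n_tests, 1)
    table = pd.DataFrame(
        {
            "estimate": fit.coef[1],
            "statistic": tstat,
            "p": p,
            "significant": (p < thr) & tested,
            "mean_ref": beta.values.loc[~is_drinker].mean(axis=0).to_numpy(),
            "mean_alt": beta.values.loc[is_drinker].mean(axis=0).to_numpy(),
            "n_used": fit.n_used,
        },
        index=beta.probe_ids,
    )
    table = table[tested]
    return AssocResult(table, n_tests, family_alpha, "drinking_step1", ("control", "drinker"))


# ---------------------------------------------------------------------------
# behavioral PCA
# ---------------------------------------------------------------------------


class BehaviorPCA(BaseEstimator, TransformerMixin):
    """PCA of the standardized behavior scores, keeping enough PCs to reach
    a cumulative-variance target.

    The heterogeneous ranges of the instruments make the correlation
    (standardized) scale the right one; components are eigenvectors of the
    correlation matrix, and ``k_`` is the smallest number of components whose
    cumulative explained variance reaches ``variance_target``.
    """

    def __init__(self, variance_target: float = 0.90):
        self.variance_target = variance_target

    def fit(self, B: pd.DataFrame, y=None) -> "BehaviorPCA":
        B = pd.DataFrame(B)
        if B.isna().any().any():
            raise ValueError("behavior matrix contains missing scores")
        sd = B.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant behavior measure {sd.index[sd == 0][0]!r}")
        Z = (B - B.mean(axis=0)) / sd
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # deterministic sign: largest-|loading| entry positive
        for j in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        ratios = evals / evals.sum()
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.variance_target - 1e-12) + 1)
        self.measures_ = list(B.columns)
        self.mean_ = B.mean(axis=0)
        self.scale_ = sd
        self.loadings_ = pd.DataFrame(
            evecs, index=B.columns, columns=[f"PC{j + 1}" for j in range(len(evals))]
        )
        self.explained_variance_ratio_ = ratios
        self.k_ = k
        self.scores_ = self.transform(B)
        return self

    def transform(self, B: pd.DataFrame) -> pd.DataFrame:
        B = pd.DataFrame(B)[self.measures_]
        Z = (B - self.mean_) / self.scale_
        S = Z.to_numpy() @ self.loadings_.to_numpy()[:, : self.k_]
        return pd.DataFrame(S, index=B.index, columns=[f"PC{j + 1}" for j in range(self.k_)])


def behavior_pca(B: pd.DataFrame, variance_target: float = 0.90) -> BehaviorPCA:
    """Fit :class:`BehaviorPCA` on a complete behavior-score matrix."""
    return BehaviorPCA(variance_target).fit(B)


# ---------------------------------------------------------------------------
# step-2 per-PC verification
# ---------------------------------------------------------------------------


def pc_association(
    beta: BetaMatrix,
    pc_scores: pd.DataFrame,
    sheet: SampleSheet,
    step2_alpha: float = 0.05,
    mode: str = "any",
) -> pd.DataFrame:
    """Per probe x PC regression of methylation on one PC plus covariates.

    Each PC enters its own model (beta ~ PC + age + sex + race dummies); a
    probe passes when ``mode='any'`` and its minimum PC p-value is below
    ``step2_alpha`` (uncorrected), when ``mode='all'`` and every PC p-value
    is, or for ``mode='PCj'`` on that specific component.
    """
    ids = list(pc_scores.index)
    d = sheet.data.loc[ids]
    sub = beta.select_samples(ids)
    Y = sub.values.to_numpy(dtype=float)
    age = d["age"].to_numpy(dtype=float)
    sex = (d["sex"] == "M").to_numpy(dtype=float)
    R, rnames, _ = race_dummies(d["race"])
    pvals = {}
    for pc in pc_scores.columns:
        s = pc_scores[pc].to_numpy(dtype=float)
        if s.std() == 0:
            raise ValueError(f"zero-variance component {pc!r}")
        X = np.column_stack([np.ones(len(d)), s, age, sex, R])
        fit = ols_by_pattern(Y, X, names=["intercept", pc, "age", "sex[M]"] + rnames)
        pvals[pc] = fit.pvalue(1)
    P = pd.DataFrame(pvals, index=sub.probe_ids)
    out = pd.DataFrame(index=sub.probe_ids)
    out["min_p"] = P.min(axis=1)
    out["best_pc"] = P.idxmin(axis=1)
    if mode == "any":
        out["passed"] = out["min_p"] < step2_alpha
    elif mode == "all":
        out["passed"] = (P < step2_alpha).all(axis=1)
    elif mode in P.columns:
        out["passed"] = P[mode] < step2_alpha
    else:
        raise ValueError(f"unknown step-2 mode {mode!r}")
    return pd.concat([out, P.add_prefix("p_")], axis=1)


# ---------------------------------------------------------------------------
# the composed two-step drinking analysis
# ---------------------------------------------------------------------------


@dataclass
class DrinkingResult:
    """Composition of group discovery and behavioral verification."""

    step1: AssocResult
    pca: BehaviorPCA | None
    step2: pd.DataFrame | None
    probes: tuple[str, ...] = ()

    def direction(self) -> pd.Series:
        return self.step1.direction().loc[list(self.probes)]


def two_step_drinking(
    beta_cc: BetaMatrix,
    sheet_cc: SampleSheet,
    beta_dr: BetaMatrix,
    sheet_dr: SampleSheet,
    config: RunConfig | None = None,
    step2_mode: str = "any",
) -> DrinkingResult:
    """Bonferroni group-difference discovery verified against behavior PCs.

    The final drinking-associated set is the subset of step-1 hits whose
    methylation associates with at least one behavior PC in the drinkers-only
    cohort (uncorrected, per the two-step design); it is therefore monotone
    in the step-1 output.
    """
    config = config or RunConfig()
    step1 = group_diff_regression(beta_cc, sheet_cc, config.family_alpha)
    hits = step1.hits
    if not hits:
        log.warning("two-step drinking: no step-1 hits; empty result")
        return DrinkingResult(step1, None, None, ())
    usable = [p for p in hits if p in beta_dr.values.columns]
    dropped = len(hits) - len(usable)
    if dropped:
        log.info("two-step drinking: %d step-1 hits absent from drinking matrix", dropped)
    behav = sheet_dr.behavior(complete_only=True)
    if list(behav.columns) != list(BEHAVIOR_MEASURES):
        raise ValueError("drinking cohort behavior block malformed")
    pca = behavior_pca(behav, config.pca_variance_target)
    sub = beta_dr.select_probes(usable).select_samples(list(behav.index))
    step2 = pc_association(sub, pca.scores_, sheet_dr, config.step2_alpha, step2_mode)
    final = tuple(sorted(step2.index[step2["passed"]]))
    log.info(
        "two-step drinking: %d step-1 hits -> %d verified (k=%d PCs)",
        len(hits),
        len(final),
        pca.k_,
    )
    return DrinkingResult(step1, pca, step2, final)
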