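"""Quality control and filtering chain for beta-value matrices.

The fixed stage order is: detection-p masking -> sample missing-rate filter
-> probe missing-rate filter (plus cross-hybridizing exclusion) -> per-probe
batch adjustment -> replicate-error SD filter -> (longitudinal cohort only)
age-probe screening.  Inter-subject SDs are therefore computed on
analysis-ready, batch-adjusted data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._linalg import ols_by_pattern, race_dummies
from .io_config import BetaMatrix, RunConfig, SampleSheet
from .synth_cohorts import ReferencePanel, ReplicatePairs

log = logging.getLogger("oppomark")


# ---------------------------------------------------------------------------
# masking and missing-rate filters
# ---------------------------------------------------------------------------


def mask_detection(beta: BetaMatrix, p_max: float = 0.05) -> BetaMatrix:
    """Set measurements with detection p strictly above ``p_max`` to missing."""
    if beta.detection_p is None:
        log.warning("no detection p-values present; masking is a no-op")
        return beta.copy()
    vals = beta.values.copy()
    mask = beta.detection_p.to_numpy() > p_max
    arr = vals.to_numpy()
    arr[mask] = np.nan
    out = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    out.attrs.update(vals.attrs)
    n = int(mask.sum())
    if n:
        log.info("detection masking: %d measurements set missing", n)
    return BetaMatrix(out, beta.detection_p.copy())


def filter_missing(
    beta: BetaMatrix, max_rate: float, axis: str
) -> tuple[BetaMatrix, list[str]]:
    """Drop samples or probes whose missing fraction strictly exceeds ``max_rate``."""
    if not (0 <= max_rate <= 1):
        raise ValueError("max_rate must lie in [0, 1]")
    rates = beta.missing_rate(axis)
    removed = list(rates.index[rates > max_rate])
    if axis == "samples":
        keep = [s for s in beta.sample_ids if s not in set(removed)]
        if not keep:
            raise ValueError("missing-rate filter removed every sample")
        out = beta.select_samples(keep)
    else:
        keep = [p for p in beta.probe_ids if p not in set(removed)]
        if not keep:
            raise ValueError("missing-rate filter removed every probe")
        out = beta.select_probes(keep)
    if removed:
        log.info("missing-rate filter (%s > %.2f): removed %d", axis, max_rate, len(removed))
    return out, removed


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------


def adjust_batch(beta: BetaMatrix, batch: pd.Series) -> BetaMatrix:
    """Regress batch dummies out of each probe; return residual + probe mean.

    Complete cases only; missing entries stay missing.  A single batch makes
    this the identity.  Output is clipped to [0, 1] with the clip count logged.
    """
    batch = batch.reindex(beta.sample_ids)
    if batch.isna().any():
        raise ValueError("batch label missing for some samples")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        return beta.copy()
    small = batch.value_counts()
    if (small < 2).any():
        raise ValueError("each batch needs at least 2 samples")
    Y = beta.values.to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(batch))] + [(batch == l).to_numpy(dtype=float) for l in levels[1:]]
    )
    fit = ols_by_pattern(Y, X, names=["intercept"] + [f"batch[{l}]" for l in levels[1:]])
    grand = np.nanmean(Y, axis=0)
    adj = fit.resid + grand[None, :]
    n_clip = int(np.nansum((adj < 0) | (adj > 1)))
    if n_clip:
        log.info("batch adjustment: %d values clipped to [0, 1]", n_clip)
    adj = np.clip(adj, 0.0, 1.0)
    out = pd.DataFrame(adj, index=beta.values.index, columns=beta.values.columns)
    out.attrs.update(beta.values.attrs)
    det = beta.detection_p.copy() if beta.detection_p is not None else None
    return BetaMatrix(out, det)


# ---------------------------------------------------------------------------
# replicate error and variance filtering
# ---------------------------------------------------------------------------


def estimate_error_sd(replicates: ReplicatePairs) -> float:
    """Per-measurement technical error SD from replicate pairs.

    The SD of paired replicate differences, pooled over probes and pairs,
    divided by sqrt(2) — the standard technical-replicate estimator.
    """
    if replicates.n_pairs < 2:
        raise ValueError("need at least 2 replicate pairs")
    d = (replicates.second.to_numpy() - replicates.first.to_numpy()).ravel()
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("no complete replicate differences")
    return float(np.std(d, ddof=1) / np.sqrt(2.0))


def sd_filter(beta: BetaMatrix, sd_threshold: float) -> list[str]:
    """Probes whose complete-case inter-subject SD strictly exceeds the threshold."""
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be non-negative")
    sds = beta.values.std(axis=0, ddof=1)
    retained = list(sds.index[sds > sd_threshold])
    log.info("SD filter (> %.3f): retained %d / %d probes", sd_threshold, len(retained), beta.n_probes)
    return retained


# ---------------------------------------------------------------------------
# age screening
# ---------------------------------------------------------------------------


def screen_age_probes(
    beta: BetaMatrix, sheet: SampleSheet, p_threshold: float = 0.01
) -> set[str]:
    """Probes whose methylation tracks age (adjusted for sex and race).

    Per probe, a linear model beta ~ age + sex + race dummies on complete
    cases; probes with an age-coefficient p below ``p_threshold``
    (uncorrected, deliberately liberal) are flagged for exclusion.  In a
    longitudinal cohort only the baseline sample of each subject enters, so
    observations are independent.
    """
    d = sheet.data.loc[beta.sample_ids]
    if "timepoint" in d.columns and d["timepoint"].notna().any():
        keep = d.index[d["timepoint"] == "baseline"]
        d = d.loc[keep]
        beta = beta.select_samples(list(keep))
    age = d["age"].to_numpy(dtype=float)
    sex = (d["sex"] == "M").to_numpy(dtype=float)
    R, rnames, _ = race_dummies(d["race"])
    X = np.column_stack([np.ones(len(d)), age, sex, R])
    names = ["intercept", "age", "sex[M]"] + rnames
    fit = ols_by_pattern(beta.values.to_numpy(dtype=float), X, names=names)
    p = fit.pvalue(1)
    excluded = {pr for pr, pv in zip(beta.probe_ids, p) if np.isfinite(pv) and pv < p_threshold}
    log.info("age screening: %d probes flagged at p < %g", len(excluded), p_threshold)
    return excluded


# ---------------------------------------------------------------------------
# reference-based cell-type deconvolution
# ---------------------------------------------------------------------------


@dataclass
class CellProportions:
    """Estimated cell-type mixture per sample (rows on the probability simplex)."""

    proportions: pd.DataFrame   # samples x cell types
    residual_norm: pd.Series

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy()
        if (arr < -1e-9).any():
            raise ValueError("negative cell proportion")
        if np.abs(arr.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("cell proportions do not sum to 1")


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    k = np.arange(1, v.size + 1)
    cond = u + (1.0 - css) / k > 0
    rho = np.nonzero(cond)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


class CellTypeDeconvolution(BaseEstimator):
    """Reference-based mixture estimation by constrained projection.

    Solves, per sample, ``min_w || P^T w - x ||^2`` over the probability
    simplex (non-negative proportions summing to one) by projected gradient
    with the 1/L step, which decreases the residual monotonically.

    Parameters
    ----------
    panel : ReferencePanel
        Cell-type mean beta profiles; at least 20 probes must overlap the
        queried matrix.
    max_iter, tol : solver controls (iterations stop when the proportion
        update falls below ``tol`` in max norm).
    """

    def __init__(self, panel: ReferencePanel, max_iter: int = 2000, tol: float = 1e-10):
        self.panel = panel
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, beta: BetaMatrix, record_path: bool = False) -> "CellTypeDeconvolution":
        common = [p for p in beta.probe_ids if p in self.panel.profiles.columns]
        if len(common) < 20:
            raise ValueError(
                f"only {len(common)} probes overlap the reference panel (need >= 20)"
            )
        A = self.panel.profiles[common].to_numpy().T  # probes x types
        contrast = np.abs(A - A.mean(axis=1, keepdims=True)).max()
        if contrast < 0.01:
            raise ValueError("reference profiles are indistinguishable; mixture not identifiable")
        k = A.shape[1]
        Y = beta.select_probes(common).values.to_numpy(dtype=float)
        props = np.zeros((Y.shape[0], k))
        resid = np.zeros(Y.shape[0])
        paths: list[list[float]] = []
        for i in range(Y.shape[0]):
            x = Y[i]
            ok = ~np.isnan(x)
            Ai, xi = A[ok], x[ok]
            L = np.linalg.eigvalsh(Ai.T @ Ai).max()
            w = np.full(k, 1.0 / k)
            path = []
            for _ in range(self.max_iter):
                grad = Ai.T @ (Ai @ w - xi)
                w_new = _project_simplex(w - grad / L)
                if record_path:
                    path.append(float(np.linalg.norm(Ai @ w_new - xi)))
                if np.abs(w_new - w).max() < self.tol:
                    w = w_new
                    break
                w = w_new
            props[i] = w
            resid[i] = float(np.linalg.norm(Ai @ w - xi))
            if record_path:
                paths.append(path)
        self.proportions_ = pd.DataFrame(
            props, index=beta.sample_ids, columns=self.panel.cell_types
        )
        self.residual_norm_ = pd.Series(resid, index=beta.sample_ids)
        if record_path:
            self.residual_path_ = paths
        return self

    def results(self) -> CellProportions:
        return CellProportions(self.proportions_, self.residual_norm_)


def estimate_cell_props(beta: BetaMatrix, panel: ReferencePanel, **kw) -> CellProportions:
    """Functional wrapper over :class:`CellTypeDeconvolution`."""
    return CellTypeDeconvolution(panel, **kw).fit(beta).results()


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    """Per-stage accounting of the filtering chain."""

    stages: list[dict] = field(default_factory=list)
    error_sd: float | None = None
    sd_threshold_used: float | None = None
    retained_probes: list[str] = field(default_factory=list)
    age_excluded: list[str] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})
        log.info("preprocess stage %-18s %s", stage, info)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "error_sd": self.error_sd,
            "sd_threshold_used": self.sd_threshold_used,
            "n_retained": len(self.retained_probes),
            "n_age_excluded": len(self.age_excluded),
        }


def preprocess_cohort(
    beta: BetaMatrix,
    sheet: SampleSheet,
    config: RunConfig,
    *,
    cross_hybridizing: set[str] = frozenset(),
    age_probe_list: set[str] = frozenset(),
    age_screen: bool = False,
    sd_threshold: float | None = None,
    replicates: ReplicatePairs | None = None,
) -> tuple[BetaMatrix, PreprocessReport]:
    """Run the full QC chain on one cohort.

    ``sd_threshold`` overrides the config value (the pipeline passes the max
    of the per-cohort replicate-error estimates); ``age_screen`` adds the
    a-priori age probe list plus the regression screen (longitudinal cohort).
    """
    rep = PreprocessReport()
    n0s, n0p = beta.n_samples, beta.n_probes

    beta = mask_detection(beta, config.detect_p_max)
    rep.add("mask_detection", p_max=config.detect_p_max)

    beta, rm_samples = filter_missing(beta, config.max_missing_rate, "samples")
    rep.add("filter_samples", removed=len(rm_samples), ids=rm_samples)
    beta, rm_probes = filter_missing(beta, config.max_missing_rate, "probes")
    rep.add("filter_probes_missing", removed=len(rm_probes))

    drop_xhyb = [p for p in beta.probe_ids if p in cross_hybridizing]
    if drop_xhyb:
        beta = beta.select_probes([p for p in beta.probe_ids if p not in set(drop_xhyb)])
    rep.add("filter_cross_hybridizing", removed=len(drop_xhyb))

    if "batch" in sheet.data.columns and sheet.data["batch"].notna().all():
        batch = sheet.data["batch"].reindex(beta.sample_ids)
        if batch.nunique() > 1:
            beta = adjust_batch(beta, batch)
            rep.add("adjust_batch", n_batches=int(batch.nunique()))
        else:
            rep.add("adjust_batch", skipped="single batch")
    else:
        rep.add("adjust_batch", skipped="no batch labels")

    if replicates is not None:
        rep.error_sd = estimate_error_sd(replicates)
        rep.add("estimate_error_sd", error_sd=rep.error_sd)
    thr = sd_threshold if sd_threshold is not None else config.sd_threshold
    rep.sd_threshold_used = thr
    retained = sd_filter(beta, thr)
    dropped = beta.n_probes - len(retained)
    beta = beta.select_probes(retained)
    rep.add("sd_filter", threshold=thr, removed=dropped, retained=len(retained))

    if age_screen:
        prior = [p for p in beta.probe_ids if p in age_probe_list]
        screened = screen_age_probes(beta, sheet, config.age_screen_p)
        excluded = set(prior) | screened
        rep.age_excluded = sorted(excluded)
        beta = beta.select_probes([p for p in beta.probe_ids if p not in excluded])
        rep.add(
            "age_screen",
            prior_list=len(prior),
            regression_flagged=len(screened),
            removed=len(excluded),
        )

    rep.retained_probes = beta.probe_ids
    rep.add("done", samples=f"{n0s}->{beta.n_samples}", probes=f"{n0p}->{beta.n_probes}")
    return beta, rep
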