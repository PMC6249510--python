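"""Multivariate methylation-behavior association via Infomax ICA.

Each modality matrix X (samples x features) is decomposed as X = A S: the
mixing/loading matrix A (samples x components) carries each participant's
expression of a component, the source matrix S (components x features)
carries each feature's contribution.  Cross-modality association is tested
between loading columns with Bonferroni control over all component pairs;
contributors of an associated pair are the features beyond |z| > 1.5 on the
standardized source scores.

Component number is chosen by a resampling stability criterion: repeated
ICA fits under random restarts and bootstrap resampling of features are
clustered by absolute source correlation, and a candidate order is stable
when every cluster is compact and distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from ._linalg import ols_by_pattern, race_dummies
from .io_config import BetaMatrix, SampleSheet

log = logging.getLogger("oppomark")


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------


def residualize(
    beta: BetaMatrix | pd.DataFrame,
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("age", "sex", "race"),
) -> pd.DataFrame:
    """Per-probe OLS residuals after removing demographic covariates.

    Returns a complete samples x probes matrix of mean-zero residuals;
    samples with any missing value at the kept probes are dropped so the
    downstream decomposition sees a dense matrix.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else pd.DataFrame(beta)
    complete = values.dropna(axis=0)
    d = sheet.data.loc[complete.index]
    cols = [np.ones(len(d))]
    names = ["intercept"]
    if "age" in covariates:
        cols.append(d["age"].to_numpy(dtype=float))
        names.append("age")
    if "sex" in covariates:
        cols.append((d["sex"] == "M").to_numpy(dtype=float))
        names.append("sex[M]")
    if "race" in covariates:
        R, rnames, _ = race_dummies(d["race"])
        for j in range(R.shape[1]):
            cols.append(R[:, j])
        names += rnames
    X = np.column_stack(cols)
    fit = ols_by_pattern(complete.to_numpy(dtype=float), X, names=names)
    return pd.DataFrame(fit.resid, index=complete.index, columns=complete.columns)


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------


@dataclass
class IcaModel:
    """Fitted decomposition X ~ A S in the whitened k-dimensional subspace."""

    mixing: pd.DataFrame     # samples x k loadings (A)
    sources: pd.DataFrame    # k x features scores (S)
    unmixing: np.ndarray     # k x samples, applied to the centered data
    converged: bool
    n_iter: int
    seed: int | None
    k: int


class InfomaxICA(BaseEstimator):
    """Natural-gradient Infomax ICA with the logistic nonlinearity.

    The decomposition is X = A S with X (n samples x p features), loadings
    A (n x k) and source scores S (k x p).  The samples are the statistical
    observations: the feature covariance is whitened by PCA to exactly
    ``n_components`` dimensions (square ICA in whitened space), and the
    loading columns are the maximally independent, non-Gaussian sequences
    over samples.  The unmixing matrix is iterated with natural-gradient
    ascent of the information-maximization objective,
    ``W <- W + lr (I + (1 - 2 y) u^T / n) W`` with ``y = sigmoid(W z)``,
    until the update falls below ``tol`` or ``max_iter`` is reached; the
    learning rate halves whenever an update blows up.  Each component's
    sign is fixed so its largest-|score| feature is positive.
    Deterministic for a fixed ``random_state``.
    """

    def __init__(
        self,
        n_components: int = 2,
        random_state: int | None = 0,
        max_iter: int = 10000,
        tol: float = 1e-7,
        learning_rate: float = 0.1,
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.learning_rate = learning_rate

    def fit(self, X, y=None) -> "InfomaxICA":
        X = pd.DataFrame(X)
        sample_ids, feature_ids = list(X.index), list(X.columns)
        M = X.to_numpy(dtype=float)
        if not np.isfinite(M).all():
            raise ValueError("ICA input must be finite")
        n, p = M.shape
        k = self.n_components
        if k < 1 or k > min(n, p):
            raise ValueError(f"n_components={k} out of range for {n}x{p} data")
        self.mean_ = M.mean(axis=0)  # per-feature mean
        Mc = M - self.mean_[None, :]
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
        if k > rank:
            raise ValueError(f"n_components={k} exceeds data rank {rank}")
        K = np.sqrt(n) * (Vt[:k].T / s[:k]).T  # k x p whitening of the feature space
        Z = K @ Mc.T                            # k x n, identity covariance over samples

        rng = np.random.default_rng(self.random_state)
        Wq, _ = np.linalg.qr(rng.standard_normal((k, k)))
        W = Wq
        lr = self.learning_rate
        eye = np.eye(k)
        converged = False
        it = 0
        from scipy.special import expit

        for it in range(1, self.max_iter + 1):
            Us = W @ Z
            Y = expit(Us)
            G = (eye + (1.0 - 2.0 * Y) @ Us.T / n) @ W
            step = lr * G
            if not np.isfinite(step).all() or np.abs(step).max() > 1e6:
                lr *= 0.5
                if lr < 1e-12:
                    break
                continue
            W = W + step
            if np.abs(step).max() < self.tol:
                converged = True
                break
            # anneal: a fixed natural-gradient step can orbit the optimum;
            # shrinking it turns the orbit into convergence
            if it % 500 == 0:
                lr *= 0.8
        if not converged:
            log.warning("Infomax ICA did not converge in %d iterations", it)

        T = W @ K                     # k x p: loadings_i = T (x_i - mean)
        A = Mc @ T.T                  # n x k independent loading sequences
        S = np.linalg.pinv(A) @ Mc    # k x p source scores (X ~ A S)
        # sign convention: largest-|score| feature of each component positive
        for j in range(k):
            i = np.argmax(np.abs(S[j]))
            if S[j, i] < 0:
                S[j] = -S[j]
                A[:, j] = -A[:, j]
                T[j] = -T[j]
        comp_names = [f"IC{j + 1}" for j in range(k)]
        self.mixing_ = pd.DataFrame(A, index=sample_ids, columns=comp_names)
        self.sources_ = pd.DataFrame(S, index=comp_names, columns=feature_ids)
        self.unmixing_ = T
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def transform(self, X) -> np.ndarray:
        """Loadings of new samples on the fitted components."""
        M = pd.DataFrame(X).to_numpy(dtype=float)
        return (M - self.mean_[None, :]) @ self.unmixing_.T

    def model(self) -> IcaModel:
        return IcaModel(
            mixing=self.mixing_,
            sources=self.sources_,
            unmixing=self.unmixing_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            seed=self.random_state,
            k=self.n_components,
        )


def infomax_ica(
    X, k: int, seed: int | None = 0, max_iter: int = 10000, tol: float = 1e-7
) -> IcaModel:
    """Functional wrapper over :class:`InfomaxICA`."""
    return InfomaxICA(k, random_state=seed, max_iter=max_iter, tol=tol).fit(X).model()


# ---------------------------------------------------------------------------
# stability-based order selection
# ---------------------------------------------------------------------------


@dataclass
class StabilityProfile:
    chosen_k: int
    table: pd.DataFrame      # per candidate: mean/min cluster index
    per_cluster: dict[int, list[float]]
    all_stable: bool


def stability_select(
    X,
    k_candidates,
    n_restarts: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.5,
    max_iter: int = 5000,
) -> StabilityProfile:
    """Choose the component number by resampling stability.

    For each candidate order the decomposition is refit ``n_restarts`` times
    under random restarts and bootstrap resampling of the sample
    observations; the pooled components (loading sequences evaluated on the
    original samples) are clustered by absolute correlation and each cluster
    scored as (mean within-cluster |r|) minus (mean between-cluster |r|).
    The chosen order is the largest candidate whose worst cluster stays
    above ``stability_threshold`` — under-fitting is always reproducible, so
    stability must hold at every component before a larger order is
    credited.  If no candidate qualifies, the smallest is returned with a
    warning.
    """
    if n_restarts < 5:
        raise ValueError("need at least 5 restarts for a meaningful stability index")
    X = pd.DataFrame(X)
    M = X.to_numpy(dtype=float)
    n, p = M.shape
    rng = np.random.default_rng(seed)
    candidates = sorted(int(k) for k in k_candidates)
    rank = np.linalg.matrix_rank(M - M.mean(axis=0, keepdims=True))
    candidates = [k for k in candidates if 1 <= k <= rank]
    if not candidates:
        raise ValueError("no feasible candidate orders")

    rows = []
    per_cluster: dict[int, list[float]] = {}
    for k in candidates:
        comps = []
        for _ in range(n_restarts):
            # bootstrap the sample observations; retry degenerate draws
            for _try in range(50):
                idx = rng.integers(0, n, size=n)
                sub = M[idx]
                subc = sub - sub.mean(axis=0, keepdims=True)
                if np.linalg.matrix_rank(subc) >= k:
                    break
            else:
                continue
            ica = InfomaxICA(
                k,
                random_state=int(rng.integers(0, 2**31 - 1)),
                max_iter=max_iter,
            ).fit(sub)
            # loading sequences evaluated on the original samples
            A_full = (M - ica.mean_[None, :]) @ ica.unmixing_.T
            comps.append(A_full.T)
        if len(comps) < 5:
            per_cluster[k] = [0.0]
            rows.append({"k": k, "mean_index": 0.0, "min_index": 0.0})
            continue
        C = np.vstack(comps)  # (<= n_restarts*k) x n
        R = np.abs(np.corrcoef(C))
        np.fill_diagonal(R, 1.0)
        if k == 1:
            indices = [float(R[np.triu_indices(len(C), 1)].mean())]
        else:
            D = squareform(1.0 - R, checks=False)
            labels = fcluster(linkage(D, method="average"), t=k, criterion="maxclust")
            indices = []
            for c in np.unique(labels):
                inside = labels == c
                Rin = R[np.ix_(inside, inside)]
                within = (
                    float(Rin[np.triu_indices(inside.sum(), 1)].mean())
                    if inside.sum() > 1
                    else 0.0
                )
                between = float(R[np.ix_(inside, ~inside)].mean()) if (~inside).any() else 0.0
                indices.append(within - between)
        per_cluster[k] = indices
        rows.append({"k": k, "mean_index": float(np.mean(indices)), "min_index": float(np.min(indices))})

    table = pd.DataFrame(rows).set_index("k")
    stable = table.index[table["min_index"] >= stability_threshold]
    if len(stable):
        chosen = int(stable.max())
        all_stable = True
    else:
        chosen = candidates[0]
        all_stable = False
        log.warning(
            "no candidate order is stable (all indices < %.2f); falling back to k=%d",
            stability_threshold,
            chosen,
        )
    return StabilityProfile(chosen_k=chosen, table=table, per_cluster=per_cluster, all_stable=all_stable)


# ---------------------------------------------------------------------------
# loading correlation and contributors
# ---------------------------------------------------------------------------


@dataclass
class FusionResult:
    """Cross-modality loading correlations with multiplicity control."""

    r: pd.DataFrame          # meth components x behavior components
    p: pd.DataFrame
    n: int
    alpha: float
    bonferroni_threshold: float
    significant: list[tuple[str, str]]
    contributors: dict[tuple[str, str], dict[str, pd.Series]] = field(default_factory=dict)
    models: dict[str, IcaModel] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.r.size


def loading_correlation(
    A1: pd.DataFrame, A2: pd.DataFrame, family_alpha: float = 0.05
) -> FusionResult:
    """Pearson correlation of every loading-column pair, Bonferroni over
    all k1*k2 pairs, p-values from the exact t transform with n-2 df."""
    A1, A2 = pd.DataFrame(A1), pd.DataFrame(A2)
    if list(A1.index) != list(A2.index):
        raise ValueError("loading matrices must share samples in the same order")
    n = len(A1)
    if n < 4:
        raise ValueError("need at least 4 samples to correlate loadings")
    k1, k2 = A1.shape[1], A2.shape[1]
    Z1 = (A1 - A1.mean()) / A1.std(ddof=0)
    Z2 = (A2 - A2.mean()) / A2.std(ddof=0)
    Rm = (Z1.to_numpy().T @ Z2.to_numpy()) / n
    Rm = np.clip(Rm, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = Rm * np.sqrt((n - 2) / np.maximum(1.0 - Rm**2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    r = pd.DataFrame(Rm, index=A1.columns, columns=A2.columns)
    p = pd.DataFrame(P, index=A1.columns, columns=A2.columns)
    thr = family_alpha / (k1 * k2)
    sig = [
        (i, j)
        for i in r.index
        for j in r.columns
        if p.loc[i, j] < thr
    ]
    return FusionResult(r=r, p=p, n=n, alpha=family_alpha, bonferroni_threshold=thr, significant=sig)


def top_contributors(
    scores: pd.Series, z_threshold: float = 1.5
) -> pd.Series:
    """Features whose standardized source score exceeds |z_threshold|.

    Scores are standardized to mean 0, SD 1; the signed z-scores of the
    features beyond the cut are returned, strongest first.
    """
    s = pd.Series(scores, dtype=float)
    sd = s.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance source scores")
    z = (s - s.mean()) / sd
    out = z[np.abs(z) > z_threshold]
    if out.empty:
        log.warning("no contributor exceeds |z| > %.2f", z_threshold)
    return out.reindex(out.abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# the composed fusion analysis
# ---------------------------------------------------------------------------


def plot_fusion(result: FusionResult, path, pair: tuple[str, str] | None = None) -> None:
    """Three-panel summary of one component pair: loading scatter plus the
    standardized source scores of each modality with the |z| contributor cut.

    Requires matplotlib; plots the most significant pair by default.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pair is None:
        if not result.significant:
            raise ValueError("no significant pair to plot; pass one explicitly")
        pair = min(result.significant, key=lambda ij: result.p.loc[ij])
    i, j = pair
    m1 = result.models["methylation"]
    m2 = result.models["behavior"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].scatter(m1.mixing[i], m2.mixing[j], s=8, alpha=0.6)
    axes[0].set_xlabel(f"methylation {i} loading")
    axes[0].set_ylabel(f"behavior {j} loading")
    axes[0].set_title(f"r = {result.r.loc[pair]:.2f}, p = {result.p.loc[pair]:.2e}")
    for ax, model, comp, label in (
        (axes[1], m2, j, "behavior measures"),
        (axes[2], m1, i, "CpG probes"),
    ):
        s = model.sources.loc[comp]
        z = (s - s.mean()) / s.std(ddof=0)
        ax.bar(range(len(z)), z.to_numpy(), color="steelblue")
        ax.axhline(1.5, ls="--", c="gray")
        ax.axhline(-1.5, ls="--", c="gray")
        ax.set_xticks(range(len(z)))
        ax.set_xticklabels(z.index, rotation=90, fontsize=6)
        ax.set_ylabel(f"{comp} z-score")
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fuse_modalities(
    meth_resid: pd.DataFrame,
    behavior: pd.DataFrame,
    seed: int = 0,
    family_alpha: float = 0.05,
    z_threshold: float = 1.5,
    meth_candidates=None,
    behavior_candidates=None,
    n_restarts: int = 10,
) -> FusionResult:
    """Stability-selected Infomax ICA per modality, then loading correlation.

    ``meth_resid`` is the covariate-residualized marker matrix; ``behavior``
    the raw 13-score matrix (standardized here).  Contributors are extracted
    for every Bonferroni-significant component pair.
    """
    common = [s for s in meth_resid.index if s in behavior.index]
    meth = meth_resid.loc[common]
    behav = pd.DataFrame(behavior).loc[common]
    behav = (behav - behav.mean()) / behav.std(ddof=1)

    p_m = meth.shape[1]
    if meth_candidates is None:
        meth_candidates = range(1, min(6, p_m))
    if behavior_candidates is None:
        behavior_candidates = range(1, min(9, behav.shape[1]))

    prof_m = stability_select(meth, meth_candidates, n_restarts=n_restarts, seed=seed)
    prof_b = stability_select(behav, behavior_candidates, n_restarts=n_restarts, seed=seed + 1)
    log.info("fusion: k_methylation=%d, k_behavior=%d", prof_m.chosen_k, prof_b.chosen_k)

    m1 = infomax_ica(meth, prof_m.chosen_k, seed=seed + 2)
    m2 = infomax_ica(behav, prof_b.chosen_k, seed=seed + 3)
    res = loading_correlation(m1.mixing, m2.mixing, family_alpha)
    res.models = {"methylation": m1, "behavior": m2}
    for i, j in res.significant:
        res.contributors[(i, j)] = {
            "probes": top_contributors(m1.sources.loc[i], z_threshold),
            "measures": top_contributors(m2.sources.loc[j], z_threshold),
        }
    return res
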