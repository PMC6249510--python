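"""Synthetic three-cohort methylation study with a known ground truth.

The generator emulates the statistical structure the analysis chain assumes:
27K-style probe ids, a paired longitudinal exercise cohort, an age/sex-matched
case-control drinking cohort, a behavioral drinking cohort with 13 mutually
correlated scores, technical replicate pairs for error estimation, cell-type
mixtures from a small reference panel, and planted per-probe effects of the
classes the marker analysis must distinguish (exercise-only, drinking-only,
overlapping concordant, overlapping opposite, age-driven, batch-driven).

The noise model is additive Gaussian on the beta scale with clipping to
[0, 1]; the clipping rate is logged and stored in ``values.attrs``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import BEHAVIOR_MEASURES, RACE_LEVELS, BetaMatrix, SampleSheet

log = logging.getLogger("oppomark")

PROBE_CLASSES = (
    "null",
    "exercise_only",
    "drinking_only",
    "overlap_concordant",
    "overlap_opposite",
    "age_driven",
    "batch_driven",
)

# Table-1-style demographics used as sampling frequencies.
_EXERCISE_RACE_N = (35, 2, 7, 6, 3, 0)
_DRINKER_RACE_N = (40, 1, 0, 23, 3, 14)
_CONTROL_RACE_N = (36, 3, 23, 7, 0, 12)
_BINGE_RACE_N = (128, 6, 2, 72, 17, 56)

# measure -> latent factor block (instrument-wise)
_MEASURE_FACTOR = {m: (0 if m.startswith("ADS") else 1 if m.startswith("AUDIT") else 2)
                   for m in BEHAVIOR_MEASURES}
# fixed raw scales/offsets so the 13 scores have heterogeneous ranges
_MEASURE_SCALE = {
    "ADS-con": (3.0, 5.0), "ADS-obs": (2.5, 4.0), "ADS-per": (2.0, 3.0),
    "ADS-phy": (2.0, 3.5), "ADS-tot": (9.0, 15.0),
    "AUDIT-1": (1.0, 2.5), "AUDIT-2": (1.2, 2.0), "AUDIT-3": (1.1, 2.2),
    "AUDIT-tot": (6.0, 14.0),
    "ICS-total": (8.0, 25.0), "ICS-ac": (3.0, 9.0), "ICS-fc": (4.0, 10.0),
    "ICS-pc": (3.5, 8.0),
}


def _spawn_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePanel:
    """Mean beta profiles of the constituent cell types of the bulk tissue."""

    profiles: pd.DataFrame          # cell types x probes
    discriminating: tuple[str, ...]  # probes with >= 0.2 between-type contrast

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.profiles.columns)


def probe_names(n_probes: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n_probes)]


def gen_reference_panel(
    n_types: int = 2,
    n_probes: int = 2000,
    seed: int = 0,
    discriminating_frac: float = 0.10,
    mid_range_probes=(),
) -> ReferencePanel:
    """Deterministic reference panel with designated discriminating probes.

    Discriminating probes differ between consecutive types by 0.25 beta,
    comfortably above the 0.2 contrast the deconvolution step relies on.
    Probes named in ``mid_range_probes`` get mid-range mean betas — sites
    near full or zero methylation cannot vary between subjects, so the
    variable sites an association analysis targets sit mid-range, away from
    the clipping bounds.
    """
    if n_types < 2:
        raise ValueError("a reference panel needs at least 2 cell types")
    rng = np.random.default_rng(seed)
    probes = probe_names(n_probes)
    base = rng.uniform(0.10, 0.90, size=n_probes)
    if len(mid_range_probes):
        mid = [i for i, p in enumerate(probes) if p in set(mid_range_probes)]
        base[mid] = rng.uniform(0.32, 0.68, size=len(mid))
    profiles = np.tile(base, (n_types, 1))
    n_disc = max(1, int(round(discriminating_frac * n_probes)))
    disc_idx = rng.choice(n_probes, size=n_disc, replace=False)
    for t in range(1, n_types):
        direction = np.where(base[disc_idx] < 0.5, 1.0, -1.0)
        profiles[t, disc_idx] = base[disc_idx] + direction * 0.25 * t / (n_types - 1)
        # mild type-specific jitter elsewhere
        other = np.setdiff1d(np.arange(n_probes), disc_idx)
        profiles[t, other] = np.clip(
            base[other] + rng.normal(0, 0.01, size=other.size), 0.0, 1.0
        )
    profiles = np.clip(profiles, 0.0, 1.0)
    types = [f"type{t + 1}" for t in range(n_types)]
    return ReferencePanel(
        profiles=pd.DataFrame(profiles, index=types, columns=probes),
        discriminating=tuple(probes[i] for i in sorted(disc_idx)),
    )


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------


@dataclass
class TruthManifest:
    """Ground truth of the planted simulation, keyed by probe id.

    ``probe_class`` partitions the probe set into the seven planted classes;
    ``exercise_delta``/``drinking_delta`` are the signed beta shifts; probes
    in ``behavior_link`` covary with the latent drinking-severity factor at
    the stated signed correlation; ``fusion_probes`` additionally share a
    latent factor with ``fusion_measure``.
    """

    probe_class: pd.Series
    exercise_delta: pd.Series
    drinking_delta: pd.Series
    subject_sd: pd.Series
    age_slope: pd.Series
    batch_offset: pd.Series
    behavior_link: pd.Series
    fusion_probes: tuple[str, ...] = ()
    fusion_measure: str = "ICS-total"
    mixture_alpha: tuple[float, ...] = (8.0, 2.0)

    def __post_init__(self) -> None:
        opp = self.probes_of("overlap_opposite")
        ed = self.exercise_delta[opp]
        dd = self.drinking_delta[opp]
        if len(opp) and not (
            (np.sign(ed) == -np.sign(dd)).all() and (ed != 0).all() and (dd != 0).all()
        ):
            raise ValueError("overlap_opposite probes must have opposing non-zero deltas")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probe_class.index)

    def probes_of(self, cls: str) -> list[str]:
        if cls not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {cls!r}")
        return list(self.probe_class.index[self.probe_class == cls])

    @property
    def drinking_affected(self) -> list[str]:
        m = self.probe_class.isin(["drinking_only", "overlap_concordant", "overlap_opposite"])
        return list(self.probe_class.index[m])

    @property
    def exercise_affected(self) -> list[str]:
        m = self.probe_class.isin(["exercise_only", "overlap_concordant", "overlap_opposite"])
        return list(self.probe_class.index[m])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probe_class": self.probe_class.to_dict(),
            "exercise_delta": self.exercise_delta.to_dict(),
            "drinking_delta": self.drinking_delta.to_dict(),
            "subject_sd": self.subject_sd.to_dict(),
            "age_slope": self.age_slope.to_dict(),
            "batch_offset": self.batch_offset.to_dict(),
            "behavior_link": self.behavior_link.to_dict(),
            "fusion_probes": list(self.fusion_probes),
            "fusion_measure": self.fusion_measure,
            "mixture_alpha": list(self.mixture_alpha),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        series = {
            k: pd.Series(raw[k])
            for k in (
                "probe_class",
                "exercise_delta",
                "drinking_delta",
                "subject_sd",
                "age_slope",
                "batch_offset",
                "behavior_link",
            )
        }
        return cls(
            **series,
            fusion_probes=tuple(raw["fusion_probes"]),
            fusion_measure=raw["fusion_measure"],
            mixture_alpha=tuple(raw["mixture_alpha"]),
        )


def make_manifest(
    n_probes: int = 2000,
    seed: int = 0,
    n_exercise_only: int = 40,
    n_drinking_only: int = 40,
    n_overlap_concordant: int = 8,
    n_overlap_opposite: int = 15,
    n_opposite_drinker_hypo: int = 9,
    n_age_driven: int = 30,
    n_batch_driven: int = 30,
    delta_beta: float = 0.08,
    subject_sd_variable: float = 0.04,
    subject_sd_stable: float = 0.02,
    variable_frac: float = 0.60,
    age_slope: float = 0.004,
    batch_offset: float = 0.05,
    behavior_link_r: float = 0.25,
    n_fusion_probes: int = 2,
) -> TruthManifest:
    """Plant per-probe effect classes on a fresh probe set.

    The default planted |delta beta| of 0.08 exceeds the 0.06 replicate-error
    SD retention threshold, so planted probes survive variance filtering.
    Among the opposite-class probes, ``n_opposite_drinker_hypo`` are
    hypomethylated in drinkers (and hypermethylated after exercise).
    """
    rng = np.random.default_rng(seed)
    probes = probe_names(n_probes)
    order = rng.permutation(n_probes)
    counts = {
        "exercise_only": n_exercise_only,
        "drinking_only": n_drinking_only,
        "overlap_concordant": n_overlap_concordant,
        "overlap_opposite": n_overlap_opposite,
        "age_driven": n_age_driven,
        "batch_driven": n_batch_driven,
    }
    if sum(counts.values()) > n_probes:
        raise ValueError("planted classes exceed the probe set")
    cls = pd.Series("null", index=probes, dtype=object)
    pos = 0
    for name, k in counts.items():
        cls.iloc[order[pos : pos + k]] = name
        pos += k

    ed = pd.Series(0.0, index=probes)
    dd = pd.Series(0.0, index=probes)
    for p in cls.index[cls == "exercise_only"]:
        ed[p] = delta_beta * rng.choice([-1.0, 1.0])
    for p in cls.index[cls == "drinking_only"]:
        dd[p] = delta_beta * rng.choice([-1.0, 1.0])
    for p in cls.index[cls == "overlap_concordant"]:
        s = rng.choice([-1.0, 1.0])
        ed[p] = s * delta_beta
        dd[p] = s * delta_beta
    opp = list(cls.index[cls == "overlap_opposite"])
    for i, p in enumerate(opp):
        drink_sign = -1.0 if i < n_opposite_drinker_hypo else 1.0
        dd[p] = drink_sign * delta_beta
        ed[p] = -drink_sign * delta_beta

    subject_sd = pd.Series(
        np.where(rng.random(n_probes) < variable_frac, subject_sd_variable, subject_sd_stable),
        index=probes,
    )
    planted = cls != "null"
    subject_sd[planted] = subject_sd_variable

    slope = pd.Series(0.0, index=probes)
    slope[cls == "age_driven"] = age_slope * rng.choice([-1.0, 1.0], size=(cls == "age_driven").sum())
    boff = pd.Series(0.0, index=probes)
    boff[cls == "batch_driven"] = batch_offset

    link = pd.Series(0.0, index=probes)
    drink_probes = cls.index[cls.isin(["drinking_only", "overlap_concordant", "overlap_opposite"])]
    link[drink_probes] = behavior_link_r * np.sign(dd[drink_probes])

    hypo_opp = [p for p in opp if dd[p] < 0]
    fusion = tuple(hypo_opp[:n_fusion_probes])
    # fusion probes covary with behavior only through the dedicated latent,
    # so the planted multivariate pattern is distinct from the severity link
    link[list(fusion)] = 0.0
    return TruthManifest(
        probe_class=cls,
        exercise_delta=ed,
        drinking_delta=dd,
        subject_sd=subject_sd,
        age_slope=slope,
        batch_offset=boff,
        behavior_link=link,
        fusion_probes=fusion,
    )


def null_manifest(n_probes: int = 2000, seed: int = 0, **kw) -> TruthManifest:
    """A manifest with no planted effects (for calibration studies)."""
    return make_manifest(
        n_probes=n_probes,
        seed=seed,
        n_exercise_only=0,
        n_drinking_only=0,
        n_overlap_concordant=0,
        n_overlap_opposite=0,
        n_opposite_drinker_hypo=0,
        n_age_driven=0,
        n_batch_driven=0,
        n_fusion_probes=0,
        **kw,
    )


# ---------------------------------------------------------------------------
# shared sample machinery
# ---------------------------------------------------------------------------


def _clip_report(arr: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    clipped = float(np.mean((arr < 0) | (arr > 1)))
    if clipped > 0.10:
        log.warning("%s: clipping rate %.1f%% exceeds 10%%", what, 100 * clipped)
    elif clipped > 0:
        log.info("%s: clipping rate %.2f%%", what, 100 * clipped)
    return np.clip(arr, 0.0, 1.0), clipped


def _sample_truth(
    n: int, manifest: TruthManifest, panel: ReferencePanel, rng: np.random.Generator
):
    """Per-sample noiseless profiles: cell mixture plus subject-level effect."""
    probes = manifest.probe_ids
    P = panel.profiles[probes].to_numpy()
    W = rng.dirichlet(manifest.mixture_alpha, size=n)
    base = W @ P
    subj = rng.normal(0.0, manifest.subject_sd.to_numpy()[None, :], size=base.shape)
    return base + subj, W


def _detection_p(shape, rng, frac_bad=0.003):
    p = rng.uniform(0.0, 0.04, size=shape)
    bad = rng.random(shape) < frac_bad
    p[bad] = rng.uniform(0.051, 1.0, size=int(bad.sum()))
    return p


def _ages(rng, n, mean, sd, lo, hi):
    return np.clip(np.round(rng.normal(mean, sd, size=n)).astype(int), lo, hi)


def _races(rng, n, freq_counts):
    p = np.asarray(freq_counts, dtype=float)
    return rng.choice(np.array(RACE_LEVELS, dtype=object), size=n, p=p / p.sum())


def _sexes(rng, n, n_female):
    v = np.array(["F"] * n_female + ["M"] * (n - n_female), dtype=object)
    rng.shuffle(v)
    return v


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------


def gen_exercise_cohort(
    n_subjects: int = 53,
    manifest: TruthManifest | None = None,
    panel: ReferencePanel | None = None,
    noise_sd: float = 0.045,
    seed: int = 0,
    n_vo2_increased: int = 29,
    with_detection_p: bool = True,
) -> tuple[BetaMatrix, SampleSheet]:
    """Paired baseline/follow-up cohort with planted exercise shifts.

    Follow-up values at exercise-affected probes are shifted by the
    manifest's signed delta; both timepoints share each subject's biological
    profile so paired differences isolate the shift plus measurement noise.
    """
    if manifest is None:
        manifest = make_manifest(seed=seed)
    if panel is None:
        planted = manifest.probe_class.index[manifest.probe_class != "null"]
        panel = gen_reference_panel(
            n_probes=len(manifest.probe_ids), seed=seed, mid_range_probes=tuple(planted)
        )
    rng = _spawn_rng(seed, 1)
    probes = manifest.probe_ids
    truth, _ = _sample_truth(n_subjects, manifest, panel, rng)

    ages = _ages(rng, n_subjects, 28.45, 7.94, 18, 44)
    age_eff = np.outer(ages - 30.0, manifest.age_slope.to_numpy())
    batches = np.array(["B1", "B2"])[np.arange(n_subjects) % 2]
    batch_eff = np.outer(batches == "B2", manifest.batch_offset.to_numpy())
    truth = truth + age_eff + batch_eff

    delta = manifest.exercise_delta.to_numpy()
    baseline = truth + rng.normal(0, noise_sd, truth.shape)
    followup = truth + delta[None, :] + rng.normal(0, noise_sd, truth.shape)

    values = np.vstack([baseline, followup])
    values, clip_rate = _clip_report(values, "exercise cohort")

    subj_ids = [f"EXS{i:03d}" for i in range(n_subjects)]
    sample_ids = [f"{s}_T0" for s in subj_ids] + [f"{s}_T1" for s in subj_ids]
    vals = pd.DataFrame(values, index=sample_ids, columns=probes)
    vals.attrs["clip_rate"] = clip_rate
    det = (
        pd.DataFrame(_detection_p(values.shape, rng), index=sample_ids, columns=probes)
        if with_detection_p
        else None
    )
    beta = BetaMatrix(vals, det)

    vo2 = np.zeros(n_subjects, dtype=bool)
    vo2[rng.choice(n_subjects, size=min(n_vo2_increased, n_subjects), replace=False)] = True
    half = dict(
        subject_id=subj_ids * 2,
        cohort="exercise",
        timepoint=["baseline"] * n_subjects + ["followup"] * n_subjects,
        group=None,
        age=np.concatenate([ages, ages]),
        sex=np.concatenate([(s := _sexes(rng, n_subjects, min(42, n_subjects))), s]),
        race=np.concatenate([(r := _races(rng, n_subjects, _EXERCISE_RACE_N)), r]),
        batch=np.concatenate([batches, batches]),
        vo2_increased=np.concatenate([vo2, vo2]),
    )
    sheet = SampleSheet(pd.DataFrame(half, index=pd.Index(sample_ids, name="sample_id")))
    return beta, sheet


@dataclass
class RaceConfound:
    """Optional race-driven structure for the case-control generator."""

    drinker_freqs: tuple[int, ...] = _DRINKER_RACE_N
    control_freqs: tuple[int, ...] = _CONTROL_RACE_N
    effect_probes: tuple[str, ...] = ()
    effect_size: float = 0.08
    effect_level: str = "Asian American"


def gen_casecontrol_cohort(
    n_per_group: int = 81,
    manifest: TruthManifest | None = None,
    panel: ReferencePanel | None = None,
    race_confound: RaceConfound | None = None,
    noise_sd: float = 0.06,
    seed: int = 0,
    with_detection_p: bool = True,
) -> tuple[BetaMatrix, SampleSheet]:
    """Age/sex-matched drinkers vs controls with planted drinking shifts.

    Age and sex vectors are shared between the groups (exact matching);
    races are drawn from group-specific frequencies mirroring the imbalance
    the covariate adjustment must absorb.  Probes listed in
    ``race_confound.effect_probes`` shift with race membership, not group.
    """
    if manifest is None:
        manifest = make_manifest(seed=seed)
    if panel is None:
        planted = manifest.probe_class.index[manifest.probe_class != "null"]
        panel = gen_reference_panel(
            n_probes=len(manifest.probe_ids), seed=seed, mid_range_probes=tuple(planted)
        )
    if race_confound is None:
        race_confound = RaceConfound()
    rng = _spawn_rng(seed, 2)
    probes = manifest.probe_ids
    n = 2 * n_per_group
    truth, _ = _sample_truth(n, manifest, panel, rng)

    group = np.array(["control"] * n_per_group + ["drinker"] * n_per_group, dtype=object)
    ages_half = _ages(rng, n_per_group, 32.0, 10.5, 20, 56)
    ages = np.concatenate([ages_half, ages_half])  # matched in age
    sex_half = _sexes(rng, n_per_group, min(53, n_per_group))
    sexes = np.concatenate([sex_half, sex_half])  # matched in sex
    races = np.concatenate(
        [
            _races(rng, n_per_group, race_confound.control_freqs),
            _races(rng, n_per_group, race_confound.drinker_freqs),
        ]
    )
    batches = np.array(["B1", "B2"])[np.arange(n) % 2]

    truth = truth + np.outer(ages - 32.0, manifest.age_slope.to_numpy())
    truth = truth + np.outer(batches == "B2", manifest.batch_offset.to_numpy())
    truth = truth + np.outer(group == "drinker", manifest.drinking_delta.to_numpy())
    if race_confound.effect_probes:
        idx = [probes.index(p) for p in race_confound.effect_probes]
        hit = (races == race_confound.effect_level).astype(float)
        for j in idx:
            truth[:, j] += hit * race_confound.effect_size

    values = truth + rng.normal(0, noise_sd, truth.shape)
    values, clip_rate = _clip_report(values, "case-control cohort")
    sample_ids = [f"CC{i:03d}" for i in range(n)]
    vals = pd.DataFrame(values, index=sample_ids, columns=probes)
    vals.attrs["clip_rate"] = clip_rate
    det = (
        pd.DataFrame(_detection_p(values.shape, rng), index=sample_ids, columns=probes)
        if with_detection_p
        else None
    )
    beta = BetaMatrix(vals, det)
    sheet = SampleSheet(
        pd.DataFrame(
            dict(
                subject_id=sample_ids,
                cohort="case_control",
                timepoint=None,
                group=group,
                age=ages,
                sex=sexes,
                race=races,
                batch=batches,
            ),
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return beta, sheet


@dataclass
class BehaviorModel:
    """Latent-factor model generating the 13 mutually correlated scores.

    Three instrument-wise factors (dependence, use, impaired control) with
    inter-factor correlation ``factor_corr`` drive the measures with loading
    ``loading``; drinking-linked probes covary with the standardized mean
    factor ("severity") at the manifest's signed target correlation.  When
    ``linked`` is true an extra latent ties the manifest's fusion probes to
    ``fusion_measure`` for the multivariate association to discover.
    """

    loading: float = 0.8
    factor_corr: float = 0.5
    linked: bool = True
    fusion_measure_strength: float = 1.0
    fusion_probe_r: float = 0.7

    @property
    def target_mean_corr(self) -> float:
        """Analytic mean off-diagonal correlation of the 13 raw scores."""
        l2 = self.loading**2
        within_pairs = sum(
            k * (k - 1) // 2
            for k in pd.Series(_MEASURE_FACTOR).value_counts()
        )
        total_pairs = 13 * 12 // 2
        between_pairs = total_pairs - within_pairs
        return (within_pairs * l2 + between_pairs * l2 * self.factor_corr) / total_pairs


def gen_drinking_cohort(
    n: int = 281,
    manifest: TruthManifest | None = None,
    panel: ReferencePanel | None = None,
    behavior_model: BehaviorModel | None = None,
    noise_sd: float = 0.06,
    seed: int = 0,
    with_detection_p: bool = True,
) -> tuple[BetaMatrix, SampleSheet]:
    """Drinkers-only cohort with complete 13-score behavior vectors."""
    if manifest is None:
        manifest = make_manifest(seed=seed)
    if panel is None:
        planted = manifest.probe_class.index[manifest.probe_class != "null"]
        panel = gen_reference_panel(
            n_probes=len(manifest.probe_ids), seed=seed, mid_range_probes=tuple(planted)
        )
    bm = behavior_model or BehaviorModel()
    rng = _spawn_rng(seed, 3)
    probes = manifest.probe_ids
    truth, _ = _sample_truth(n, manifest, panel, rng)

    ages = _ages(rng, n, 31.8, 9.9, 21, 56)
    sexes = _sexes(rng, n, min(86, n))
    races = _races(rng, n, _BINGE_RACE_N)
    batches = np.array(["B1", "B2"])[np.arange(n) % 2]
    truth = truth + np.outer(ages - 32.0, manifest.age_slope.to_numpy())
    truth = truth + np.outer(batches == "B2", manifest.batch_offset.to_numpy())
    truth = truth + manifest.drinking_delta.to_numpy()[None, :]  # all drinkers

    # latent factors with the configured inter-factor correlation; the
    # factors are heavy-tailed (Laplace), as severity scales are in practice,
    # which also makes the latent structure identifiable to ICA
    C = np.full((3, 3), bm.factor_corr)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    F = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n, 3)) @ L.T
    severity = F.mean(axis=1)
    severity = (severity - severity.mean()) / severity.std()
    g = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=n) if bm.linked else np.zeros(n)

    uniq_sd = np.sqrt(max(1.0 - bm.loading**2, 1e-6))
    scores = {}
    for m in BEHAVIOR_MEASURES:
        z = bm.loading * F[:, _MEASURE_FACTOR[m]] + rng.normal(0, uniq_sd, n)
        if bm.linked and m == manifest.fusion_measure:
            z = z + bm.fusion_measure_strength * g
        scale, offset = _MEASURE_SCALE[m]
        scores[m] = np.round(offset + scale * z, 2)

    values = truth + rng.normal(0, noise_sd, truth.shape)
    # behavior-linked probes: add severity at the signed target correlation
    link = manifest.behavior_link
    linked_probes = [p for p in probes if link[p] != 0]
    if linked_probes:
        idx = [probes.index(p) for p in linked_probes]
        sd_emp = values[:, idx].std(axis=0, ddof=1)
        r = link[linked_probes].to_numpy()
        c = np.abs(r) / np.sqrt(1 - r**2) * sd_emp
        values[:, idx] += np.outer(severity, np.sign(r) * c)
    if bm.linked and manifest.fusion_probes:
        idx = [probes.index(p) for p in manifest.fusion_probes]
        sd_emp = values[:, idx].std(axis=0, ddof=1)
        rf = bm.fusion_probe_r
        c = rf / np.sqrt(1 - rf**2) * sd_emp
        sgn = np.sign(manifest.drinking_delta[list(manifest.fusion_probes)].to_numpy())
        values[:, idx] += np.outer(g, sgn * c)

    values, clip_rate = _clip_report(values, "drinking cohort")
    sample_ids = [f"DR{i:03d}" for i in range(n)]
    vals = pd.DataFrame(values, index=sample_ids, columns=probes)
    vals.attrs["clip_rate"] = clip_rate
    det = (
        pd.DataFrame(_detection_p(values.shape, rng), index=sample_ids, columns=probes)
        if with_detection_p
        else None
    )
    beta = BetaMatrix(vals, det)
    cols = dict(
        subject_id=sample_ids,
        cohort="drinking",
        timepoint=None,
        group="drinker",
        age=ages,
        sex=sexes,
        race=races,
        batch=batches,
    )
    cols.update(scores)
    sheet = SampleSheet(pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id")))
    return beta, sheet


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------


@dataclass
class ReplicatePairs:
    """Two technical measurements of the same underlying samples."""

    first: pd.DataFrame   # replicated samples x probes
    second: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.first.index)

    @property
    def n_pairs(self) -> int:
        return len(self.first)


def gen_replicates(
    beta: BetaMatrix, error_sd: float, n_replicated: int = 10, seed: int = 0
) -> ReplicatePairs:
    """Re-measure randomly chosen samples twice with fresh technical noise.

    The stored beta values are treated as the underlying signal; each of the
    two replicate measurements adds independent Normal(0, error_sd) noise
    (clipped to [0, 1]), so the SD of paired differences is error_sd * sqrt(2).
    """
    if error_sd < 0:
        raise ValueError("error_sd must be non-negative")
    if n_replicated > beta.n_samples:
        raise ValueError("cannot replicate more samples than exist")
    rng = _spawn_rng(seed, 4)
    chosen = sorted(rng.choice(beta.n_samples, size=n_replicated, replace=False))
    ids = [beta.sample_ids[i] for i in chosen]
    signal = beta.values.loc[ids].to_numpy()
    first = np.clip(signal + rng.normal(0, error_sd, signal.shape), 0, 1) if error_sd else signal.copy()
    second = np.clip(signal + rng.normal(0, error_sd, signal.shape), 0, 1) if error_sd else signal.copy()
    return ReplicatePairs(
        first=pd.DataFrame(first, index=ids, columns=beta.probe_ids),
        second=pd.DataFrame(second, index=ids, columns=beta.probe_ids),
    )


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-level knobs of the synthetic three-cohort simulation."""

    n_probes: int = 2000
    n_exercise_subjects: int = 53
    n_per_group: int = 81
    n_drinkers: int = 281
    delta_beta: float = 0.08
    noise_sd_exercise: float = 0.045
    noise_sd_drinking: float = 0.06
    n_replicated: int = 10
    linked_fusion: bool = True
    null_only: bool = False
    n_cross_hybridizing: int = 20
    n_age_list: int = 25


@dataclass
class SyntheticStudy:
    """All artifacts of one simulated study, plus its ground truth."""

    manifest: TruthManifest
    panel: ReferencePanel
    betas: dict[str, BetaMatrix]
    sheets: dict[str, SampleSheet]
    replicates: dict[str, ReplicatePairs]
    cross_hybridizing: set[str] = field(default_factory=set)
    age_probe_list: set[str] = field(default_factory=set)


def simulate_study(sim: SimConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the three cohorts, replicates, panel and exclusion lists."""
    sim = sim or SimConfig()
    if sim.null_only:
        manifest = null_manifest(n_probes=sim.n_probes, seed=seed)
    else:
        manifest = make_manifest(
            n_probes=sim.n_probes, seed=seed, delta_beta=sim.delta_beta
        )
    planted = manifest.probe_class.index[manifest.probe_class != "null"]
    panel = gen_reference_panel(
        n_probes=sim.n_probes, seed=seed, mid_range_probes=tuple(planted)
    )
    bm = BehaviorModel(linked=sim.linked_fusion and not sim.null_only)

    beta_ex, sheet_ex = gen_exercise_cohort(
        sim.n_exercise_subjects, manifest, panel, sim.noise_sd_exercise, seed
    )
    beta_cc, sheet_cc = gen_casecontrol_cohort(
        sim.n_per_group, manifest, panel, None, sim.noise_sd_drinking, seed
    )
    beta_dr, sheet_dr = gen_drinking_cohort(
        sim.n_drinkers, manifest, panel, bm, sim.noise_sd_drinking, seed
    )

    reps = {
        "exercise": gen_replicates(beta_ex, sim.noise_sd_exercise, sim.n_replicated, seed),
        "case_control": gen_replicates(beta_cc, sim.noise_sd_drinking, sim.n_replicated, seed + 1),
        "drinking": gen_replicates(beta_dr, sim.noise_sd_drinking, sim.n_replicated, seed + 2),
    }

    # a-priori exclusion lists are independent of the planted signal: they are
    # drawn from null and age-driven probes only
    rng = _spawn_rng(seed, 5)
    nulls = manifest.probes_of("null")
    cross_hyb = set(
        rng.choice(nulls, size=min(sim.n_cross_hybridizing, len(nulls)), replace=False)
    )
    age_pool = [p for p in nulls if p not in cross_hyb] + manifest.probes_of("age_driven")
    n_list = min(sim.n_age_list, len(age_pool))
    age_list = set(rng.choice(age_pool, size=n_list, replace=False)) if n_list else set()

    return SyntheticStudy(
        manifest=manifest,
        panel=panel,
        betas={"exercise": beta_ex, "case_control": beta_cc, "drinking": beta_dr},
        sheets={"exercise": sheet_ex, "case_control": sheet_cc, "drinking": sheet_dr},
        replicates=reps,
        cross_hybridizing=cross_hyb,
        age_probe_list=age_list,
    )
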