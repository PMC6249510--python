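"""Data containers, file I/O and run configuration.

Beta matrices travel as wide delimited text with probes as rows and samples
as columns — the 27K-style arrays this package targets are small enough that
plain text is the friendliest interchange format.  Internally the orientation
is samples x probes and missing measurements are a real mask (NaN), never a
sentinel number.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("oppomark")

PROBE_ID_RE = re.compile(r"^cg\d+$")

#: The six self-reported ancestry categories carried by the sample sheets.
RACE_LEVELS = (
    "Caucasian",
    "African American",
    "Asian American",
    "Hispanic",
    "Native",
    "Multiracial",
)

#: The 13 behavioral scores (alcohol-dependence, alcohol-use and
#: impaired-control instruments) tested for methylation associations.
BEHAVIOR_MEASURES = (
    "ADS-con",
    "ADS-obs",
    "ADS-per",
    "ADS-phy",
    "ADS-tot",
    "AUDIT-1",
    "AUDIT-2",
    "AUDIT-3",
    "AUDIT-tot",
    "ICS-total",
    "ICS-ac",
    "ICS-fc",
    "ICS-pc",
)

COHORTS = ("exercise", "case_control", "drinking")


class SchemaError(ValueError):
    """Malformed input file or inconsistent identifiers/shapes."""


class ValidationError(ValueError):
    """A hard violation that makes a run unanalyzable."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Methylation beta values, samples x probes, with explicit missingness.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns are CpG probes; entries in [0, 1] or NaN.
    detection_p : pandas.DataFrame, optional
        Per-measurement detection p-values, same shape and labels.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise SchemaError(f"duplicate probe id {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"beta value {arr[i, j]!r} out of [0, 1] at "
                f"sample {v.index[i]!r}, probe {v.columns[j]!r}"
            )
        if self.detection_p is not None:
            d = self.detection_p
            if d.shape != v.shape or list(d.index) != list(v.index) or list(
                d.columns
            ) != list(v.columns):
                raise SchemaError("detection-p matrix does not match beta matrix")
            darr = d.to_numpy(dtype=float, copy=False)
            with np.errstate(invalid="ignore"):
                if np.nanmin(darr) < 0 or np.nanmax(darr) > 1:
                    raise SchemaError("detection p-values outside [0, 1]")

    # -- basic introspection ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def missing_rate(self, axis: str) -> pd.Series:
        """Fraction missing per ``"samples"`` (rows) or ``"probes"`` (cols)."""
        if axis == "samples":
            return self.values.isna().mean(axis=1)
        if axis == "probes":
            return self.values.isna().mean(axis=0)
        raise ValueError(f"axis must be 'samples' or 'probes', got {axis!r}")

    # -- subsetting ---------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[ids], det)

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        ids = [p for p in probe_ids if p in self.values.columns]
        det = self.detection_p[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values[ids], det)

    def copy(self) -> "BetaMatrix":
        det = self.detection_p.copy() if self.detection_p is not None else None
        return BetaMatrix(self.values.copy(), det)


SHEET_REQUIRED = ("subject_id", "cohort", "age", "sex", "race")


@dataclass
class SampleSheet:
    """Per-sample covariates, group labels, pairing and behavior scores.

    ``data`` is indexed by sample_id and must carry subject_id, cohort, age,
    sex and race; timepoint, group, batch, vo2_increased and the 13 behavior
    columns are optional depending on the cohort.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r} in sample sheet")
        missing = [c for c in SHEET_REQUIRED if c not in d.columns]
        if missing:
            raise SchemaError(f"sample sheet lacks required columns {missing}")
        bad_cohort = set(d["cohort"].dropna()) - set(COHORTS)
        if bad_cohort:
            raise SchemaError(f"unknown cohort labels {sorted(bad_cohort)}")
        bad_race = set(d["race"].dropna()) - set(RACE_LEVELS)
        if bad_race:
            raise SchemaError(f"unknown race labels {sorted(bad_race)}")
        behav = [c for c in d.columns if c in BEHAVIOR_MEASURES]
        if behav and len(behav) != len(BEHAVIOR_MEASURES):
            missing_b = sorted(set(BEHAVIOR_MEASURES) - set(behav))
            raise SchemaError(
                f"behavior block incomplete: missing measures {missing_b}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def has_behavior(self) -> bool:
        return all(c in self.data.columns for c in BEHAVIOR_MEASURES)

    def behavior(self, complete_only: bool = True) -> pd.DataFrame:
        """The 13-score behavior block (optionally complete rows only)."""
        if not self.has_behavior():
            raise SchemaError("sample sheet carries no behavior block")
        b = self.data[list(BEHAVIOR_MEASURES)].astype(float)
        return b.dropna() if complete_only else b

    def select(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)].copy())

    def pairs(self) -> pd.DataFrame:
        """subject_id -> (baseline sample, followup sample) for paired cohorts."""
        d = self.data
        if "timepoint" not in d.columns:
            raise SchemaError("sample sheet has no timepoint column")
        piv = d.reset_index().pivot_table(
            index="subject_id",
            columns="timepoint",
            values=d.index.name or "index",
            aggfunc="first",
        )
        return piv


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every threshold of the analysis chain, with its conventional default.

    detect_p_max : measurements with detection p strictly above this are
        masked as missing.
    max_missing_rate : samples/probes with missing fraction strictly above
        this are dropped.
    sd_threshold : probes must exceed this inter-subject SD to be retained
        (the replicate-error ceiling; per-cohort estimates are pooled by max).
    age_screen_p : uncorrected p below which a probe is considered
        age-driven and excluded from the longitudinal analysis.
    family_alpha : family-wise level for Bonferroni-corrected discovery.
    step2_alpha : uncorrected level of the behavioral verification step.
    pca_variance_target : cumulative variance the behavior PCs must reach.
    z_contrib_threshold : |z| cut for top component contributors.
    """

    detect_p_max: float = 0.05
    max_missing_rate: float = 0.05
    sd_threshold: float = 0.06
    age_screen_p: float = 0.01
    family_alpha: float = 0.05
    step2_alpha: float = 0.05
    pca_variance_target: float = 0.90
    z_contrib_threshold: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detect_p_max",
            "max_missing_rate",
            "age_screen_p",
            "family_alpha",
            "step2_alpha",
        ):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0 < self.pca_variance_target <= 1):
            raise ValueError("pca_variance_target must lie in (0, 1]")
        if self.sd_threshold < 0:
            raise ValueError("sd_threshold must be non-negative")
        if self.z_contrib_threshold < 0:
            raise ValueError("z_contrib_threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)})
        )

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DIALECTS = {"wide_tsv": "\t", "wide_csv": ","}


def _read_wide(path: str | Path, dialect: str, what: str) -> pd.DataFrame:
    sep = _DIALECTS.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=False)
    try:
        df = df.astype(float)
    except ValueError as e:
        raise SchemaError(f"unparseable cell in {what} file {path}: {e}") from e
    return df


def read_beta_matrix(
    path: str | Path,
    dialect: str = "wide_tsv",
    detection_p_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a wide (probes x samples) beta-value text file.

    Values outside [0, 1] raise, naming the offending probe and sample;
    nothing is clipped silently.
    """
    wide = _read_wide(path, dialect, "beta")
    det = None
    if detection_p_path is not None:
        dwide = _read_wide(detection_p_path, dialect, "detection-p")
        det = dwide.T
    return BetaMatrix(wide.T, det)


def write_beta_matrix(
    beta: BetaMatrix,
    path: str | Path,
    dialect: str = "wide_tsv",
    precision: int = 6,
    detection_p_path: str | Path | None = None,
) -> None:
    sep = _DIALECTS[dialect]
    wide = beta.values.T
    wide.to_csv(path, sep=sep, na_rep="NA", float_format=f"%.{precision}f")
    if detection_p_path is not None and beta.detection_p is not None:
        beta.detection_p.T.to_csv(
            detection_p_path, sep=sep, na_rep="NA", float_format=f"%.{precision}f"
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, index_col="sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index_label="sample_id")


def read_probe_list(path: str | Path) -> set[str]:
    """One probe id per line; ``#`` comments and blank lines allowed.

    Duplicates are collapsed with a warning; an empty file yields an empty
    set with a warning.
    """
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    probes = set(lines)
    if len(probes) < len(lines):
        log.warning(
            "probe list %s: %d duplicate lines collapsed", path, len(lines) - len(probes)
        )
    if not probes:
        log.warning("probe list %s is empty", path)
    log.info("probe list %s: %d probes", path, len(probes))
    return probes


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(probes)) + "\n")


# ---------------------------------------------------------------------------
# run validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-cohort bookkeeping produced before any analysis runs."""

    cohort_counts: dict[str, int] = field(default_factory=dict)
    n_analyzable: dict[str, int] = field(default_factory=dict)
    excluded_samples: dict[str, list[str]] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_run(
    config: RunConfig,
    sheets: Mapping[str, SampleSheet],
    betas: Mapping[str, BetaMatrix],
) -> ValidationReport:
    """Cross-check sheets against matrices and the pairing/behavior contracts.

    Hard violations (broken longitudinal pairing, samples absent from the
    beta matrix) raise :class:`ValidationError`.  Samples with incomplete
    behavior blocks in the drinking cohort are flagged for exclusion, not
    fatal — the analyzable count reflects complete records only.

    The function never mutates its inputs.
    """
    report = ValidationReport()
    for cohort, sheet in sheets.items():
        d = sheet.data
        report.cohort_counts[cohort] = len(d)
        n_analyzable = len(d)
        excluded: list[str] = []

        beta = betas.get(cohort)
        if beta is None:
            raise ValidationError(f"no beta matrix provided for cohort {cohort!r}")
        absent = [s for s in d.index if s not in beta.values.index]
        if absent:
            raise ValidationError(
                f"cohort {cohort!r}: samples missing from beta matrix: {absent[:5]}"
            )

        for col in ("age", "sex", "race"):
            n_miss = int(d[col].isna().sum())
            if n_miss:
                report.violations.append(
                    f"{cohort}: {n_miss} samples missing covariate {col!r}"
                )

        if cohort == "exercise":
            counts = d.groupby("subject_id")["timepoint"].nunique()
            bad = counts[counts != 2]
            if len(bad):
                raise ValidationError(
                    "exercise cohort: subjects without both timepoints: "
                    f"{sorted(bad.index.tolist())[:5]}"
                )

        if cohort == "drinking":
            if not sheet.has_behavior():
                raise ValidationError("drinking cohort sheet lacks behavior scores")
            behav = sheet.behavior(complete_only=False)
            incomplete = behav.index[behav.isna().any(axis=1)].tolist()
            excluded.extend(incomplete)
            n_analyzable = len(d) - len(incomplete)
            if incomplete:
                log.info(
                    "drinking cohort: %d samples flagged for exclusion "
                    "(incomplete behavior), %d analyzable",
                    len(incomplete),
                    n_analyzable,
                )

        report.excluded_samples[cohort] = excluded
        report.n_analyzable[cohort] = n_analyzable
    return report
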