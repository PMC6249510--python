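import logging

import numpy as np
import pandas as pd
import pytest

from oppomark.io_config import BEHAVIOR_MEASURES, BetaMatrix, RunConfig, SampleSheet
from oppomark.synth_cohorts import (
    ReferencePanel,
    gen_casecontrol_cohort,
    gen_drinking_cohort,
    gen_exercise_cohort,
    gen_reference_panel,
    make_manifest,
)

logging.getLogger("oppomark").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def manifest_small():
    """A compact planted manifest shared by the slower generator tests."""
    return make_manifest(
        n_probes=400,
        seed=11,
        n_exercise_only=12,
        n_drinking_only=12,
        n_overlap_concordant=4,
        n_overlap_opposite=8,
        n_opposite_drinker_hypo=5,
        n_age_driven=8,
        n_batch_driven=8,
    )


@pytest.fixture(scope="session")
def panel_small(manifest_small):
    planted = manifest_small.probe_class.index[manifest_small.probe_class != "null"]
    return gen_reference_panel(
        n_probes=400, seed=11, mid_range_probes=tuple(planted)
    )


@pytest.fixture(scope="session")
def exercise_small(manifest_small, panel_small):
    return gen_exercise_cohort(30, manifest_small, panel_small, seed=5)


@pytest.fixture(scope="session")
def casecontrol_small(manifest_small, panel_small):
    return gen_casecontrol_cohort(60, manifest_small, panel_small, seed=5)


@pytest.fixture(scope="session")
def drinking_small(manifest_small, panel_small):
    return gen_drinking_cohort(200, manifest_small, panel_small, seed=5)


def simple_beta(values, sample_prefix="S", probe_prefix="cg", detection_p=None):
    """Build a BetaMatrix from a plain array."""
    arr = np.asarray(values, dtype=float)
    idx = [f"{sample_prefix}{i}" for i in range(arr.shape[0])]
    cols = [f"{probe_prefix}{j:08d}" for j in range(arr.shape[1])]
    det = (
        pd.DataFrame(np.asarray(detection_p, dtype=float), index=idx, columns=cols)
        if detection_p is not None
        else None
    )
    return BetaMatrix(pd.DataFrame(arr, index=idx, columns=cols), det)
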