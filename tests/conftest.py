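"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from fmriverse import synth
from fmriverse.multiverse import PipelineSpec

FACTOR_ORDER = (
    "despike", "slice_timing", "normalization", "smoothing_fwhm", "order",
    "highpass", "autocorr", "concat", "basis", "motion",
)

BASE_OPTIONS = dict(
    despike="off", slice_timing="on", normalization="epi_template",
    smoothing_fwhm="8", order="normalize_first", highpass="cutoff_128s",
    autocorr="ar1", concat="on", basis="hrf", motion="m6",
)


def make_pipeline(**overrides) -> PipelineSpec:
    opts = dict(BASE_OPTIONS)
    opts.update({k: str(v) for k, v in overrides.items()})
    return PipelineSpec(tuple((k, opts[k]) for k in FACTOR_ORDER))


@pytest.fixture(scope="session")
def tiny_spec() -> synth.SyntheticSpec:
    """3 subjects, 12x12x8 grid, 2 runs of 60 volumes: fast unit-test scale."""
    return synth.desk_spec(
        n_subjects=3, n_runs=2, n_volumes_per_run=60,
        grid_shape=(12, 12, 8), n_slices=8,
        trial_counts={"go": 6, "stop_success": 3, "stop_fail": 3},
        active_regions=(
            synth.ActiveRegion("r_inferior_frontal", (8, 8, 5), 6.0,
                               {"stop_success": 3.0, "stop_fail": 1.5}),
            synth.ActiveRegion("r_temporal", (8, 3, 3), 6.0,
                               {"stop_success": 3.0, "go": 0.5}),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec) -> synth.Cohort:
    return synth.generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def desk_cohort() -> synth.Cohort:
    """The default 13-subject desk-scale cohort (study conditions)."""
    return synth.generate_cohort(synth.desk_spec(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
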