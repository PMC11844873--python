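"""Shared fixtures.

The heavy end-to-end objects (the n=120 synthetic study and its evaluation
runs) are session-scoped so the acceptance-style tests share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pdprog.cohort import add_total_scores, assemble_features, encode_features
from pdprog.evaluation import CVScheme, ModelSpec, nested_cv_per_combo, permutation_null
from pdprog.synthetic import simulate_study
from pdprog.workflows import WorkflowConfig, run_workflow

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")

STUDY_N = 120
STUDY_SEED = 1


@pytest.fixture(scope="session")
def baseline_study():
    """The shipped synthetic study: n=120, theoretical baseline R2 = 0.5."""
    return simulate_study(n_participants=STUDY_N, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def baseline_features(baseline_study):
    """Truth-parcellation feature matrix and targets at baseline."""
    scored = add_total_scores(baseline_study.cohort)
    base = scored[scored["EVENT_ID"] == "BL"]
    encoded = encode_features(base, "all")
    fm = assemble_features(encoded, baseline_study.imaging["slab6"], "all")
    y = base.set_index("PATNO")["UPDRS_TOT"].astype(float).loc[fm.df.index]
    return fm, y


@pytest.fixture(scope="session")
def baseline_run(baseline_study):
    """Default-workflow report (4 families, truth parcellation, LOO)."""
    config = WorkflowConfig(
        timepoints=("baseline",), parcellations=("slab6",), seed=STUDY_SEED
    )
    return run_workflow(config, baseline_study)


@pytest.fixture(scope="session")
def baseline_null(baseline_features):
    """100-permutation chance-level distribution for the baseline target."""
    fm, y = baseline_features
    return permutation_null(fm, y, n_permutations=100, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def noiseless_result(baseline_study):
    """Elastic-net LOO result when the targets are (almost) pure signal."""
    study = simulate_study(n_participants=STUDY_N, seed=STUDY_SEED, noise_sd=1e-6)
    scored = add_total_scores(study.cohort)
    base = scored[scored["EVENT_ID"] == "BL"]
    encoded = encode_features(base, "all")
    fm = assemble_features(encoded, study.imaging["slab6"], "all")
    y = base.set_index("PATNO")["UPDRS_TOT"].astype(float).loc[fm.df.index]
    return nested_cv_per_combo(fm, y, ModelSpec("elasticnet"), CVScheme(seed=STUDY_SEED),
                               keep_fits=False)


@pytest.fixture(scope="session")
def followup_study():
    """Follow-up study with a dominant baseline-score term (alpha = 0.9)."""
    return simulate_study(
        n_participants=STUDY_N,
        seed=STUDY_SEED + 1,
        alpha_baseline_score=0.9,
        imaging_beta_scale=0.5,
        target_r2_followup=0.7,
    )


@pytest.fixture(scope="session")
def followup_runs(followup_study):
    """Year-1 elastic-net runs with and without the baseline-score feature."""
    full = run_workflow(
        WorkflowConfig(
            timepoints=("year1",),
            parcellations=("slab6",),
            model_families=("elasticnet",),
            seed=STUDY_SEED,
        ),
        followup_study,
    )
    no_baseline = run_workflow(
        WorkflowConfig(
            variant="D2",
            timepoints=("year1",),
            parcellations=("slab6",),
            model_families=("elasticnet",),
            seed=STUDY_SEED,
        ),
        followup_study,
    )
    return full, no_baseline
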