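"""Shared fixtures: toy taxonomies, report files, and the default synthetic
study cohort with its (expensive) cross-validated and leave-one-out results,
computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from necmil.synthetic import SimConfig, simulate_cohort

#: Seed of the default synthetic study cohort used throughout the suite.
STUDY_SEED = 7
#: Seed driving model training / splitting randomness.
RUN_SEED = 1


@pytest.fixture(scope="session")
def study_cohort():
    """The default synthetic cohort (n=120, 5 planted taxa, effect 2.0)."""
    cohort, truth = simulate_cohort(SimConfig(seed=STUDY_SEED))
    return cohort, truth


@pytest.fixture(scope="session")
def cv_results(study_cohort):
    """Five stratified train/test trials on the default cohort."""
    from necmil.pipeline import run_trials

    cohort, _ = study_cohort
    return run_trials(cohort, n_trials=5, seed=RUN_SEED)


@pytest.fixture(scope="session")
def loo_trajectories(study_cohort):
    """Leave-one-patient-out growing-bag risk trajectories (the heavy one)."""
    from necmil.pipeline import loo_risk_pipeline

    cohort, _ = study_cohort
    return loo_risk_pipeline(cohort, seed=RUN_SEED)


@pytest.fixture
def tiny_cohort():
    """A fast small cohort for plumbing tests."""
    cohort, truth = simulate_cohort(
        SimConfig(n_patients=14, n_leaf_taxa=16, samples_min=3, samples_max=5,
                  prevalence=0.4, seed=11)
    )
    return cohort, truth


def make_kraken_report(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def kraken_fixture_lines():
    """A hand-built report: D -> P -> C chain plus a sibling phylum."""
    return [
        " 10.00\t10\t10\tU\t0\tunclassified",
        " 90.00\t90\t5\tD\t2\tBacteria",
        " 60.00\t60\t20\tP\t100\t  Firmicutes",
        " 40.00\t40\t40\tC\t110\t    Bacilli",
        " 25.00\t25\t25\tP\t200\t  Proteobacteria",
    ]
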