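"""End-to-end drivers that keep preprocessing inside the resampling loop.

Feature selection and covariate encoding are supervised (they see labels
and training statistics), so refitting them on each trial's or fold's
training patients — never on held-out ones — is required for honest
held-out metrics.  These drivers wire cohort -> CLR -> selection -> bags
-> MIL -> evaluation with that discipline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from necmil.cohort import Cohort
from necmil.interpret import ImportanceReport, attention_rf_replicate
from necmil.mil import MILConfig, MILParams, predict_bag, train_ensemble, train_mil
from necmil.preprocess import (
    ClrMatrix,
    CovariateEncoder,
    assemble_instances,
    clr_transform,
    fit_feature_selection,
)
from necmil.trajectory import (
    RiskConfig,
    RiskTrajectory,
    growing_bag_trace,
    risk_trajectory,
)

__all__ = ["TrialResult", "build_bags", "run_trials", "loo_risk_pipeline"]


@dataclass
class TrialResult:
    trial: int
    roc_auc: float
    pr_auc: float
    params: MILParams
    bags: list                      # all bags in this trial's feature space
    train_patients: List[str]
    test_patients: List[str]
    selection: object
    scores: np.ndarray
    test_labels: np.ndarray


def build_bags(
    cohort: Cohort,
    train_patients: Sequence[str],
    clr: Optional[ClrMatrix] = None,
    corr_threshold: float = 0.7,
    include_metadata: bool = True,
):
    """Fit selection + encoders on ``train_patients`` and assemble all bags."""
    if clr is None:
        clr = clr_transform(cohort)
    train_set = set(train_patients)
    train_sample_ids = [s.sample_id for s in cohort.samples if s.patient_id in train_set]
    selection = fit_feature_selection(
        cohort.tree, clr, cohort, train_sample_ids, threshold=corr_threshold
    )
    encoder = None
    if include_metadata:
        encoder = CovariateEncoder().fit(cohort.metadata, list(train_patients))
    bags = assemble_instances(clr, selection, cohort, encoder, include_metadata)
    return bags, selection


def run_trials(
    cohort: Cohort,
    n_trials: int = 5,
    seed: int = 0,
    test_fraction: float = 0.2,
    mil_config: Optional[MILConfig] = None,
    corr_threshold: float = 0.7,
    include_metadata: bool = True,
    n_models: int = 3,
) -> Tuple[pd.DataFrame, List[TrialResult]]:
    """Stratified repeated train/test evaluation with per-trial refitting.

    Each trial draws a stratified patient split, refits the feature
    selection and covariate encoders on the training patients only, trains
    the MIL classifier and scores the held-out bags.  Returns per-trial
    ROC/PR AUCs (means and 95% CIs in ``df.attrs``) plus full trial state
    for downstream interpretability.
    """
    from necmil.evaluate import roc_pr

    clr = clr_transform(cohort)
    patients = cohort.patients()
    labels = np.array([cohort.metadata[p].nec_label for p in patients])
    splitter = StratifiedShuffleSplit(n_splits=n_trials, test_size=test_fraction, random_state=seed)
    rows, results = [], []
    for trial, (tr, te) in enumerate(splitter.split(np.zeros(len(patients)), labels)):
        train_patients = [patients[i] for i in tr]
        test_patients = [patients[i] for i in te]
        bags, selection = build_bags(
            cohort, train_patients, clr, corr_threshold, include_metadata
        )
        by_pid = {b.patient_id: b for b in bags}
        train_bags = [by_pid[p] for p in train_patients]
        test_bags = [by_pid[p] for p in test_patients]
        params = train_ensemble(
            train_bags, config=mil_config, seed=seed * 1000 + trial, n_models=n_models
        )
        scores = np.array([predict_bag(b, params).confidence for b in test_bags])
        y_te = np.array([b.label for b in test_bags])
        roc, pr = roc_pr(scores, y_te)
        rows.append({"trial": trial, "roc_auc": roc.auc, "pr_auc": pr.auc})
        results.append(TrialResult(
            trial=trial, roc_auc=roc.auc, pr_auc=pr.auc, params=params, bags=bags,
            train_patients=train_patients, test_patients=test_patients,
            selection=selection, scores=scores, test_labels=y_te,
        ))
    df = pd.DataFrame(rows)
    for col in ("roc_auc", "pr_auc"):
        vals = df[col].to_numpy()
        mean = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        df.attrs[f"{col}_mean"] = mean
        df.attrs[f"{col}_ci95"] = (mean - half, mean + half)
    return df, results


def interpretability_replicates(
    results: Sequence[TrialResult],
    cohort: Cohort,
    ranks: Sequence[str] = ("phylum", "class", "family"),
    seed: int = 0,
    n_trees: int = 500,
) -> List[ImportanceReport]:
    """One attention-guided RF replicate per MIL trial (same splits)."""
    reports = []
    for res in results:
        by_pid = {b.patient_id: b for b in res.bags}
        idx = {p: i for i, p in enumerate(by_pid)}
        bag_list = list(by_pid.values())
        tr = [idx[p] for p in res.train_patients]
        te = [idx[p] for p in res.test_patients]
        reports.append(attention_rf_replicate(
            bag_list, res.params, cohort.tree, tr, te,
            ranks=ranks, replicate_id=res.trial, seed=seed + res.trial, n_trees=n_trees,
        ))
    return reports


def loo_traces(
    cohort: Cohort,
    mil_config: Optional[MILConfig] = None,
    seed: int = 0,
    corr_threshold: float = 0.7,
    include_metadata: bool = True,
    n_models: int = 3,
):
    """Leave-one-patient-out growing-bag traces.

    For every patient: selection and encoders are refitted on the other
    patients' samples, the MIL model is trained on their complete bags,
    and the held-out patient's growing bag is traced.  No model or
    preprocessing step ever saw its evaluation patient.
    """
    clr = clr_transform(cohort)
    patients = cohort.patients()
    traces = []
    for i, pid in enumerate(patients):
        others = [p for p in patients if p != pid]
        bags, _sel = build_bags(cohort, others, clr, corr_threshold, include_metadata)
        by_pid = {b.patient_id: b for b in bags}
        train_bags = [by_pid[p] for p in others]
        params = train_ensemble(
            train_bags, config=mil_config, seed=seed * 10007 + i, n_models=n_models
        )
        traces.append(
            growing_bag_trace(by_pid[pid], params, trained_without=[pid], strict=True)
        )
    return traces


def loo_risk_pipeline(
    cohort: Cohort,
    mil_config: Optional[MILConfig] = None,
    risk_config: Optional[RiskConfig] = None,
    seed: int = 0,
    corr_threshold: float = 0.7,
    include_metadata: bool = True,
    n_models: int = 3,
) -> List[RiskTrajectory]:
    """Leave-one-patient-out risk trajectories (see :func:`loo_traces`)."""
    risk_config = risk_config or RiskConfig()
    traces = loo_traces(cohort, mil_config, seed, corr_threshold, include_metadata, n_models)
    return [risk_trajectory(t, risk_config) for t in traces]
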