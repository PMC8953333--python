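"""Compositional preprocessing and hierarchical feature selection.

Count tables are compositional: only relative abundances carry meaning,
and most entries are zero.  The pipeline here is

1. pseudocount — zeros become 0.66 (two-thirds of the smallest possible
   read count of 1) so logarithms are defined;
2. centered log-ratio (CLR) transform, applied independently *within each
   taxonomic rank* so that sister taxa are normalized against each other;
3. hierarchical pruning — a taxon whose CLR profile has Pearson r > 0.7
   with its parent's is redundant and removed (top-down, children of a
   pruned node are compared against their nearest retained ancestor);
4. information-gain pruning — taxa whose best decision-stump split yields
   zero information gain about the NEC label are removed.

Selection is fitted on training samples only and then applied to the whole
cohort; clinical covariates are encoded with training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from necmil.bags import InstanceVector, PatientBag
from necmil.cohort import CONTINUOUS_COVARIATES, COVARIATE_COLUMNS, ClinicalMetadata, Cohort
from necmil.taxonomy import RANKS, TaxonomyTree

__all__ = [
    "PSEUDOCOUNT",
    "ClrMatrix",
    "FeatureSelection",
    "CovariateEncoder",
    "apply_pseudocount",
    "clr_level",
    "clr_transform",
    "prune_correlated",
    "information_gain",
    "prune_zero_ig",
    "fit_feature_selection",
    "assemble_instances",
]

#: Zero-replacement value: two-thirds of the smallest possible read count (1).
PSEUDOCOUNT = 0.66


def apply_pseudocount(counts: np.ndarray) -> np.ndarray:
    """Replace zeros with :data:`PSEUDOCOUNT`; positive entries pass through."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return np.where(counts == 0, PSEUDOCOUNT, counts)


def clr_level(values: np.ndarray) -> np.ndarray:
    """Centered log-ratio of one composition: log(x_j / geometric_mean(x)).

    Requires strictly positive input (apply the pseudocount first).  The
    output sums to zero.  Accepts a 1-D composition or a 2-D array of
    row compositions.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("clr_level requires strictly positive values")
    logs = np.log(values)
    return logs - logs.mean(axis=-1, keepdims=True)


@dataclass
class ClrMatrix:
    """Samples x taxa CLR values, columns grouped by taxonomic rank."""

    sample_ids: List[str]
    taxids: List[int]
    ranks: List[str]           # rank of each column, aligned with taxids
    values: np.ndarray         # (n_samples, n_taxa)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxids)):
            raise ValueError("ClrMatrix shape mismatch")
        self._col = {t: j for j, t in enumerate(self.taxids)}
        self._row = {s: i for i, s in enumerate(self.sample_ids)}

    def column(self, taxid: int) -> np.ndarray:
        return self.values[:, self._col[taxid]]

    def rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.values[[self._row[s] for s in sample_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxids)


def clr_transform(cohort: Cohort) -> ClrMatrix:
    """Pseudocount + per-rank CLR for every sample in the cohort.

    Columns cover every taxon of the cohort tree, grouped by rank (coarse
    to fine) and sorted by taxid within a rank; taxa missing from a sample
    count as zero before the pseudocount.  A rank with a single taxon gets
    CLR value 0 (the log-ratio of a value to itself).
    """
    tree = cohort.tree
    taxids: List[int] = []
    ranks: List[str] = []
    groups: List[Tuple[int, int]] = []  # (start, stop) column slices per rank
    for rank in RANKS:
        members = sorted(tree.nodes_at_rank(rank))
        if not members:
            continue
        groups.append((len(taxids), len(taxids) + len(members)))
        taxids.extend(members)
        ranks.extend([rank] * len(members))

    col = {t: j for j, t in enumerate(taxids)}
    raw = np.zeros((len(cohort.samples), len(taxids)))
    for i, s in enumerate(cohort.samples):
        for t, c in s.counts.items():
            raw[i, col[t]] = c
    pos = apply_pseudocount(raw)
    out = np.empty_like(pos)
    for start, stop in groups:
        out[:, start:stop] = clr_level(pos[:, start:stop])
    return ClrMatrix(
        sample_ids=[s.sample_id for s in cohort.samples],
        taxids=taxids,
        ranks=ranks,
        values=out,
    )


@dataclass
class FeatureSelection:
    retained_taxa: List[int]
    corr_pruned: Set[int]
    ig_pruned: Set[int]
    corr_threshold: float
    fitted_on: List[str]
    parent_r: Dict[int, float] = field(default_factory=dict)
    info_gain: Dict[int, float] = field(default_factory=dict)

    def report(self, tree: TaxonomyTree) -> pd.DataFrame:
        rows = []
        for t in list(self.retained_taxa) + sorted(self.corr_pruned) + sorted(self.ig_pruned):
            stage = (
                "retained" if t in set(self.retained_taxa)
                else "corr_pruned" if t in self.corr_pruned
                else "ig_pruned"
            )
            node = tree.nodes[t]
            rows.append({
                "taxid": t, "name": node.name, "rank": node.rank, "stage": stage,
                "r_with_parent": self.parent_r.get(t, np.nan),
                "information_gain": self.info_gain.get(t, np.nan),
            })
        return pd.DataFrame(rows)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with the convention r = 0 when either side has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        return 0.0
    return float((a @ b) / (na * nb))


def prune_correlated(
    tree: TaxonomyTree,
    clr: ClrMatrix,
    training_ids: Sequence[str],
    threshold: float = 0.7,
    compare_to: str = "nearest_retained",
) -> FeatureSelection:
    """Drop taxa redundant with their parent (Pearson r > ``threshold``).

    Traversal is top-down; with ``compare_to="nearest_retained"`` (default)
    a pruned node's children are tested against their nearest retained
    ancestor, with ``"parent"`` always against the original parent.
    Roots are always retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(training_ids) < 3:
        raise ValueError("need at least 3 training samples for correlation pruning")
    if compare_to not in ("nearest_retained", "parent"):
        raise ValueError(f"unknown compare_to mode {compare_to!r}")
    sub = ClrMatrix(
        sample_ids=list(training_ids),
        taxids=clr.taxids,
        ranks=clr.ranks,
        values=clr.rows(training_ids),
    )
    in_matrix = set(clr.taxids)
    retained: List[int] = []
    retained_set: Set[int] = set()
    pruned: Set[int] = set()
    parent_r: Dict[int, float] = {}
    for taxid in tree.preorder():
        if taxid not in in_matrix:
            continue
        parent = tree.nodes[taxid].parent
        if parent is None or parent not in in_matrix:
            retained.append(taxid)
            retained_set.add(taxid)
            continue
        if compare_to == "nearest_retained":
            ref = parent
            while ref is not None and ref not in retained_set:
                ref = tree.nodes[ref].parent
        else:
            ref = parent
        if ref is None:
            retained.append(taxid)
            retained_set.add(taxid)
            continue
        r = _pearson(sub.column(taxid), sub.column(ref))
        parent_r[taxid] = r
        if r > threshold:
            pruned.add(taxid)
        else:
            retained.append(taxid)
            retained_set.add(taxid)
    # keep the matrix's canonical column order
    order = {t: j for j, t in enumerate(clr.taxids)}
    retained.sort(key=order.__getitem__)
    return FeatureSelection(
        retained_taxa=retained,
        corr_pruned=pruned,
        ig_pruned=set(),
        corr_threshold=threshold,
        fitted_on=list(training_ids),
        parent_r=parent_r,
    )


def _entropy_counts(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy (bits) from positive counts ``pos`` out of ``n``."""
    pos = np.asarray(pos, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = pos / n
        h = -(np.where(p > 0, p * np.log2(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return np.where(n > 0, h, 0.0)


def information_gain(feature: np.ndarray, labels: np.ndarray) -> float:
    """Decision-stump information gain of a feature about binary labels (bits).

    Candidate thresholds are the midpoints between consecutive distinct
    sorted feature values; the gain is label entropy minus the best split's
    weighted child entropy.  A constant feature (no split) has gain 0.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("feature and labels must be equal-length vectors of length >= 2")
    n = len(x)
    base = float(_entropy_counts(np.array(y.sum()), np.array(float(n))))
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cut = np.nonzero(np.diff(xs) > 0)[0]  # split between positions i and i+1
    if cut.size == 0:
        return 0.0
    n_left = cut + 1.0
    pos_left = np.cumsum(ys)[cut]
    n_right = n - n_left
    pos_right = ys.sum() - pos_left
    child = (n_left * _entropy_counts(pos_left, n_left)
             + n_right * _entropy_counts(pos_right, n_right)) / n
    return max(0.0, base - float(child.min()))


def prune_zero_ig(
    clr: ClrMatrix,
    selection: FeatureSelection,
    instance_labels: Sequence[int],
    tol: float = 1e-12,
) -> FeatureSelection:
    """Drop correlation-retained taxa with zero information gain about NEC.

    ``instance_labels`` are the per-training-sample labels (each sample
    inherits its bag's label), aligned with ``selection.fitted_on``.
    """
    y = np.asarray(instance_labels, dtype=float)
    if len(y) != len(selection.fitted_on):
        raise ValueError("instance_labels must align with selection.fitted_on")
    rows = clr.rows(selection.fitted_on)
    col = {t: j for j, t in enumerate(clr.taxids)}
    retained: List[int] = []
    ig_pruned: Set[int] = set(selection.ig_pruned)
    gains: Dict[int, float] = dict(selection.info_gain)
    for t in selection.retained_taxa:
        ig = information_gain(rows[:, col[t]], y)
        gains[t] = ig
        if ig <= tol:
            ig_pruned.add(t)
        else:
            retained.append(t)
    if not retained:
        raise ValueError(
            "information-gain pruning discarded every taxon; "
            "review the correlation threshold or the labels"
        )
    return FeatureSelection(
        retained_taxa=retained,
        corr_pruned=set(selection.corr_pruned),
        ig_pruned=ig_pruned,
        corr_threshold=selection.corr_threshold,
        fitted_on=list(selection.fitted_on),
        parent_r=dict(selection.parent_r),
        info_gain=gains,
    )


def fit_feature_selection(
    tree: TaxonomyTree,
    clr: ClrMatrix,
    cohort: Cohort,
    training_sample_ids: Sequence[str],
    threshold: float = 0.7,
    compare_to: str = "nearest_retained",
) -> FeatureSelection:
    """Two-stage selection (correlation then information gain) on training samples."""
    sel = prune_correlated(tree, clr, training_sample_ids, threshold, compare_to)
    pat = {s.sample_id: s.patient_id for s in cohort.samples}
    labels = [cohort.metadata[pat[sid]].nec_label for sid in training_sample_ids]
    return prune_zero_ig(clr, sel, labels)


class CovariateEncoder:
    """Encodes the ten clinical covariates; continuous ones are z-scored
    with statistics fitted on training patients only (no leakage)."""

    def __init__(self) -> None:
        self.means: Dict[str, float] = {}
        self.stds: Dict[str, float] = {}
        self.fitted_on: List[str] = []

    def fit(self, metadata: Dict[str, ClinicalMetadata], training_patients: Sequence[str]) -> "CovariateEncoder":
        for name in CONTINUOUS_COVARIATES:
            vals = np.array([getattr(metadata[p], name) for p in training_patients], dtype=float)
            self.means[name] = float(vals.mean())
            sd = float(vals.std(ddof=0))
            self.stds[name] = sd if sd > 0 else 1.0
        self.fitted_on = list(training_patients)
        return self

    def transform(self, md: ClinicalMetadata) -> np.ndarray:
        if not self.means:
            raise RuntimeError("CovariateEncoder not fitted")
        out = []
        for name in COVARIATE_COLUMNS:
            v = float(getattr(md, name))
            if name in CONTINUOUS_COVARIATES:
                v = (v - self.means[name]) / self.stds[name]
            out.append(v)
        return np.array(out)


def assemble_instances(
    clr: ClrMatrix,
    selection: FeatureSelection,
    cohort: Cohort,
    encoder: Optional[CovariateEncoder] = None,
    include_metadata: bool = True,
) -> List[PatientBag]:
    """Build per-patient bags: retained-taxon CLR values (++ encoded covariates).

    ``include_metadata=False`` drops the ten covariate columns, leaving a
    microbiome-only feature space.
    """
    if include_metadata and encoder is None:
        raise ValueError("an encoder is required when clinical covariates are included")
    cols = [clr._col[t] for t in selection.retained_taxa]
    covnames = COVARIATE_COLUMNS if include_metadata else ()
    by_patient: Dict[str, List[InstanceVector]] = {}
    for i, s in enumerate(cohort.samples):
        taxa_feats = clr.values[clr._row[s.sample_id], cols]
        if include_metadata:
            cov = encoder.transform(cohort.metadata[s.patient_id])
            feats = np.concatenate([taxa_feats, cov])
        else:
            feats = taxa_feats
        by_patient.setdefault(s.patient_id, []).append(
            InstanceVector(
                patient_id=s.patient_id,
                sample_id=s.sample_id,
                day_of_life=s.day_of_life,
                features=feats,
            )
        )
    bags = []
    for pid, instances in by_patient.items():
        instances.sort(key=lambda iv: (iv.day_of_life, iv.sample_id))
        md = cohort.metadata[pid]
        bags.append(
            PatientBag(
                patient_id=pid,
                instances=instances,
                label=md.nec_label,
                onset_day=md.nec_onset_day,
                feature_taxids=tuple(selection.retained_taxa),
                covariate_names=tuple(covnames),
            )
        )
    return bags
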