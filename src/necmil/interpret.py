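"""Attention-guided interpretability via random-forest feature importance.

The MIL attention weights identify, for every patient, the single stool
sample that contributed most to the bag prediction.  Representing each
patient by that highest-attention instance (microbiome features only, no
clinical covariates) turns the weakly supervised problem into an ordinary
supervised one, where a random forest's Gini impurity importances can be
read off per taxon and summed over the taxonomy to any rank of interest
(phylum, class, family ...): the importance of a taxon c at a rank is the
sum of importances of the selected features that descend from (or equal) c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from necmil.bags import PatientBag
from necmil.mil import MILParams, predict_bag
from necmil.taxonomy import TaxonomyTree

__all__ = [
    "ImportanceReport",
    "highest_attention_instance",
    "fit_rf_importance",
    "aggregate_importance",
    "rank_report",
    "attention_rf_replicate",
]


@dataclass
class ImportanceReport:
    """Per-feature RF importances plus their taxonomic aggregates."""

    per_feature: Dict[int, float]           # taxid -> normalized Gini importance
    per_level: Dict[str, Dict[int, float]]  # rank -> taxon taxid -> summed importance
    replicate_id: int = 0
    seed: int = 0
    holdout_roc_auc: Optional[float] = None


def highest_attention_instance(attention: np.ndarray) -> int:
    """Index of the largest attention weight (0-based).

    Instances are ordered by day of life, so on ties the earliest day wins
    (numpy argmax returns the first maximum).
    """
    a = np.asarray(attention, dtype=float)
    if a.size == 0:
        raise ValueError("empty attention vector")
    return int(np.argmax(a))


def fit_rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
) -> Tuple[np.ndarray, RandomForestClassifier]:
    """Random forest (Gini impurity) feature importances.

    Importances are per-tree normalized impurity-reduction sums averaged
    over trees, so they are non-negative and sum to 1.  Requires both
    classes present and the clinical covariates already removed.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(X, dtype=float), y)
    return rf.feature_importances_, rf


def aggregate_importance(
    per_feature: Dict[int, float],
    tree: TaxonomyTree,
    rank: str,
) -> Dict[int, float]:
    """Sum feature importances up the taxonomy to the taxa of ``rank``.

    A feature contributes to the rank-level taxon it descends from; a
    feature that *is* a taxon at that rank counts as its own descendant.
    Taxa at the rank with no selected descendants get 0.  Importance mass
    of features above the rank (no ancestor at that rank) stays
    unaggregated by construction.
    """
    for t in per_feature:
        if t not in tree:
            raise ValueError(f"feature taxid {t} not in taxonomy")
    out: Dict[int, float] = {t: 0.0 for t in tree.nodes_at_rank(rank)}
    for t, fi in per_feature.items():
        node = t if tree.nodes[t].rank == rank else None
        if node is None:
            for anc in tree.ancestors(t):
                if tree.nodes[anc].rank == rank:
                    node = anc
                    break
        if node is not None:
            out[node] += fi
    return out


def rank_report(
    reports: Sequence[ImportanceReport],
    rank: str,
    tree: TaxonomyTree,
    top_n: int = 15,
) -> pd.DataFrame:
    """Taxa at ``rank`` ordered by mean importance across replicates.

    A taxon absent from a replicate (e.g. pruned by that replicate's
    feature selection) is averaged in with importance 0 and flagged in the
    ``in_all_replicates`` column.
    """
    if not reports:
        raise ValueError("no replicates")
    taxa = sorted({t for r in reports for t in r.per_level.get(rank, {})})
    rows = []
    for t in taxa:
        vals = [r.per_level.get(rank, {}).get(t, 0.0) for r in reports]
        rows.append({
            "rank": rank,
            "taxid": t,
            "name": tree.nodes[t].name,
            "mean_importance": float(np.mean(vals)),
            "in_all_replicates": all(t in r.per_level.get(rank, {}) for r in reports),
            **{f"rep{r.replicate_id}": v for r, v in zip(reports, vals)},
        })
    df = pd.DataFrame(rows).sort_values("mean_importance", ascending=False, kind="mergesort")
    return df.head(top_n).reset_index(drop=True)


def attention_rf_replicate(
    bags: Sequence[PatientBag],
    params: MILParams,
    tree: TaxonomyTree,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    ranks: Sequence[str] = ("phylum", "class", "family"),
    replicate_id: int = 0,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceReport:
    """One interpretability replicate on a given train/test split.

    Each patient is represented by the microbiome features of their
    highest-attention instance under the full (t = k) bag attention; a
    random forest is fitted on the training patients and its held-out ROC
    AUC plus aggregated importances are reported.
    """
    from necmil.evaluate import roc_pr

    def representative(bag: PatientBag) -> np.ndarray:
        att = predict_bag(bag, params).attention
        return bag.microbiome_matrix()[highest_attention_instance(att)]

    X_tr = np.stack([representative(bags[i]) for i in train_idx])
    y_tr = np.array([bags[i].label for i in train_idx])
    fi, rf = fit_rf_importance(X_tr, y_tr, seed=seed, n_trees=n_trees)

    auc = None
    y_te = np.array([bags[i].label for i in test_idx])
    if len(test_idx) and len(np.unique(y_te)) == 2:
        X_te = np.stack([representative(bags[i]) for i in test_idx])
        scores = rf.predict_proba(X_te)[:, 1]
        auc = roc_pr(scores, y_te)[0].auc

    taxids = bags[train_idx[0]].feature_taxids
    per_feature = {t: float(v) for t, v in zip(taxids, fi)}
    per_level = {r: aggregate_importance(per_feature, tree, r) for r in ranks}
    return ImportanceReport(
        per_feature=per_feature,
        per_level=per_level,
        replicate_id=replicate_id,
        seed=seed,
        holdout_roc_auc=auc,
    )
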