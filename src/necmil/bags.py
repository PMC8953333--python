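"""Bag and instance containers shared by preprocessing and the MIL model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["InstanceVector", "PatientBag"]


@dataclass
class InstanceVector:
    """One stool sample's feature vector: retained-taxon CLR values followed
    by encoded clinical covariates.  ``day_of_life`` is carried alongside
    (it parameterizes the risk score) but is never part of ``features``."""

    patient_id: str
    sample_id: str
    day_of_life: int
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"instance {self.sample_id}: non-finite feature values")


@dataclass
class PatientBag:
    """One patient: instances ordered by day of life, plus the bag label.

    ``feature_taxids`` records which leading feature columns are taxa (in
    order); the remaining columns are clinical covariates.  The split is
    needed by the interpretability stage, which uses microbiome columns only.
    """

    patient_id: str
    instances: List[InstanceVector]
    label: int
    onset_day: Optional[int] = None
    feature_taxids: Tuple[int, ...] = ()
    covariate_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError(f"bag {self.patient_id}: empty bag")
        days = [iv.day_of_life for iv in self.instances]
        if days != sorted(days):
            raise ValueError(f"bag {self.patient_id}: instances not ordered by day_of_life")
        lengths = {iv.features.shape[0] for iv in self.instances}
        if len(lengths) != 1:
            raise ValueError(f"bag {self.patient_id}: ragged feature lengths {lengths}")
        if self.label not in (0, 1):
            raise ValueError(f"bag {self.patient_id}: label must be 0/1")
        if self.label == 1 and self.onset_day is None:
            raise ValueError(f"bag {self.patient_id}: positive bag without onset day")

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def days(self) -> List[int]:
        return [iv.day_of_life for iv in self.instances]

    def matrix(self) -> np.ndarray:
        """Instances stacked into a (k, n_features) array."""
        return np.stack([iv.features for iv in self.instances])

    def microbiome_matrix(self) -> np.ndarray:
        """Taxon columns only (clinical covariates removed)."""
        return self.matrix()[:, : len(self.feature_taxids)]

    def prefix(self, t: int) -> "PatientBag":
        """The growing bag after ``t`` samples (1-based)."""
        if not 1 <= t <= len(self):
            raise ValueError(f"prefix length {t} out of range for bag of size {len(self)}")
        return PatientBag(
            patient_id=self.patient_id,
            instances=self.instances[:t],
            label=self.label,
            onset_day=self.onset_day,
            feature_taxids=self.feature_taxids,
            covariate_names=self.covariate_names,
        )
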