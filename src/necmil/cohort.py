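"""Cohort assembly: per-sample counts, clinical metadata, bacterial filtering.

The clinical metadata table doubles as the sample manifest: one row per
stool sample with ``sample_id``, ``patient_id``, ``day_of_life`` plus the
patient-level covariates and NEC outcome repeated on every row for that
patient.  The ten shared covariates are the ones reported by both source
cohorts (gestational age, sex, birthweight, delivery mode, multiple
gestation, live-born number, three feeding-exclusivity flags, NPO).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from necmil.taxonomy import TaxonomyTree, read_kraken2_report

logger = logging.getLogger(__name__)

__all__ = [
    "COVARIATE_COLUMNS",
    "CONTINUOUS_COVARIATES",
    "SampleCounts",
    "ClinicalMetadata",
    "Cohort",
    "filter_bacteria",
    "read_metadata",
    "write_metadata",
    "build_cohort",
]

#: The ten shared clinical covariates, in canonical feature order.
COVARIATE_COLUMNS = (
    "gestational_age_at_birth",
    "male",
    "birthweight",
    "vaginal_delivery",
    "multiple_gestation",
    "number_live_born",
    "exclusively_formula",
    "exclusively_breast",
    "combination_fed",
    "npo_throughout",
)

#: Covariates z-scored with training statistics; the rest are 0/1 flags.
CONTINUOUS_COVARIATES = ("gestational_age_at_birth", "birthweight", "number_live_born")

_BINARY_COVARIATES = tuple(c for c in COVARIATE_COLUMNS if c not in CONTINUOUS_COVARIATES)

_EXCLUSIVITY_FLAGS = ("exclusively_formula", "exclusively_breast", "combination_fed")


@dataclass
class SampleCounts:
    """Direct Kraken2 read counts for one stool sample."""

    sample_id: str
    patient_id: str
    day_of_life: int
    counts: Dict[int, int]

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ClinicalMetadata:
    patient_id: str
    gestational_age_at_birth: float
    male: int
    birthweight: float
    vaginal_delivery: int
    multiple_gestation: int
    number_live_born: int
    exclusively_formula: int
    exclusively_breast: int
    combination_fed: int
    npo_throughout: int
    nec_label: int
    nec_onset_day: Optional[int] = None

    def __post_init__(self) -> None:
        flags = [getattr(self, f) for f in _EXCLUSIVITY_FLAGS]
        if sum(flags) > 1:
            raise ValueError(
                f"patient {self.patient_id}: more than one feeding-exclusivity flag set"
            )
        if self.number_live_born not in (1, 2, 3):
            raise ValueError(
                f"patient {self.patient_id}: number_live_born must be 1-3, "
                f"got {self.number_live_born}"
            )
        if self.nec_label not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: nec_label must be 0/1")
        if self.nec_label == 1:
            if self.nec_onset_day is None:
                raise ValueError(f"patient {self.patient_id}: NEC-positive but no onset day")
            if self.nec_onset_day < 0:
                raise ValueError(f"patient {self.patient_id}: negative onset day")

    def covariate_vector(self) -> List[float]:
        return [float(getattr(self, c)) for c in COVARIATE_COLUMNS]


@dataclass
class Cohort:
    """A shared taxonomy, per-sample counts and per-patient metadata."""

    tree: TaxonomyTree
    samples: List[SampleCounts]
    metadata: Dict[str, ClinicalMetadata]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.patient_id not in self.metadata:
                raise ValueError(f"sample {s.sample_id}: unknown patient {s.patient_id}")

    def patients(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def samples_for(self, patient_id: str) -> List[SampleCounts]:
        return [s for s in self.samples if s.patient_id == patient_id]

    def labels(self) -> Dict[str, int]:
        return {p: self.metadata[p].nec_label for p in self.patients()}


def filter_bacteria(tree: TaxonomyTree, counts: SampleCounts):
    """Restrict a parsed report to the Bacteria subtree.

    Drops unclassified reads and non-bacterial kingdoms (archaea, fungi,
    viruses ...).  Returns ``(bacterial_tree, filtered_counts)``.  A sample
    whose reads are entirely non-bacterial is returned with empty counts
    and a warning.
    """
    hits = [t for t in tree.find_by_name("Bacteria") if tree.nodes[t].rank == "kingdom"]
    if not hits:
        raise ValueError("no kingdom-level Bacteria node in taxonomy")
    root = hits[0]
    sub = tree.subtree(root)
    kept = {t: c for t, c in counts.counts.items() if t in sub}
    if counts.counts and not any(kept.values()):
        warnings.warn(
            f"sample {counts.sample_id}: no bacterial reads after filtering",
            stacklevel=2,
        )
    return sub, SampleCounts(
        sample_id=counts.sample_id,
        patient_id=counts.patient_id,
        day_of_life=counts.day_of_life,
        counts=kept,
    )


_META_COLUMNS = ("sample_id", "patient_id", "day_of_life", "nec_label", "nec_onset_day") + COVARIATE_COLUMNS


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample-manifest/metadata table (TSV or CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return df


def write_metadata(df: pd.DataFrame, path: str | os.PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def _metadata_from_rows(patient_id: str, rows: pd.DataFrame) -> ClinicalMetadata:
    first = rows.iloc[0]
    for col in ("nec_label", "nec_onset_day") + COVARIATE_COLUMNS:
        vals = rows[col].fillna(-1).nunique()
        if vals > 1:
            raise ValueError(f"patient {patient_id}: inconsistent values in column {col!r}")
    onset = first["nec_onset_day"]
    onset = None if pd.isna(onset) else int(onset)
    kwargs = {c: first[c] for c in COVARIATE_COLUMNS}
    for c in _BINARY_COVARIATES:
        kwargs[c] = int(kwargs[c])
    kwargs["number_live_born"] = int(kwargs["number_live_born"])
    return ClinicalMetadata(
        patient_id=patient_id,
        nec_label=int(first["nec_label"]),
        nec_onset_day=onset,
        **kwargs,
    )


def build_cohort(
    report_paths: Sequence[str | os.PathLike],
    metadata_path: str | os.PathLike,
    drop_post_onset: bool = True,
) -> Cohort:
    """Assemble a cohort from per-sample Kraken2 reports plus a metadata table.

    Reports are matched to manifest rows by filename stem == ``sample_id``.
    The taxonomy is the union over samples (consistency enforced by taxid);
    taxa absent from a sample implicitly have count 0.  Samples are grouped
    by patient and ordered by ``day_of_life`` (ties broken by sample_id).
    For NEC-positive patients, samples collected after the onset day are
    excluded, mirroring a birth-through-onset collection protocol.
    """
    meta_df = read_metadata(metadata_path)
    by_sample = meta_df.set_index("sample_id")
    if by_sample.index.has_duplicates:
        dups = by_sample.index[by_sample.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id rows in metadata: {dups}")

    metadata: Dict[str, ClinicalMetadata] = {}
    for pid, rows in meta_df.groupby("patient_id", sort=False):
        metadata[str(pid)] = _metadata_from_rows(str(pid), rows)

    union_tree = TaxonomyTree()
    samples: List[SampleCounts] = []
    for path in sorted(report_paths, key=lambda p: os.path.basename(os.fspath(p))):
        tree, counts = read_kraken2_report(path)
        if counts.sample_id not in by_sample.index:
            raise ValueError(f"report {path}: sample {counts.sample_id!r} not in metadata")
        row = by_sample.loc[counts.sample_id]
        pid = str(row["patient_id"])
        btree, bcounts = filter_bacteria(tree, counts)
        union_tree.merge(btree)
        bcounts.patient_id = pid
        bcounts.day_of_life = int(row["day_of_life"])
        md = metadata[pid]
        if drop_post_onset and md.nec_label == 1 and bcounts.day_of_life > md.nec_onset_day:
            logger.info("dropping post-onset sample %s (day %d > onset %d)",
                        bcounts.sample_id, bcounts.day_of_life, md.nec_onset_day)
            continue
        samples.append(bcounts)

    samples.sort(key=lambda s: (s.patient_id, s.day_of_life, s.sample_id))
    return Cohort(tree=union_tree, samples=samples, metadata=metadata)
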