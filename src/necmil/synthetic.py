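"""Synthetic longitudinal NEC cohorts with planted pre-onset dysbiosis.

The generator emulates the statistical structure the MIL system assumes:

* a rank-complete bacterial taxonomy (kingdom down to species);
* sparse compositional fragment counts per stool sample, from a
  hierarchical Dirichlet model: a sparse cohort-level community template
  (preterm gut communities share their dominant taxa), per-patient
  baselines drawn around the template, per-sample compositions drawn
  around the baseline; reads are multinomially drawn at a log-normal
  sequencing depth and assigned to a taxonomic rank per read (most resolve
  to species, a fraction "sticks" at coarser ranks, as in real classifier
  reports, with per-sample, per-taxon variation in how well reads resolve),
  with extra zero-inflation on top;
* irregular sampling: a renewal process of day-of-life values per infant;
* bag labels driven by planted taxa: NEC-positive infants have the
  composition of ``n_signal_taxa`` species multiplied by exp(effect_size)
  in every sample within ``lead_window`` days before onset; post-onset
  samples are never generated, mirroring a birth-through-onset protocol;
* ten Table-1-style clinical covariates, independent of the label by
  default (an optional ``covariate_effect`` knob shifts gestational age
  and birthweight downward in affected infants for stress tests).

Everything is driven by one ``numpy.random.default_rng(seed)`` stream in a
fixed draw order, so cohorts are reproducible across platforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from necmil.cohort import ClinicalMetadata, Cohort, SampleCounts
from necmil.taxonomy import RANKS, TaxonomyTree, write_kraken2_report

__all__ = ["SimConfig", "GroundTruth", "simulate_taxonomy", "simulate_cohort", "write_cohort"]

# Probability that a read is classified exactly at each rank (species-heavy,
# like shotgun classifier output); renormalized over the ranks present.
_RANK_WEIGHTS = {
    "kingdom": 0.02,
    "phylum": 0.04,
    "class": 0.05,
    "order": 0.06,
    "family": 0.08,
    "genus": 0.15,
    "species": 0.60,
}


@dataclass
class SimConfig:
    n_patients: int = 120
    prevalence: float = 0.3
    n_leaf_taxa: int = 60
    ranks: int = 7
    samples_min: int = 4
    samples_max: int = 12
    mean_gap_days: float = 5.0
    first_day_min: int = 3
    first_day_max: int = 7
    onset_mean: float = 30.0
    onset_sd: float = 8.0
    onset_min: int = 10
    n_signal_taxa: int = 5
    effect_size: float = 2.0       # log-scale composition shift of signal taxa
    lead_window: int = 14          # days before onset when the shift is active
    depth_log_mean: float = 9.9    # ~2e4 reads
    depth_log_sd: float = 0.5
    zero_inflation: float = 0.15
    resolution_noise: float = 3.0  # gamma shape of per-sample per-taxon
                                   # classification-rate jitter (smaller = noisier)
    dirichlet_alpha: float = 0.3   # sparsity of the cohort community template
    patient_concentration: float = 100.0  # patient-to-patient overdispersion
    sample_concentration: float = 100.0   # sample-to-sample overdispersion
    covariate_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_signal_taxa > self.n_leaf_taxa:
            raise ValueError("more signal taxa than leaves")


@dataclass
class GroundTruth:
    labels: Dict[str, int]
    onset_days: Dict[str, Optional[int]]
    signal_taxids: List[int]
    signal_samples: Set[str]       # sample_ids where the planted shift was active
    node_taxids: List[int]
    expected_composition: Dict[str, np.ndarray]  # sample_id -> P(read -> node)


def simulate_taxonomy(n_leaf_taxa: int, ranks: int = 7, seed: int = 0) -> TaxonomyTree:
    """A random rank-complete taxonomy with the requested number of leaves.

    Level sizes interpolate geometrically from the single kingdom root to
    ``n_leaf_taxa`` leaves; every internal node gets at least one child and
    every bottom-rank parent at least two (so sibling leaves exist, as in
    real genera).  Deterministic per seed.
    """
    if n_leaf_taxa < 2:
        raise ValueError("need at least 2 leaf taxa")
    if not 2 <= ranks <= 7:
        raise ValueError("ranks must be between 2 (kingdom+1) and 7")
    rng = np.random.default_rng(seed)
    rank_names = list(RANKS[:ranks])
    sizes = [max(1, int(round(n_leaf_taxa ** (r / (ranks - 1))))) for r in range(ranks)]
    sizes[0], sizes[-1] = 1, n_leaf_taxa
    if n_leaf_taxa >= 4:
        sizes[-2] = min(sizes[-2], n_leaf_taxa // 2)  # >=2 species per genus on average
    for r in range(1, ranks):  # level sizes never shrink going down
        sizes[r] = max(sizes[r], sizes[r - 1])

    tree = TaxonomyTree()
    tree.add_node(2, "Bacteria", "kingdom", parent=None)
    level_ids: List[List[int]] = [[2]]
    next_taxid = 10
    for r in range(1, ranks):
        parents = level_ids[-1]
        n = sizes[r]
        # each parent gets one child first (two at the leaf rank, so sibling
        # species exist); the rest pick parents at random
        per_parent = 2 if r == ranks - 1 and n >= 2 * len(parents) else 1
        assignment = list(parents) * per_parent
        extra = n - len(assignment)
        if extra > 0:
            assignment += list(rng.choice(parents, size=extra, replace=True))
        assignment = assignment[:n]
        ids = []
        for i, parent in enumerate(assignment[:n]):
            tid = next_taxid
            next_taxid += 1
            tree.add_node(tid, f"{rank_names[r].capitalize()}_{i + 1}", rank_names[r], parent=int(parent))
            ids.append(tid)
        level_ids.append(ids)
    return tree


def _node_read_probs(
    tree: TaxonomyTree,
    leaves: Sequence[int],
    node_order: Sequence[int],
    leaf_comp: np.ndarray,
    rank_weights: Dict[str, float],
) -> np.ndarray:
    """P(read classified at node) = rank weight x leaf mass of its subtree."""
    mass: Dict[int, float] = {t: 0.0 for t in node_order}
    for leaf, p in zip(leaves, leaf_comp):
        mass[leaf] = p
    for t in reversed(list(tree.preorder())):
        for c in tree.nodes[t].children:
            mass[t] += mass[c]
    return np.array([rank_weights[tree.nodes[t].rank] * mass[t] for t in node_order])


def _draw_covariates(rng: np.random.Generator, label: int, effect: float) -> Dict[str, float]:
    ga = rng.normal(27.0, 2.3) - effect * 2.3 * label
    bw = rng.normal(1000.0, 280.0) - effect * 280.0 * label
    multiple = int(rng.random() < 0.28)
    feeding = rng.choice(4, p=[0.05, 0.25, 0.65, 0.05])  # formula/breast/combo/none
    return {
        "gestational_age_at_birth": round(float(np.clip(ga, 22.0, 36.0)), 1),
        "male": int(rng.random() < 0.5),
        "birthweight": round(float(np.clip(bw, 400.0, 2500.0)), 0),
        "vaginal_delivery": int(rng.random() < 0.3),
        "multiple_gestation": multiple,
        "number_live_born": int(rng.integers(2, 4)) if multiple else 1,
        "exclusively_formula": int(feeding == 0),
        "exclusively_breast": int(feeding == 1),
        "combination_fed": int(feeding == 2),
        "npo_throughout": int(rng.random() < 0.01),
    }


def _schedule(rng: np.random.Generator, config: SimConfig) -> List[int]:
    k = int(rng.integers(config.samples_min, config.samples_max + 1))
    day = int(rng.integers(config.first_day_min, config.first_day_max + 1))
    days = [day]
    for _ in range(k - 1):
        day += max(1, int(round(rng.exponential(config.mean_gap_days))))
        days.append(day)
    return days


def simulate_cohort(config: Optional[SimConfig] = None) -> Tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort; see the module docstring for the model."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_taxonomy(config.n_leaf_taxa, config.ranks, seed=int(rng.integers(2**31 - 1)))
    leaves = sorted(tree.nodes_at_rank(RANKS[config.ranks - 1]))
    node_order = sorted(tree.nodes)
    present = {RANKS[r] for r in range(config.ranks)}
    total_w = sum(_RANK_WEIGHTS[r] for r in present)
    rank_weights = {r: _RANK_WEIGHTS[r] / total_w for r in present}

    # cohort-level community template; patients vary around it
    template = rng.dirichlet(np.full(len(leaves), config.dirichlet_alpha))
    template = np.maximum(template, 1e-6)
    template /= template.sum()

    # dysbiosis is planted in community members that are actually observed:
    # signal taxa are drawn abundance-weighted, like the facultative
    # anaerobe blooms reported before NEC onset
    sig_pos = rng.choice(len(leaves), size=config.n_signal_taxa, replace=False, p=template)
    signal_taxids = sorted(int(leaves[i]) for i in sig_pos)
    signal_idx = np.array([leaves.index(t) for t in signal_taxids])

    samples: List[SampleCounts] = []
    metadata: Dict[str, ClinicalMetadata] = {}
    labels: Dict[str, int] = {}
    onsets: Dict[str, Optional[int]] = {}
    signal_samples: Set[str] = set()
    expected: Dict[str, np.ndarray] = {}

    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        label = int(rng.random() < config.prevalence)
        baseline = rng.dirichlet(config.patient_concentration * template)
        baseline = np.maximum(baseline, 1e-9)
        baseline /= baseline.sum()

        onset: Optional[int] = None
        if label:
            for _try in range(100):
                onset = max(config.onset_min, int(round(rng.normal(config.onset_mean, config.onset_sd))))
                days = [d for d in _schedule(rng, config) if d <= onset]
                in_window = [d for d in days if d > onset - config.lead_window]
                if days and in_window:
                    break
            else:
                raise RuntimeError(f"could not draw a feasible schedule for {pid}")
        else:
            days = _schedule(rng, config)

        for j, day in enumerate(days):
            sid = f"{pid}_s{j:02d}"
            comp = rng.dirichlet(config.sample_concentration * baseline)
            comp = np.maximum(comp, 1e-12)
            active = bool(label and day > onset - config.lead_window)
            if active:
                comp = comp.copy()
                comp[signal_idx] *= np.exp(config.effect_size)
                signal_samples.add(sid)
            comp = comp / comp.sum()
            q = _node_read_probs(tree, leaves, node_order, comp, rank_weights)
            if config.resolution_noise > 0:
                # per-sample, per-taxon variability in classification rates
                q = q * rng.gamma(config.resolution_noise, 1.0 / config.resolution_noise, len(q))
            depth = max(100, int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd))))
            counts = rng.multinomial(depth, q / q.sum())
            if config.zero_inflation > 0:
                # technical dropout hits low-abundance taxa: the dropout
                # probability decays with the observed count
                p_drop = config.zero_inflation * np.exp(-counts / 20.0)
                counts = np.where(rng.random(len(counts)) < p_drop, 0, counts)
            samples.append(
                SampleCounts(
                    sample_id=sid,
                    patient_id=pid,
                    day_of_life=int(day),
                    counts={int(t): int(c) for t, c in zip(node_order, counts) if c > 0},
                )
            )
            expected[sid] = q / q.sum()

        cov = _draw_covariates(rng, label, config.covariate_effect)
        metadata[pid] = ClinicalMetadata(
            patient_id=pid, nec_label=label, nec_onset_day=onset, **cov
        )
        labels[pid] = label
        onsets[pid] = onset

    cohort = Cohort(tree=tree, samples=samples, metadata=metadata)
    truth = GroundTruth(
        labels=labels,
        onset_days=onsets,
        signal_taxids=signal_taxids,
        signal_samples=signal_samples,
        node_taxids=node_order,
        expected_composition=expected,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir: str | os.PathLike) -> Dict[str, List[str]]:
    """Emit the cohort as Kraken2-dialect reports + metadata and truth TSVs.

    Re-ingesting the written files with :func:`necmil.cohort.build_cohort`
    reproduces the count matrices exactly.  Returns the written paths.
    """
    import pandas as pd

    outdir = os.fspath(outdir)
    reports_dir = os.path.join(outdir, "reports")
    os.makedirs(reports_dir, exist_ok=True)
    report_paths = []
    for s in cohort.samples:
        path = os.path.join(reports_dir, f"{s.sample_id}.kreport")
        write_kraken2_report(cohort.tree, s.counts, path)
        report_paths.append(path)

    rows = []
    for s in cohort.samples:
        md = cohort.metadata[s.patient_id]
        rows.append({
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "day_of_life": s.day_of_life,
            "nec_label": md.nec_label,
            "nec_onset_day": md.nec_onset_day,
            **{c: getattr(md, c) for c in (
                "gestational_age_at_birth", "male", "birthweight", "vaginal_delivery",
                "multiple_gestation", "number_live_born", "exclusively_formula",
                "exclusively_breast", "combination_fed", "npo_throughout",
            )},
        })
    meta_path = os.path.join(outdir, "metadata.tsv")
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)

    truth_path = os.path.join(outdir, "ground_truth.tsv")
    pd.DataFrame({
        "signal_taxid": truth.signal_taxids,
        "name": [cohort.tree.nodes[t].name for t in truth.signal_taxids],
    }).to_csv(truth_path, sep="\t", index=False)
    return {"reports": report_paths, "metadata": [meta_path], "ground_truth": [truth_path]}
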