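# Methods

## Problem setting

Necrotizing enterocolitis (NEC) is a rapidly progressing intestinal disease
of preterm infants with no established predictive biomarker.  The premise of
this package is that serially collected stool microbiome profiles carry a
pre-onset signature of NEC risk, but that no single stool sample can be
labeled "NEC" or "healthy" on its own.  That makes the problem weakly
supervised: labels exist per patient, not per sample.  We therefore model
each infant as a *bag* of unlabeled instances — one instance per stool
sample — and learn a bag-level classifier by multiple-instance learning
(MIL), with an attention mechanism that additionally reveals *which*
samples drove each prediction.

## Input representation

Per-sample taxon counts follow the Kraken2 report dialect; the direct-read
column is used (reads classified exactly at a node), never the clade
rollup, because the taxonomy tree itself supplies the hierarchy and clade
rollups would double-count a read at every ancestor.  Non-bacterial
kingdoms and unclassified reads are dropped.

Counts are compositional (constrained by sequencing depth), so analysis
operates on centered log-ratios (CLR):

    x_clr,j = ln( x_j / G(x) ),   G(x) = (x_1 x_2 ... x_D)^(1/D)

computed *within each taxonomic rank* of each sample, after replacing
zeros by the pseudocount 0.66 (two-thirds of the smallest possible read
count of 1).  Per rank, CLR values of a sample sum to zero by
construction; a rank with a single taxon maps to 0.

Dimensionality is then reduced by two supervised, hierarchical filters
fitted on training samples only:

1. **Correlation pruning.**  Walking the taxonomy top-down, a node whose
   CLR column has Pearson r > 0.7 with its nearest retained ancestor's is
   removed as redundant.  The threshold applies to r, not |r|, so
   anti-correlated children are retained (they carry complementary
   information).  Zero-variance columns get r = 0 and survive this stage.
2. **Information-gain pruning.**  A decision-stump information gain
   (exhaustive midpoint thresholds, entropy in bits) is computed for every
   surviving taxon against the NEC label, each sample inheriting its
   patient's label; taxa with zero gain are discarded.

Instance vectors are the retained taxa's CLR values, optionally
concatenated with ten clinical covariates (gestational age, sex,
birthweight, delivery mode, multiple gestation, live-born number, three
feeding-exclusivity flags, NPO status).  Continuous covariates are
z-scored with training-set statistics.  Day of life is stored alongside
each instance but deliberately excluded from the features: it
parameterizes the risk score, and baking it into the classifier would let
the model learn calendar time instead of microbiome state.

## The gated-attention MIL classifier

Instances x_k are embedded by a two-layer fully connected network
(input → 128 → M, ReLU; M = 64), giving h_k.  The bag embedding is the
attention-weighted mean z = Σ_k a_k h_k with gated attention logits

    e_k = w^T ( tanh(V h_k) ⊙ sigm(U h_k) ),   a = softmax(e)

where V, U ∈ R^{L×M} (L = 32) and w ∈ R^L; the sigmoid gate modulates the
tanh branch elementwise.  Softmax is computed with max subtraction.  A
final linear layer with a sigmoid maps z to the Bernoulli parameter
θ(X) ∈ (0,1) — the bag confidence.  The construction is permutation
invariant and handles variable bag sizes natively.

Training minimizes the class-weighted (inverse prevalence; NEC bags are a
minority) Bernoulli negative log-likelihood of bag labels with Adam
(lr 5e-4, weight decay 1e-2, minibatches of 16 bags, at most 200 epochs),
early-stopped with patience 20 on the binary cross-entropy of an internal
15% stratified validation split; the best-validation parameters are
returned.  The forward and backward passes are written directly in numpy;
gradients are analytic and verified against central finite differences in
the test suite.  Weight decay is set an order of magnitude stronger than
habit would suggest because cohorts of ~100 bags are small relative to the
parameter count; weaker settings let training memorize the bags and made
held-out performance swing widely between runs.

Because small-cohort training remains seed-sensitive even when
regularized, the pipeline drivers train a 3-member ensemble of
independently initialized models and average confidences and attention
vectors.  This is pure variance reduction; single-model training is the
documented `train_mil` surface and all contracts hold for both.

Evaluation uses five independent stratified 80/20 train/test partitions.
Feature selection and covariate encoders are refitted inside every
partition on its training patients only — selection is supervised, and
fitting it once on the full cohort would leak held-out labels into the
feature space.

## Growing-bag inference and the risk score

For monitoring, the model is applied to every prefix of a patient's bag:
after t samples it emits confidence c_t and attention A^t over the t
samples seen so far.  Prefix evaluations are pure: appending a sample
never changes earlier confidences.  The evaluating model is always trained
leave-one-patient-out, so no patient is ever scored by a model that saw
their data.

Confidences become a bounded risk trajectory via per-sample contributions

    v_t = (d_t − d_{t−1}) · (c_t − 0.5) · (a_t − a_t^min)

(day gap × zero-centered confidence × marginal attention of the newest
sample, a_t^min being the smallest attention in the current bag), with
d_0 = 0 at birth.  A confidence drop greater than 0.75 between consecutive
evaluations permanently flips the sign of all later contributions —
empirically, unaffected infants' confidence collapses once enough healthy
samples accumulate, and the flip locks their trajectory downward.  The
risk accumulates as

    r_t = clip( r_{t−1} + v_t / τ , 0, 1 ),   r_0 = r_init = 0.5

with τ = 30 day-units.  τ is a free scale parameter: it changes how fast
trajectories saturate but not the sign of movements, and (at the cutoff
r_init exactly) not the classification; it is exposed in configuration.
A patient is called positive when the risk ever exceeds a cutoff, and the
lead time is the span from first crossing to clinical onset (negative
values — post-onset detections — are flagged and excluded from mean lead
times).

Two structural consequences of this formulation are worth knowing.
First, the contribution of the very first sample is always zero (its
attention is both a_t and a_t^min), so r_1 = r_init for every patient.
Second, with r_init = 0.5, any cutoff at or below 0.5 therefore classifies
every patient positive; meaningful operating points lie above r_init, and
the threshold sweep (selecting the cutoff with maximal balanced accuracy
over a 0.05-spaced grid) finds them.  The 0.35 default cutoff is retained
in configuration for continuity, but the sweep-selected cutoff is what the
evaluation reports.

## Attention-guided interpretability

MIL predictions are hard to attribute to taxa directly, so each patient is
reduced to the single instance with the highest full-bag attention weight
(ties → earliest day), clinical covariates are removed, and a random
forest (500 trees, Gini impurity, √d features per split) is fitted on
these representatives over the same five train/test partitions as the MIL
trials.  Feature importances are the forest's normalized mean per-tree
impurity reductions (they sum to 1), and are aggregated to any taxonomic
rank by summing each selected feature's importance into its
ancestor-or-self at that rank.  Aggregation conserves mass exactly: a rank
level's total equals the summed importances of the features at or below
that rank.  Importance carried by features *above* the chosen rank (e.g. a
retained family when reporting at species level) has no descendant at that
rank and is intentionally not redistributed.

## The synthetic cohort generator

Real NEC cohorts are access-controlled, so the package ships a simulator
that reproduces the statistical structure the method assumes, and the
whole test battery runs against it.  Per cohort:

* **Taxonomy** — a random rank-complete tree (kingdom → species, 7 ranks,
  60 species by default), level sizes interpolating geometrically, every
  genus with sibling species.
* **Compositions** — hierarchical Dirichlet: one sparse cohort-level
  template (Dirichlet α = 0.3 over species), per-patient baselines
  ~ Dirichlet(100 · template), per-sample compositions
  ~ Dirichlet(100 · baseline).  The hierarchy matters: preterm gut
  communities share dominant taxa, and fully independent per-patient
  compositions would bury any per-sample signal under between-patient
  variance.
* **Counts** — reads are assigned a resolution rank per read
  (species-heavy, with per-sample per-taxon gamma jitter of the
  classification rates, as database coverage varies), drawn multinomially
  at a log-normal depth (~2×10^4 reads), then thinned by technical
  dropout whose probability decays with the observed count — sparsity
  concentrates in low-abundance taxa, as in real data.
* **Sampling** — 4–12 stools per infant at renewal-process days (mean gap
  5 d, first sample day 3–7).
* **Outcome** — 30% of infants are NEC-positive with onset
  ~ N(30, 8²) days (≥ 10); their samples within the 14-day pre-onset
  window have five *signal taxa* (drawn abundance-weighted, like the
  facultative-anaerobe blooms described before NEC) multiplied by
  exp(2.0) in composition.  Post-onset samples are never generated,
  matching birth-through-onset collection; schedules are redrawn until at
  least one in-window sample exists, so positive bags contain a positive
  instance.
* **Covariates** — drawn to match published preterm-cohort marginals
  (GA ~ N(27, 2.3) weeks, birthweight ~ N(1000, 280) g, etc.),
  independent of the label by default; an optional `covariate_effect`
  knob shifts GA/birthweight in affected infants for stress tests.

All draws come from one `numpy.random.default_rng(seed)` stream in fixed
order, so cohorts are bit-reproducible.  What the simulator does *not*
emulate: strain-level phylogenetic structure, taxon–taxon ecological
interactions, batch effects between sequencing platforms, antibiotic
perturbations, and any real biological identity of the signal taxa.
Passing tests therefore demonstrate that the pipeline recovers a planted
compositional shift under realistic sparsity, overdispersion and
irregular sampling — not that it would achieve the same numbers on any
particular clinical cohort.

## Problem sizes and numerical choices

The default study conditions are 120 infants (~900 samples, 120 taxonomy
nodes), five stratified trials, and full leave-one-patient-out risk
scoring (120 refitted selections and ensembles); the complete battery
runs in a few minutes on one CPU.  Tolerances: CLR level sums are held to
1e-9; attention normalization to 1e-6; permutation invariance of bag
confidence to 1e-9; importance-mass conservation to 1e-9.  Ties in
day-of-life ordering break lexicographically by sample id; attention ties
break toward the earliest sample.  Degenerate inputs fail loudly rather
than silently: empty bags, single-class training sets, non-positive CLR
inputs, and NEC-positive patients without onset days are all errors.

## Known limitations

* The risk recursion is one consistent reading of "dependent on the prior
  risk scores"; the accumulation scale τ and the start value r_init are
  design choices, and operating cutoffs must be chosen above r_init (see
  above).
* The sharp-decrease rule compares consecutive confidences; a
  drop-from-running-peak variant is available in configuration but is not
  the default.
* Gini impurity importances are biased toward features with many distinct
  values; all CLR features are continuous, so the bias is roughly uniform
  here, but comparisons against categorical features would need
  permutation importance (out of scope).
* With heavy feature pruning, importance can sit at coarse ranks
  (genus/family) whose descendants were pruned; species-level reports
  then understate those clades by construction.
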