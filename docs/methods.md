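# Methods

## The prediction problem

Given a features × samples table of microbial gene-family abundances (KEGG
orthologs or reactions) and, for training/evaluation, a paired compounds ×
samples table of metabolite intensities with case/control and study labels,
the package predicts the community's metabolite profile by three routes and
scores every route against the measured metabolome. All identifiers are
namespaced strings (`ko:`, `rxn:`, `cpd:`, `ec:`, `biocyc:`); KEGG-style and
BioCyc-style universes can live in one graph, but queries never cross
namespaces implicitly — a KEGG-referenced and a BioCyc-referenced run are
realized by supplying different reference graphs.

## Relationship graph

The reference is a five-relation graph: KO→reaction, KO→EC, EC→reaction,
reaction→compound (with optional signed stoichiometry) and transporter
KO→compound, plus the *chemical dictionary* — the compound universe from
which random-coverage null draws are taken. Construction deduplicates
records, logs (but tolerates) reactions referenced without compound entries,
and auto-adds dictionary entries for compounds referenced by edges with a
warning. Linkage semantics:

* a function's compounds are the union over its reactions' compounds plus
  its transporter compounds;
* the EC route applies **only** when a function has zero direct reaction
  annotations (a config flag switches to always-union); this fallback
  exclusivity is load-bearing — deleting the EC entries of a KO with direct
  reactions must not change its result;
* reaction direction is ignored for linkage (many reactions run either way
  in vivo), but the signed coefficients are kept for CMP scoring.

Serialization is JSON with sorted keys, so round trips are byte-stable.

## Community metabolic potential

`CMP[c, s] = Σ_{r: c∈r} ν_{cr} · Σ_{f linked to r} a_{fs}` — the
net-production linear form (stoichiometric matrix × gene abundance).
Function→reaction resolution uses the same direct-else-EC-fallback rule as
linkage; transporter edges carry no stoichiometry and do not contribute.
Functions annotated to several reactions contribute to each with no
down-weighting. Edges lacking a coefficient default to +1 with a warning
(or raise, if the default policy is disabled). Gene abundances should be
normalized to copies-per-genome first; `single_copy_normalize` divides each
sample by the median abundance of a supplied universal single-copy marker
set (the inter-sample core of marker-based normalization), and an
externally normalized table is accepted as-is. CMP is linear in abundance
by construction, which the tests exploit.

## Elastic-net regression

Both tables are converted to per-sample relative abundance; features must be
present in strictly more than 10% of samples with mean relative abundance
strictly above 0.01% to enter training. Values are variance-stabilized with
arcsin(√x). One `ElasticNetCV` per metabolite searches a mixing grid
l1_ratio ∈ {0.1, 0.5, 0.7, 0.9, 0.95, 1.0} and a 30-point penalty path by
internal 5-fold CV (folds shuffled by the run seed, so fits are
bit-reproducible). Models are independent per metabolite and must not depend
on fit order. Models selecting fewer than two functions are pruned — a lone
predictor is usually a spurious association. Cross-study generalization uses
leave-one-study-out: each study is held out in turn, filters + transform +
fit + prune run on the rest, and the held-out samples are predicted once
each; predictions are back-transformed with sin²(y) after clipping y to
[0, π/2], so they are non-negative relative abundances. Functions unseen in
training are ignored at prediction time; compounds not modelled in a fold
report 0 for that fold's samples. Per-metabolite prediction-quality
filtering (beyond size pruning) is deliberately not applied by default.

## Differential statistics

* **Prevalence filter** (5% default): a feature detected in *fewer than* the
  threshold fraction of samples is dropped; exactly-at-threshold is kept.
  Presence means |value| > 1e-12, which handles signed CMP matrices too.
* **Function counts**: median-of-ratios size factors (computed over features
  nonzero in every sample, rescaled to geometric mean 1; a 0.5 pseudocount
  fallback is used with a warning when no such feature exists), per-feature
  method-of-moments negative-binomial dispersion pooled across the two
  groups, and a Wald test on the group coefficient of a log-link NB GLM with
  the log size factor as offset. The GLM is fitted by IRLS vectorized across
  features (the design is the same 2-column matrix everywhere, so the normal
  equations are closed-form 2×2 solves); it matches `statsmodels` GLM
  coefficients and standard errors to 1e-6 at fixed dispersion. Fitted group
  means are floored at 0.125 normalized counts so a group with all-zero
  counts keeps a finite, strongly significant coefficient instead of a
  divergent one (the Hauck–Donner collapse); the floor makes very-low-count
  features conservative, which is the acceptable direction. This test is a
  transparent stand-in for DESeq2 — no dispersion shrinkage, no independent
  filtering — and `import_differential` consumes genuine DESeq2 output
  (feature_id/padj TSV) whenever exact replication is wanted.
* **Measured/regression-predicted intensities**: zeros imputed with each
  metabolite's minimum nonzero value across all samples (not per group),
  natural log, two-sided pooled-variance Student's t (Welch is a switch
  away), BH adjustment, flagged at adjusted p ≤ 0.2 (inclusive). All-zero
  metabolites are excluded with a warning. The statistic is invariant to
  positive rescaling of a metabolite (the log shift cancels).
* **Signed CMP matrices**: two-sided Wilcoxon rank-sum, exact when the
  combined n ≤ 20 and tie-free, otherwise the normal approximation with tie
  correction; all-tied compounds get p = 1. The `log2fc` column of this
  table holds the case−control median difference (a signed score has no
  fold change).
* Two-sided testing throughout; BH via the standard step-up.

## Evaluation

Occurrence is presence/absence: predicted and measured compound sets (each
from the 5% prevalence filter; linkage prediction is already a set) are
compared with precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R),
all defined as 0 when empty. Abundance similarity: each matrix restricted to
shared samples → Euclidean distances → classical MDS keeping all
positive-eigenvalue axes → least-squares Procrustes superimposition
(translation, rotation/reflection, uniform scaling) of the two
configurations; m12² is the residual of unit-normalized configurations
(0 identical, near 1 unrelated), correlation = √(1−m12²), and significance
comes from permuting one configuration's sample labels (999 by default)
with empirical p on 1−m12². The implementation agrees with
`vegan::procrustes(symmetric=TRUE)` to 1e-9 (cross-checked in the tests).

Two nulls calibrate the scores, both with 99 replicates and the add-one
empirical p convention `(1 + #{null ≥ observed}) / (n + 1)` (so p is never
0 and lies on the grid {0.01, …, 1}):

* **coverage null** — draw as many compounds as the pipeline predicted,
  uniformly without replacement from the chemical dictionary, and score
  against the measured set;
* **differential null** — for linkage prediction, permute the function-ID
  row labels of the count table and rerun detection → linkage → scoring
  ("shuffle genes"); for abundance pipelines, permute the compound-ID row
  labels of the predicted matrix and rerun the differential test and
  scoring ("shuffle metabolites").

Pipelines are compared across datasets with two-sided Wilcoxon signed-rank
tests on the paired per-dataset metrics (zero differences dropped, exact
for n ≤ 25, NA below two nonzero differences).

## Synthetic data

The generator emulates the statistical structure the benchmark assumes, not
any particular organism. A random reference graph links KOs to reactions to
compounds with signed ±1/±2 coefficients; a fraction of KOs (20% by
default) reach reactions only through EC numbers, 10% are transporters, and
the dictionary carries 20% decoy compounds never linked to anything.
Default shape n_ko = 60, n_rxn = 80, n_cpd = 150 with ~2 reactions per KO
keeps the compound universe large relative to per-function linkage — in a
small dense graph any random function set covers most compounds and the
shuffled-gene null cannot discriminate, which is not how a
thousands-of-compounds dictionary behaves.

Cohorts: function counts are negative-binomial (Var = μ + 0.3μ²) around
lognormal baselines (σ = 1.5) scaled by lognormal library sizes (5×10⁴
median, σ = 0.3); 15% of functions are forced to very low abundance so the
5%/10% prevalence filters actually bite. Planted differential functions
(10 by default) are drawn from below-median-baseline linked functions and
receive balanced fold changes (half × fc in cases, half × 1/fc): a
one-directional block of strongly changed features carrying a large library
share violates the most-features-unchanged assumption every size-factor
estimator rests on and would make the entire community look differential —
a failure of the data, not the test. Each linked compound's latent
intensity is a positive-weight linear mix of 1–3 of its linked functions'
relative abundances (a metabolite tracks a few dominant enzymes) times
lognormal noise (σ = 0.3); dictionary decoys become host-derived
metabolites independent of the community. A detection limit zeroes the
faintest 10% of intensities, and the measured panel is a random 70% subset
of the dictionary — untargeted-coverage censoring applied to compounds, not
samples. Samples are assigned to studies in blocks balanced over
case/control. Identical parameters and seed give byte-identical outputs.

What the generator does **not** emulate: taxon structure and
taxon–function coupling, compositional coupling between metabolites beyond
the shared denominators, batch/platform effects between studies, and a
realistic dictionary-to-measured size ratio — measured compounds span most
of the synthetic dictionary, so the random-coverage occurrence null is
competitive with linkage-based occurrence prediction here, unlike in a real
setting where the dictionary is orders of magnitude larger than any one
study's panel. Passing tests therefore demonstrate the correctness and
calibration of the machinery, not field performance on real cohorts.

## Numerical and design choices

* "Over 10%" / "over 0.01%" training filters are strict inequalities;
  "fewer than 5%" evaluation filtering keeps exactly-at-threshold features.
* Significance flags use adjusted p ≤ α (inclusive), α = 0.2.
* The linkage occurrence set (a pure set) is compared on equal footing with
  the abundance-derived occurrence sets of the other pipelines.
* One global seed fans out to per-stage child seeds via a SHA-256 hash of
  the stage name (all below 2³¹), so adding a stage never perturbs earlier
  stages' randomness and whole benchmark runs are reproducible.
* PCoA axes with non-positive eigenvalues are dropped; configurations are
  zero-padded to a common width before superimposition.
* Degenerate inputs: empty tables predict nothing (with a warning);
  constant metabolites are skipped by the regression; all-tied compounds
  get rank-sum p = 1; a sample with zero marker median is a hard error
  naming the sample.

## Problem sizes

Tests and the acceptance script run the benchmark on cohorts of 60 samples
(30 case / 30 control, 2 studies) over ~60 functions and ~180 dictionary
compounds, with 99-replicate nulls and up to 999 Procrustes permutations —
sizes chosen so the full suite exercises every code path, including the
heavy permutation machinery, while a complete run stays in the
tens-of-seconds range on one core.
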