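# Methods

`igomeprof` implements a pipeline for profiling the public IgM repertoire
(the "igome") with rationally designed peptide mimotope libraries: from
phage-display deep-panning reads, through motif clustering of the selected
7-mer mimotopes, to probe-library design, peptide-microarray reactivity
processing, and diagnostic profile extraction. This note documents the
models, the numerical choices, and what the synthetic-data validation does
and does not establish.

## Read processing and the copy-number window

Amplicon reads carry the 21-nt peptide-coding insert between fixed vector
flanks. A read contributes a peptide only when both flanks occur exactly
once and the insert translates cleanly (no ambiguous bases, no stop codon);
drops are counted per reason rather than raised. Ph.D.-series display
libraries are propagated in supE hosts, where the amber stop TAG is read as
glutamine; translation treats TAG as a stop by default (conservative) with
an `amber_suppression` flag for the supE reading.

Unique peptides are tallied and filtered to a strict copy-number window,
default (2, 11) exclusive: the lower bound suppresses sequencing-error
singletons/doubletons, the upper bound removes overgrown phage clones whose
abundance reflects growth advantage rather than binding. The thresholds are
plain configuration; no automatic derivation from copy-number distributions
is attempted, because only the outcome of such a derivation is known for
the reference datasets.

## Composition statistics

Residue frequencies are maximum-likelihood counts, overall or by position.
Backgrounds come from three sources: uniform (q = 0.05), the NNK
degenerate-codon scheme of the display library (32 codons, one amber stop;
frequencies conditioned on coding codons so they sum to one), or observed
frequencies of an unselected amplified library (add-one smoothed, optionally
positional). Log-odds matrices are pseudocount-smoothed:

    LO_pa = log2( ((n f_pa + beta q_a) / (n + beta)) / q_a )

with beta = 50 background pseudocounts by default for composition displays.
When the background carries positional frequencies, each column is compared
against its own background column, which cancels positional biases shared
with the unselected library (e.g. the N-terminal skew and proline abundance
that are properties of the amplified library, not of antibody selection).

## Gibbs clustering and the KLD criterion

Peptides are all length 7 and anchored (the arrays are synthesized
C-terminus down), so clustering is ungapped: no insertions, deletions or
offsets, a deliberate restriction of the general Gibbs motif aligner.

Each cluster is summarized by a position count matrix smoothed with
beta = 10 background pseudocounts (default; comparable to the
tens-of-members clusters targeted at desk scale). Clusterings are compared
by the size-weighted information content of the cluster PWMs,

    KLD = sum_g (N_g / N) sum_pos sum_a f'_g[pos, a] log2(f'_g[pos, a] / q_a),

a Kullback-Leibler divergence of the smoothed cluster models from the
background. Two candidate criteria were considered. The mean per-peptide
own-cluster log-odds score is superficially attractive but is, at the
optimum, non-decreasing in the number of clusters G — adding clusters can
only raise member scores — so a scan over G cannot peak; this was confirmed
empirically (better optimization made planted-cluster-number recovery
worse). The PWM-information criterion penalizes fragmentation through the
pseudocount shrinkage (small clusters are pulled toward the background and
contribute little), so the scan exhibits a genuine maximum. The smoothing
weight trades off against cluster size: beta comparable to the expected
cluster size favors merging (the two-motif example with clusters of ten
needs beta of about 2), while beta much smaller than the cluster size
under-penalizes splinters. The default of 10 suits the 30-50-member
clusters of the validation experiments; callers clustering much smaller or
larger sets should scale it.

The sampler anneals the criterion directly: one sweep visits each peptide
in random order, removes it from its cluster, computes the exact criterion
value for every candidate destination (an O(G·L·20) incremental update) and
resamples the assignment with probability proportional to 2^(KLD/T) under a
geometric temperature ladder (T0 = 1.5 to Tfinal = 0.01, 50 sweeps, 3
restarts by default). The best state by the criterion across all sweeps and
restarts is returned; runs are deterministic per seed. Because moves target
the criterion itself, the annealed optimum can be compared directly with an
exhaustive search over all G^n labelings on tiny instances; agreement is
100/100 runs at n = 10, G = 2 in the shipped validation.

The per-peptide score (sum of own-cluster log-odds, leave-one-out counts)
and the corrected score — own-cluster score minus the best rival cluster's
score, a margin that flags peptides uncertain to belong anywhere — are
reported per member. With G = 1 the corrected score is defined as the own
score.

## Cluster significance and library design

Clusters are ranked by the improbability of their score coherence under the
background: for each cluster, t is the median member PWM score; p0 the
probability (estimated from M >= 10^4 seeded background draws, add-one
smoothed) that a background peptide exceeds t; and p the upper binomial
tail of seeing at least the observed number of above-median members among
all N library peptides. Clusters with p < 1e-4 are significant; ranking is
by ascending p with ties broken by larger membership, then higher mean
member score. The "trials = all N library peptides, successes = members
above the cluster's own member median" operationalization is this package's
reading of a briefly stated test; it is deliberately conservative in
treating every library peptide as a chance to hit the cluster's profile.

Libraries:

- **SYM** — the top-scoring member of each of the k_top best-ranked
  significant clusters (default 519, the count that fits a five-field,
  600-peptide array layout after controls), plus a set of negative-control
  peptides (75 NGR members by default, giving 594). Duplicate
  representatives backfill from the affected cluster's next-best member.
- **NG1 / NG2** — the weakest member of each significant cluster; NG2
  keeps those with corrected score < 5 (probes least certain to belong to
  any cluster).
- **C5 / C5P** — whole clusters by id; and background peptides
  rejection-sampled until they score above the respective cluster's member
  median (150 per cluster by default) — probes that test whether the PWM
  profile alone captures the binding phenotype.
- **NGR** — anti-selected negatives: among n_candidates background draws
  (2e6 by default), the m (753) peptides whose maximum score over all
  cluster PWMs is lowest.
- **RND** — plain background draws (800).

All random draws use the display library's NNK residue frequencies, and all
designs are deterministic given (state, seed).

## Peptide space

Peptides embed as 35-dimensional vectors (five principal-property z-scales
per residue — hydrophobicity, steric bulk, polarity and two electronic
factors — by seven positions, position-major). The z-scale table is bundled
in source. t-SNE (scikit-learn, perplexity 30, 1000 iterations, PCA
initialization, seeded) is provided for visualization only and enters no
tested numerics. Classical (Torgerson) multidimensional scaling —
double-centering of squared distances and eigendecomposition — serves both
for metric-preserving 2-D maps and for building the two surrogate features
the diagnostic classifier uses; negative eigenvalues are clipped and a raw
stress value can be reported.

## Reactivity pipeline

GenePix results tables (GPR/ATF dialect) parse into typed spot tables.
Per-array cleaning: flagged spots dropped; signal = log2(max(F - B, 1));
per-block median centering to the array median (the "local" normalization,
removing print-tip and regional offsets); duplicate spots merged by mean
with a CV > 0.5 quality flag (CV on the linear scale); peptides left with
no unflagged spot are imputed at the array median and logged. Between
arrays, quantile normalization forces a common empirical distribution (the
"global" step); it is idempotent and makes sorted columns identical by
construction. This local+global contract is this pipeline's normalization
definition — the original analysis scripts' exact steps are not public, so
the contract is stated here and tested against planted spatial offsets.

Batch adjustment is parametric empirical-Bayes ComBat: per-feature
standardization against a model with batch indicators and optional
preserved covariates (e.g. diagnosis), EB shrinkage of per-batch means and
variances toward across-feature priors (iterative solve), adjustment and
restoration. The implementation was cross-checked against the Bioconductor
reference on a shared fixture (agreement to 6e-7). Group balancing before
adjustment is an explicit subset-selection utility, not automatic.

Per-patient reactivity calls: for each peptide and sample, z = (x -
mean_rest) / sd_rest against the remaining samples, two-sided normal p, and
Benjamini-Hochberg FDR within each sample at q = 0.05. Zero-variance
peptides are marked non-significant and logged.

## Library evaluation

Three criteria compare libraries on a shared reactivity matrix: (1) mean
peptide reactivity, compared by a one-way fixed-effects model with
single-step Tukey contrasts; (2) mean nearest-neighbor distance (MNND) of
peptide profiles, computed on per-sample standardized values so shape
rather than magnitude is compared — low MNND means redundant probes; (3)
mean Fisher-z-transformed correlation between patient profiles restricted
to the library — low values mean the library individualizes patients.
Ranking directions: higher reactivity, higher MNND, lower mean z are
better. The rank product (geometric mean of a library's ranks) is tested
against independent uniform ranks — exact enumeration of all L^k rank
tuples when L^k <= 1e6, else >= 1e5 seeded permutations. This null treats
the three criteria as independent, which is an approximation the original
rank-product permutation scheme does not need; with L = 8 and k = 3 the
exact tail for the best observed tuple (ranks 1, 2, 1; RP = 1.26) is
4/512 ≈ 0.0078.

## Diagnostics

Feature selection is two-stage. The filter keeps peptides significantly
reactive in at least one patient (it is label-free and near-permissive on
serum data, where individual variation makes most probes significant
somewhere). The wrapper is greedy backward elimination followed by forward
re-addition, maximizing a separation criterion of the diagnosis dichotomy
on z-scored selected features; removals are accepted while the criterion
does not decrease (so redundant features are pruned), re-additions only on
improvement > 1e-6; ties break by feature id, making runs deterministic.

The separation criterion is the worst-class silhouette: per-sample
silhouette widths (Euclidean, z-scored features) averaged within each class,
minimum over the two classes. The plain mean silhouette was evaluated first
and found degenerate under greedy maximization: one tight class suffices to
score well, so single lucky features win and every elimination run
collapses to one or two features. Requiring both patient clusters to be
coherent rewards precisely the convoluted multi-feature signatures this
method targets — no single reactivity separates a diagnostic group, but a
pool of partially penetrant reactivities does.

Selection stability is probed by a leave-one-out bootstrap: one RFE-derived
set (RFEDS) per left-out sample; consensus(n) keeps features present in at
least n sets, and n is swept rather than auto-picked. The classifier is a
linear SVM (C = 1, balanced class weights) fitted on two surrogate features
obtained by classical MDS of the consensus-feature profiles; the 2-D
reduction is what keeps a model testable with few held-out cases and
measurably controls overfitting. Performance is the Matthews correlation
coefficient, with a null band from 1000 (default) label permutations
refitting the identical construction; the 5th/95th percentiles bracket
chance performance. The number of distinct presence/absence profiles
expressible with ~500 significant reactivities and profile sizes in the
observed 28-111 range is computed by exact big-integer arithmetic and
exceeds 10^70.

## Homology classification

BLAST tabular output (outfmt-6 with named fields) is filtered to
near-full-length ungapped hits (>= 6 identities, >= 6 positives, no gaps)
before classification: 'Ig' if any retained hit's subject title matches an
immunoglobulin pattern (a configurable case-insensitive list covering
heavy/light chains; in practice most such hits fall in J/CDR3-proximal
segments), else 'non-Ig', else 'no-hit'. Library proportions are compared
by Pearson chi-square with BH-adjusted pairwise 2x2 follow-ups. Running
BLAST itself is out of scope; a command template ships in the module
docstring.

## Synthetic data: what it emulates, and what passing tests show

The selection simulator plants K motif PWMs (information-rich at 2-4
positions, cluster-specific residues drawn from disjoint pools so planted
motifs are genuinely distinguishable), samples member peptides and optional
background clones, assigns heavy-tailed log-normal multiplicities
(phage amplification), reverse-translates through NNK codons and applies
per-base substitution errors. Indels are not simulated: they break the
fixed-length frame and are dropped upstream in any case. PCR chimeras and
position-dependent error profiles are not modeled.

The reactivity simulator plants per-peptide baselines, iid Gaussian noise,
additive batch offsets, duplicate spots with multiplicative noise, and a
diagnosis effect that can be a mosaic: each discriminative feature is
elevated in a configurable fraction of target-group samples. Private
per-feature spikes reproduce the observed serum behavior that almost every
probe is significantly reactive in some patient. Correlated peptide
families, sample-level titer differences and scanner artifacts are not
modeled.

Validation experiments (frozen in `igomeprof.experiments`, reported by
`scripts/acceptance.py`) run at desk scale: selections of 120-150 peptides
instead of 2e5, cluster-number grids of 2-5 instead of 100-2500, cohorts of
38 samples on 40-peptide panels, 10^4-10^5 Monte-Carlo draws. The
diagnostics cohort uses groups of 15 GBM / 17 controls (28 in training,
matching the reference cohort size), a 10-feature mosaic signature at 4.4
noise-SD effect with 75% coverage, and one 6.5-log2-unit spike per feature.
Passing these experiments shows the algorithms recover planted structure
under the stated noise models at these sizes; it does not certify
performance on full-scale NGS data, on real serum arrays, or under noise
the simulators do not generate.

## Known limitations

- The KLD criterion's pseudocount couples to expected cluster size (above);
  very small or very large clusters need a rescaled beta.
- The rank-product null assumes independent criteria.
- C5P rejection sampling aborts (with a diagnostic) when a cluster is so
  tight that background acceptance falls below 1e-6.
- The per-patient z-test assumes approximate normality of the rest-pool;
  heavy-tailed reactivities inflate the FDR slightly (the null calibration
  test bounds the per-sample significant fraction at 0.07 for q = 0.05).
- `corrected_score` margins depend on the rival clusters present; they are
  comparable within one clustering state only.
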