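# Methods

This note documents the models, estimators and design choices in
`predgeom`, what the synthetic-data generator does and does not emulate,
and the numerical conventions that matter for reproducing its output.

## Stimulus streams

Both streams use a 12-tone whole-tone alphabet (C, D, E, F#, G#, A# over
the 4th/5th piano octaves, 261.63–932.33 Hz). Streams are built from
triplets of three distinct tones; the default length is 800 triplets
(2400 tones at one tone per 333 ms), with every tone occurring exactly
200 times, no immediate tone repeats, no immediate triplet repeats, and
every triplet confined to one octave.

*Octave constraint.* Implemented on the index lattice: adjacent alphabet
entries are one whole tone apart, so a triplet is octave-legal iff its
index span is ≤ 6. The equal-tempered frequency table puts the exact
octave at ratio 2.00002, so a literal ratio ≤ 2 test would spuriously
reject exact-octave triplets that the musical constraint intends to
allow.

*High regularity.* The 12 tones are partitioned by rejection sampling
into 4 disjoint ordered octave-legal triples (disjointness is forced by
the exact-count constraint: 4 types × 200 repetitions × 3 tones = 2400).
The 800 type tokens are shuffled uniformly and adjacent duplicates are
repaired by local swaps, which preserves type frequencies. Three
counterbalanced within-triplet orders are exposed via `variant`
(cyclic rotations); analyses are variant-agnostic.

*Low regularity.* Each triplet is drawn fresh. Because edge tones of the
alphabet belong to far fewer octave-legal triples, naive quota-weighted
sampling strands their quota; instead each triplet is anchored on the
tone with the largest remaining quota, partners are sampled
quota-weighted from the legal set, and the final few triplets are
completed exactly by randomised backtracking. Counts come out exactly
balanced; a bounded number of full restarts handles residual jams.

## Ideal observer

A softmax perceptron over the alphabet; weights start at the uniform
prior 1/12. Per transition: ŷ = softmax(x_t·W); the learning rate ω is
the Shannon entropy of ŷ (nats, so ω ∈ [0, ln 12]); the weight update is
the entropy-weighted cross-entropy gradient, applied only to the active
input row. Natural logarithms are used throughout the observer. The
conventions are chosen so that learning *descends* the cross-entropy;
with them, prediction error decays and accuracy rises on regular streams,
and the trained weight rows converge (softmax-transformed) to the
empirical transition probabilities.

Two scalarisations of the matrix-valued PE are provided:
`entropy_weighted_norm` (default) — ω·‖ŷ − x_{t+1}‖₂, the Frobenius norm
of the update, exact because the gradient has a single nonzero row; and
`entropy_weighted_surprise` — ω·(−ln ŷ[next]). Both decay exponentially
on the high-regularity stream; the norm variant is the default because
its magnitude equals that of the actual weight update. The first tone of
a stream elicits no error; the trajectory is aligned to the tone that
elicits the error, and the first epoch is dropped from encoding analyses.

*Decay-model comparison.* y = a·e^(−bx) + c is fitted by unbounded
nonlinear least squares with 100 random restarts (best RSS wins); the
linear model in closed form. BIC = n·ln(RSS/n) + k·ln(n) with k the
number of mean-function parameters (3 vs 2); the Gaussian σ term cancels
in the comparison. A floor of 1e−12 on RSS guards degenerate perfect
fits. On default high-regularity streams the exponential model wins by
~180 BIC points (e.g. −3628 vs −3449 at seed 7); the absolute BIC level
depends on the PE scalarisation, the ordering does not.

## Synthetic source-level epochs

The generator emits trials × 72 parcels × 77 time samples (−50…330 ms at
200 Hz) per subject and condition, with planted, recoverable structure:

- **Evoked tone patterns.** Each tone has a random 72-parcel pattern
  (scaled by `pattern_snr`, default 1.0 against unit noise) carried by a
  Gaussian kernel peaking at 100 ms (sd 20 ms).
- **Learning morph.** In the high-regularity condition only, tone
  patterns morph linearly toward their triplet centroid across the 5
  blocks (0 → `gamma_max`, default 0.6), restricted to a 110–130 ms band
  so the planted chunking effect has the intended latency.
- **PE-coupled gain.** A designated *encoder region* — one anchor parcel
  plus its 5 nearest neighbours, i.e. exactly one searchlight (default
  anchor 20) — carries a consistent-polarity evoked offset
  (`encoder_offset`, default 1.0) and a multiplicative trial gain
  1 + β·PE_z (`beta_pe`, default 0.5). The clustered layout is
  deliberate: the PE trajectory is strongly predictable from tone
  identity alone (≈60% of variance in the high-regularity stream), so
  every tone-decoding searchlight carries substantial copula MI about PE;
  only a multi-parcel coupled region pushes the planted searchlight
  decisively above that floor. Scattered single-parcel encoders are not
  reliably localisable by any rank-based estimator at realistic gains.
- **Synergistic pair.** Parcel i receives shared noise + coupling·PE_z,
  parcel j the same shared noise alone (defaults: parcels 10/46, shared
  sd 3.0, coupling 2.0). Each parcel alone is dominated by the shared
  noise; their difference isolates the PE, which is the signature of
  synergy. All planted trial-wise components ride on the evoked kernel,
  so they vanish in the −50–0 ms baseline.
- **Noise.** Gaussian with exponential spatial covariance over centroid
  distance (`noise_spatial_scale`, default 2.0) and optional AR(1)
  temporal correlation (default off).

Virtual subjects differ by seed offsets; the default cohort is 24, the
test/demo cohort 8. The epoch window extends to −50 ms so that the
baseline and the 90–120 ms analysis windows coexist in one array.

*What the generator does not emulate:* 1/f spectra, sensor-level physics
and beamformer leakage, evoked-latency variability, non-Gaussian noise,
inter-subject anatomical variability, and overlap of adjacent-tone
responses (the real pre-tone baseline contains the previous tone's
activity; the synthetic one is signal-free). Consequently, passing tests
show that the estimators recover what they are designed to measure under
their own assumptions — not that those effects are detectable in any
particular real recording.

## Representational similarity analysis

Per learning block (5 contiguous equal partitions in presentation order)
and time sample: 10-fold cross-validated Mahalanobis distance, folds
stratified by tone as contiguous chunks in trial order (preserving
learning-stage homogeneity within folds). The noise covariance is
estimated per fold from training-set residuals (trial minus tone mean),
pooled across all 12 tones — pooling maximises the sample for a
72-feature covariance — and shrunk by the Ledoit–Wolf method per time
point. The crossnobis estimator is unbiased: null distances centre on 0
and negative values are legitimate.

RDMs are reordered to the high-regularity triplet inventory
(triplet 1 tone 1, …, triplet 4 tone 3). "Within" is the mean over the
six unordered same-triplet pairs; "between" the mean over cross-triplet
pairs; exact self-distances are excluded everywhere (they are 0 by
construction and carry no geometry). The model RDM (0 within, 1 between)
is fitted by Spearman correlation on the off-diagonal upper triangle;
positive values mean within < between. Learning slopes are OLS against
the block counter 1…5. The searchlight uses each parcel plus its 5
nearest neighbours with the data averaged over the analysis window
(110–120 ms, i.e. samples at 110/115/120 ms on the 5 ms grid).

When trial counts per tone per block fall below the fold count (possible
in short low-regularity streams), the pipeline reduces the fold count to
the rarest tone's count with a warning, rather than failing.

## Information estimators

*Copula normalisation:* per column, ranks (average over ties) mapped
through Φ⁻¹(r/(n+1)) — the r/(n+1) convention keeps quantiles finite.
GCMI in bits follows the closed Gaussian form; determinants go through
`slogdet` with a relative floor of 1e−12, raising a conditioning error
rather than clipping silently. Raw GCMI is a lower bound on MI, invariant
to strictly monotone marginal transforms; no small-sample bias correction
is applied — baseline subtraction (mean estimate over −50–0 ms) is the
sole correction.

*PID:* for continuous copula-normalised data, redundancy is the
minimal-MI functional R = min(MI(X1;Y), MI(X2;Y)) — the standard closed
Gaussian choice, coinciding with Williams–Beer I_min for univariate
Gaussian sources; unique and synergy atoms follow by subtraction, so the
accounting identity R + U1 + U2 + S = JMI holds to machine precision by
construction. The exact discrete I_min over pointwise specific
information is implemented separately and kept as a brute-force oracle.
Network atoms are computed per 5 ms sample in the 90–120 ms window,
averaged, and baseline-corrected atom-wise. Negative corrected weights
are clipped to 0 before betweenness centrality (1/weight path lengths
need positive weights); the raw matrices are preserved. Node strength
(mean edge weight) is reported alongside betweenness, as the two common
readings of "hub" on such networks.

A property of min-MI redundancy worth noting: because the tone-driven
component of PE is encoded everywhere, all parcel pairs share a
redundancy floor, and the *global* redundancy mean can exceed the global
synergy mean in the high-regularity condition even though the planted
pair is unambiguously synergistic. The planted-structure tests therefore
target the matrix extremes, not the global means.

## Group statistics

Cluster-based permutation: element-wise paired t, parametric two-tailed
cluster-forming threshold at α = 0.05 with subjects − 1 df (the standard
mass-univariate convention; only the global α is externally specified),
clusters formed separately for positive and negative t under the supplied
adjacency (chain for time courses; for parcel maps, pairs within a
centroid-distance quantile, default 10%, exposed as config since no
anatomical neighbourhood is canonical here). Maxsum is the cluster
statistic; the null is the maximum |maxsum| under random sign flips of
subject-level differences; p = (1 + #{null ≥ obs})/(1 + n_perm).
Sign-flip t fields are computed vectorised (the per-element sum of
squares is flip-invariant), which keeps 200-replicate calibration runs
cheap. NBS thresholds edge-wise paired t two-tailed at a configurable
edge α (default 0.05) and uses the suprathreshold component's edge count
as statistic. Both procedures are calibrated: family-wise type-I error
within the binomial 95% CI of 5% over 200 null replicates.

Correlations between per-subject scalars are right-tail Pearson with
Bonferroni multiplication. The representational-shift scalar entering
those correlations is the cluster-averaged model-RSA block slope
(cluster = contiguous parcels surpassing the uncorrected threshold in the
first step of the cluster test); the negative within-triplet slope is an
equivalent alternative selectable in config.

## Problem sizes

Defaults in the orchestrated demo (`predgeom run`, `RunConfig`): 200
triplets (600 trials/condition), 8 virtual subjects, 5 folds, 1000
permutations — a full run completes in about a minute on one CPU while
exercising every stage. The study-scale settings (800 triplets, 24
subjects, 10 folds, 10 000 permutations) are plain config values. The
acceptance script uses the full 800-triplet streams; the test suite uses
the reduced cohort.

## Known limitations

- The Gaussian-copula estimators capture monotone dependence only;
  strongly non-monotone encodings (e.g. pure gain on zero-mean signed
  patterns) are invisible to them, which constrains what the generator
  can usefully plant (see the encoder-region rationale above).
- Min-MI redundancy is the weakest valid redundancy functional; it upper-
  bounds I_min-style alternatives for correlated sources and makes global
  redundancy/synergy means sensitive to common drivers of the target.
- The low-regularity constructor is stochastic constraint satisfaction;
  pathological parameter combinations (very short streams with tight
  quotas) fall back on restarts and can, in principle, exhaust them.
- PID here is strictly pairwise; higher-order decompositions and directed
  (lagged) variants are out of scope.
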