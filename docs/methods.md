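# Methods

This note documents the models, algorithmic choices and defaults behind
`topoplast`, and what the synthetic-data tests do and do not establish.

## Data model and conventions

An `ErpDataset` holds per-subject ERP averages for the full crossing of
Stimulus (puff, sham) × Side (more, less affected hand) × Session (pre,
post intervention), on a uniform time grid.  Times are milliseconds
relative to stimulus onset; sample *i* covers `start + i/rate·1000` ms on
a half-open grid, so onset (t = 0) belongs to the post-stimulus period.
A window `(a, b)` selects samples with `a ≤ t < b`.

Structural preprocessing is limited to what operates on ERP averages:

* **Average reference** — subtract the spatial mean at every sample;
  idempotent.  All metrics subtract the spatial mean internally as well,
  which is what makes "root mean square across the montage" and "spatial
  standard deviation" the same number and every quantity independent of
  the recording reference.
* **Laterality relabeling** — subjects differ in which body side is more
  affected; swapping left–right homologous channel rows for subjects
  whose affected side is not the configured reference side anchors the
  hemisphere contralateral to the more affected hand across the group.
  The homologous-pair table is user-supplied (two-column text); the
  synthetic montage ships its own.  The reference side is a free config
  choice (`left` by default in the examples) — nothing hinges on it, and
  relabeling commutes with average referencing.
* **Inclusion filter** — a subject is kept only if *every* condition has
  at least `min_trials` (default 12, boundary inclusive) usable trials;
  exclusion is dataset-wide and logged.

Spectral filtering, artifact screening and channel interpolation are
upstream concerns of whatever produced the averages, not of this package.

## Field metrics

With maps average-referenced, `GFP(u) = sqrt(mean(u²))`;
`normalize_by_gfp` divides by it (maps with GFP below 1e-12 are flagged
as degenerate rather than silently zeroed — division by instantaneous
GFP is undefined there, and downstream fitting marks such samples
unlabeled).  `DISS(u, v)` is the RMS difference of the unit-GFP maps;
`spatial_correlation` is the Pearson correlation across channels, and the
identity `DISS² = 2(1 − r)` holds to float precision (asserted at 1e-9 in
the tests).

## Sample-wise statistics and the duration criterion

GFP is analyzed with a classical repeated-measures Session × Side ANOVA
at every sample.  Both factors have two levels, so each effect has one
numerator degree of freedom and its F equals the squared paired t of the
per-subject contrast — exact, sphericity-free, and vectorizable across
time.  Higher-order ANOVAs (the 3-way Map × Session × Side) go through
`statsmodels`' `AnovaRM`; both routes are checked against a brute-force
sums-of-squares oracle.

Sample-wise testing needs multiplicity control: only maximal runs of
consecutive sub-alpha samples lasting at least `min_duration_ms`
(default 20 ms, inclusive — a 19 ms run dies, a 20 ms run survives) are
reported.  A run touching the window edge counts if its observed length
reaches the threshold.  No further correction is applied.

## TANOVA

Per sample, each subject-condition map is average-referenced and scaled
to unit GFP; the effect statistic is the GFP of the contrast of cell-mean
maps (double difference `(m₁₁ − m₁₂ − m₂₁ + m₂₂)/4` for the interaction,
half the marginal-mean difference — same ±1/4 coefficients — for main
effects).  For unit-GFP maps this is a generalized-dissimilarity measure
of the effect topography (`DISS² = 2(1 − r)`); it is exactly 0 when the
cell means coincide.

The null distribution comes from restricted permutations that never break
subject identity: swapping the tested factor's labels within a subject
(consistently across the untested factor) flips the sign of that
subject's contrast map, so the scheme reduces to the exact sign-flip
randomization of per-subject contrasts.  This is valid in the presence of
the other effects because the tested contrast annihilates them.  A
superficially attractive alternative — residualizing within subject and
permuting the four residual maps across cells — is *not* valid: a 2×2
within-subject cell structure has a single residual degree of freedom per
subject (the cells carry ±w), so cell permutations send two thirds of the
subject contributions to exactly zero and the null is biased low.  We
verified this empirically (whole-epoch false positives on null data)
before adopting the sign-flip scheme, whose per-sample type-I error is
0.047 at α = 0.05 in the calibration run (theoretical value with 999
permutations and the add-one rule: 0.049).

p-values use `(#{null ≥ observed} + 1)/(n_perm + 1)` (never zero; default
999 permutations, mandatory seed), and significant runs pass the same
20 ms criterion.

## Clustering, model selection, back-fitting

**AAHC.**  The condition-mean maps in the analysis window (default
250–550 ms, the four puff cells) are GFP-normalized — the segmentation is
sensitive to topography only — and start as singleton clusters.  At each
step the *worst* cluster is dissolved and its members reassigned to the
remaining cluster with the highest signed spatial correlation; centroids
are the renormalized signed means.  Polarity is treated as meaningful
throughout (evoked responses, unlike spontaneous microstates, do not
identify a map with its inversion), and no orthogonality of templates is
assumed.

"Worst" is defined as the cluster whose dissolution *loses* the least
explained variance, i.e. `Σ w_i (r²_own − r²_next-best)` over members,
with GFP² weights.  The naive alternative (smallest summed GEV) fails in
a characteristic way: the same template recurring in several condition
cells enters as separate chunks that AAHC, which never merges, keeps as
near-duplicates; under the summed criterion a genuine low-amplitude
template cluster is then dissolved while duplicates persist.  Under the
loss criterion duplicates cost ≈ 0 and go first; planted-template
recovery is 50/50 seeds with matches ≥ 0.95 at the default noise level.

**Model selection.**  For each candidate k the within-cluster dispersion
is `W(k) = Σ DISS²(member, centroid)`.  The modified Krzanowski–Lai index
is the ratio of successive drops of the scaled curve,
`KL(k) = DIFF(k)/DIFF(k+1)` with
`DIFF(k) = (k−1)^(2/m) W(k−1) − k^(2/m) W(k)` and m the topographic
dimensionality (channels − 1 under the average reference; the exponent is
near 0 for any realistic montage).  The index is forced to zero at the
ends of the candidate range, wherever dispersion fails to decrease, and
wherever the drop at k is below 5 % of the total dispersion span — in the
flat tail both DIFF values are noise and their ratio is meaningless, and
at desk scale a 1 % floor still let tail ratios beat genuine elbows.  A
second-difference variant was tried and rejected (biased toward k = 2
when the dispersion decays geometrically).  Ties break toward the
smaller k; a fully flat curve (single template) falls back to the
smallest candidate with a warning.

**Back-fitting.**  Every single-subject sample in the window is labeled
with the template of highest signed spatial correlation; spatially
constant samples stay unlabeled, and on an exact tie the previous
sample's label wins if it is tied (temporal stability), else the lowest
index.  No temporal smoothing or minimum segment length is imposed.
Durations are fractions of window samples per map (summing to 1 with the
unlabeled share).

**Duration statistics.**  The 3-way Map × Session × Side within-subject
ANOVA uses the template maps as the Map factor; because fractions sum
to 1 within each cell, effects that average over Map are exactly
degenerate (0/0) — their rows are reported as NaN and the unlabeled share
is excluded.  Each map then gets a 2×2 Session × Side ANOVA with partial
η², plus paired two-sided contrasts: pre-intervention more vs. less
affected, and post vs. pre within each hand.  "Clinically relevant" maps
are those with a significant interaction *and* a significant
pre-intervention hand difference.

## Brain–behavior

Six measures with their natural units and directions: somatosensory
registration (grams, lower better), single-point localization (0–4),
two-point discrimination (mm, lower better), stereognosis (0–9), pinch
and grip (psi).  Between-hand comparisons are one-tailed paired t tests
with the directional hypothesis that the less affected hand performs
better, applied after orienting every measure so that higher means
better.  Pre/post changes are two-sided.  Spearman correlations pool the
two hands of each subject as individual points (2 × n subjects);
inference is by exact permutation up to 8 points, a seeded 10 000-draw
permutation up to 10, and the t approximation beyond (the pooled analyses
have 18–20 points).  The independence of the two hands' values, which
motivates pooling, is reported as a diagnostic correlation, not enforced
as a gate.

## The simulator

`generate_erp_dataset` builds each subject-condition ERP as
`envelope(t) · template(t) + noise`, then average-references:

* **Templates** — mutually orthogonal unit-GFP maps in the zero-mean
  channel subspace (random, seeded), plus a shared background map used
  outside the analysis window.  Orthogonality is a convenience, not an
  analysis assumption.
* **Occupancy** — within the analysis window each condition realizes its
  scheduled fractions as contiguous blocks.  The block order is drawn
  once per *distinct* schedule and shared across subjects: component
  latencies are broadly consistent across participants, which is what
  lets template periods survive group averaging (fully subject-random
  orders would make group-level template recovery impossible by
  construction); cells with identical schedules also share the order, so
  they differ only by noise and jitter — a true sample-level null, which
  is how the sham cells and the calibration configurations are built.
  Per-subject Dirichlet jitter (precision κ = 60 by default) varies the
  realized fractions around the schedule and de-aligns block boundaries.
* **Envelope** — one nonnegative GFP time course for *all* conditions
  (Gaussian bumps at 120 and 400 ms, peak ≈ 3 µV, the late bump wide
  enough to keep maps strong across 250–550 ms), so response strength
  carries no condition information by construction.
* **Noise** — independent Gaussian per channel and sample (σ = 1 µV
  default), re-average-referenced; a config hook provides AR(1)-style
  spatial correlation for robustness checks.  White noise is the minimal
  assumption; nothing in the analysis depends on it.
* **Laterality** — half the cohort is assigned a right-side impairment
  and stored in native channel space, so the relabeling step does real
  work; ground truth stays in the common space.
* **Default crossover** — puff occupancy (map1, map2, map3):
  more/pre = less/post = (0.90, 0.05, 0.05) and
  less/pre = more/post = (0.05, 0.55, 0.40); sham cells share a flat
  schedule.  The paired cells share schedules *exactly* because the
  emulated finding is that the post-intervention more-affected response
  resembles the reference condition; sharing the schedule (hence the
  block order) is what produces the moment-by-moment spatial-correlation
  signature.  These effect sizes are illustrative, chosen once for
  detectability at n = 10 — the original study reports no occupancy
  effect sizes, so recovery tests certify the machinery, not the
  magnitude of any clinical effect.

Behavioral scores come from a Gaussian copula on the designated map's
realized duration: `z = ρ_p z_dur + sqrt(1 − ρ_p²) ε` with
`ρ_p = 2 sin(π ρ_s/6)`, so the population Spearman correlation equals the
configured link (default grip −0.6, pinch −0.6, stereognosis −0.4 to
map 1); ε is shared across sessions up to an innovation (σ = 0.3), which
gives pre/post changes a planted link as well.  Latents map to natural
scales by strictly monotone transforms (Spearman-invariant); count-valued
tests are rounded, which can only attenuate.  Optional explicit hand and
pre/post shifts support null-link scenarios.  Usable-trial counts are
shifted-Poisson (`6 + Poisson(14)`), putting realistic mass around the
12-trial threshold.

## Problem sizes and numerical choices

Tests and the acceptance suite run the desk-scale geometry — 32 channels,
250 Hz (16 channels and shorter epochs for the statistics-heavy
calibrations); the study-faithful 128-channel/1000-Hz geometry is a flag
(`default_config(paper_scale=True)`) and changes nothing structural.
Calibration uses 500 seeds × 999 permutations; recovery runs use 20–50
seeds.  Degenerate-map tolerance is 1e-12 (absolute GFP); analytic
identities are asserted at 1e-9; ANOVA oracles at 1e-8.

## Limitations

* Synthetic validation shows the pipeline recovers what it assumes —
  block-structured templates, shared envelopes, white noise.  Real ERPs
  have temporally autocorrelated, spatially structured noise, latency
  jitter across subjects, and gradual topographic transitions; passing
  these tests does not certify performance on such data, only the
  correctness of the implemented computations.
* The exact "modified" Krzanowski–Lai variant used by legacy toolchains
  cannot be confirmed without their data; the variant here is fully
  specified above and pinned by tests.
* The pooled-hand Spearman treats 2n hand-points as exchangeable after an
  independence diagnostic; repeated-measures correlation is out of scope.
* Source localization, continuous-EEG preprocessing and oscillatory
  measures are out of scope by design.
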