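# Methods

This note documents the models, conventions and design decisions behind
`ncrpipe`, in the order the pipeline runs.

## Signal model and preprocessing

A scan is a channels × samples matrix of [HbO] concentration changes,
16 channels at 1.77 Hz by default (a rectangular forehead probe with
four LEDs, ten shared detectors and 2.5 cm source–detector separation).
Missing samples are an input error: the pipeline never imputes.

The Stroop session is a block design: 15 stimuli per type (neutral,
congruent, incongruent) in blocks of five with a 4 s inter-stimulus
interval, i.e. nine 20 s task blocks, separated by 20 s rests and
framed by 30 s of leading and trailing rest — 400 s in total. Block
order is a seeded permutation per subject. Connectivity for one
stimulus type is computed on that type's blocks concatenated in onset
order. Sample windows are mapped by half-up rounding of `onset·fs` and
`duration·fs` (at 1.77 Hz block boundaries never fall on integer
samples; the rounding convention makes segmentation deterministic, and
20 s × 1.77 Hz → 35 samples per block, 105 per stimulus type).
Concatenation copies values bit-exactly — no resampling, no detrending
— and the regressor is concatenated over the identical boundaries.

**Systemic regressor.** Background physiology (blood-pressure waves,
respiration and cardiac activity aliased into the band) is shared
across channels, so its channel average is used as the control variable
of the partial correlation. Each channel is filtered with an 8th-order
Butterworth high-pass and averaged across channels. Two conventions
deserve note:

* *Filter sense.* The upstream description states a high-pass but
  quotes a corner (0.09 Hz) below the stop-band (0.1 Hz), which is a
  low-pass layout. The default here is the stated sense — high-pass
  with the pass-band edge at the upper corner (0.1 Hz) — and
  `FilterSpec(mode="lowpass")` provides the alternative reading.
* *Zero phase.* Filtering is forward–backward (`sosfiltfilt`) by
  default, because correlations are phase-sensitive and a causal pass
  would introduce a group delay between the regressor and the raw
  channels; `application="causal"` is available.
* The channel *mean* is used rather than the sum; correlation-based
  statistics are scale-invariant and the mean keeps concentration
  units.

## Partial-correlation connectivity

For channels i, j and the concatenated regressor k,

    r_ij|k = (r_ij − r_ik·r_jk) / sqrt((1 − r_ik²)(1 − r_jk²)),

which equals the Pearson correlation of the residuals of i and j after
least-squares regression on k (the package tests both routes against
each other). Channel series enter *unfiltered* — only the regressor is
filtered — and means are removed over the whole concatenated series,
not per segment. Degenerate inputs (zero variance, or a channel
perfectly correlated with the regressor) raise errors rather than
returning NaN. The diagonal is fixed at 1 and never participates in
thresholding.

## CM/DM separation and the component search

Each FC matrix is decomposed as `FC = Σ λ_k v_k v_kᵀ` by symmetric
eigendecomposition — interpreted as the "PCA of the FC matrix" because
it alone guarantees the exact additive split `FC = FC_CM + FC_DM` with
Frobenius-orthogonal parts. Components are indexed 1..N by descending
|λ|, with each eigenvector's largest-magnitude element made positive.

The subset defining the cognitive-mode network, and the count
thresholds, are optimized per subject group:

* **Objective.** Minimize the one-way ANOVA p-value of GE_CM across the
  three stimulus types, pooled over the group's subjects (the cognitive
  network should track task demand). After fixing the subset, Θ_DM is
  chosen to *maximize* the analogous p-value of GE_DM (the default-mode
  network should be stimulus-indifferent). The optimization is
  in-sample by design; the selected p-values are selection-biased and
  are reported as search diagnostics, not as confirmatory statistics.
* **Candidate pool.** By default the search only considers components
  whose group-mean |λ| exceeds 1.1 × the Marchenko–Pastur bulk edge
  `(1 + sqrt(N/T))²` for N channels and T concatenated samples (the
  factor covers finite-sample fluctuation of the top noise
  eigenvalues). Components inside the noise bulk are statistically
  indistinguishable from sampling noise, and admitting them lets the
  in-sample optimizer assemble arbitrary noise subsets whose
  reconstructions binarize into spuriously efficient graphs — measured
  here as p-values down to 1e−9 on structureless matrices. The
  restriction follows the original guidance that the choice is "based
  mostly on the strongest eigenvalues"; `component_pool="all"` disables
  it.
* **Strategies.** `exhaustive` enumerates every proper subset of the
  pool (feasible for all 16 channels when the pool is small, and for
  `pool="all"` up to ~12 channels); `greedy` is seeded forward
  selection widened to a beam (width 4), which removes the
  path-dependence of single-path greedy. Ties prefer smaller subsets,
  then lexicographic order, then smaller Θ. A step-to-enter factor
  (`step_improvement`) and a complement-insensitivity constraint
  (`dm_insensitivity`) are available as additional overfitting guards
  but default off: with the spectral pool in place they proved
  redundant, and the complement constraint can deadlock when real
  structure sits just below the pool threshold.

## Binarization and global efficiency

Θ is a **count** of directed off-diagonal entries (240 for N = 16), so
the range 24–48 retains the strongest 10–20% of |FC|; ⌊Θ/2⌋ undirected
pairs are kept, ties at the cutoff broken lexicographically, diagonal
always zero. An `--undirected-theta` semantic is unnecessary: passing
2k keeps exactly k pairs.

Global efficiency uses hop-count shortest paths (BFS) with the
Latora–Marchiori convention that unreachable pairs contribute zero;
1.0 for a complete graph, 0.0 for an empty one. A hand-rolled
Floyd–Warshall oracle (and networkx) cross-check the implementation in
tests. GE under a count threshold is invariant to the overall scale of
connectivity — it sees only the rank order of entries — and is monotone
in the edge budget.

**Comparability across groups.** Because GE grows with the number of
retained edges, group contrasts computed at group-specific optimized Θ
conflate edge budget with topology (verified on synthetic cohorts: the
sign of a planted group difference flipped from seed to seed when each
group used its own Θ*). The subject-level GE values entering R and NCR
are therefore computed at a *common* reporting budget, Θ = 36 (15% of
240, the midpoint of the 10–20% guidance), for every group; the
per-group optimized Θ remain part of the search output. Setting
`RunConfig.report_theta_cm/report_theta_dm = None` restores the original
group-specific protocol.

## Biomarker and statistics

Per stimulus type: `CQ = ACC/RT` (% per second; RT accepted in ms at
I/O and stored in seconds), `R = GE_CM/GE_DM`, `NCR = CQ·R`. Group
tables follow the mean-of-ratios convention: CQ/NCR are computed per
subject and then averaged (this differs from dividing group-mean ACC by
group-mean RT whenever subjects are heterogeneous). Across-stimulus
summaries are arithmetic means over {N, C, I}. Group summaries report
mean ± SD with the n−1 denominator.

One-way ANOVA is computed from sums of squares directly so degenerate
inputs are explicit (no variance → F=0, p=1 with a warning). The
two-way ANOVA (group × stimulus with interaction) uses Type II sums of
squares via statsmodels, appropriate for the unbalanced cohort.

ROC analysis scores NCR̄ (and CQ̄, GE_CM-bar) for controls versus the
pooled patients, with controls as the positive class. AUC is the
tie-aware rank (concordance) statistic; the operating point maximizes
Youden's J (ties resolved toward higher sensitivity); accuracy is
(TP+TN)/total at that point. Pairwise group ROCs take the higher-mean
group as positive. No confidence intervals are attached to AUC.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable without
any recordings. Per subject it simulates, at 1.77 Hz over the 400 s
session:

* **Slow systemic background** — a sum of five sinusoids at
  0.012–0.08 Hz with subject-random phases (unit total variance),
  shared across channels with per-channel gains U(0.7, 1.3), scaled by
  `systemic_amplitude` (default 0.3). This component survives the
  high-pass regressor, as in real data.
* **Broadband systemic** — a shared AR(1) process (ρ = 0.3), scaled by
  `fast_systemic_amplitude` (0.3); this is what the regressor captures
  and the partial correlation removes.
* **Task-evoked response** — stimulus boxcars convolved with the
  canonical double-gamma HRF (peak 6 s, undershoot 16 s), normalized to
  unit sum so a sustained block plateaus at `task_amplitude` (0.3) times
  a per-channel gain U(0.5, 1.0). (Peak normalization was rejected: the
  20 s-block plateau of a peak-normalized kernel is ~9× the nominal
  amplitude and its shared response then dominates all channel
  covariance.)
* **Cognitive-mode network** — correlated innovations in a single
  hub-organized community. The hub channel loads with share
  `0.72·c` and members with 0.4 of that, where c is the group's
  CM coupling; signed (alternating) loadings keep the factor out of the
  channel average, so the regressor stays free of network signal.
  Stimulus demand scales the recruited extent: 10 of 16 channels under
  N, 13 under C, all 16 under I. The process variance itself scales
  with c (a weakly coupled network produces little coherent activity),
  so realized inter-channel correlations fall off faster than linearly
  in c.
* **Default-mode network** — a stimulus-indifferent community over
  every third channel at the group's DM coupling.
* **White noise** — `noise_sd` (0.3) per channel.

Behavior: RT per stimulus is truncated normal above 150 ms with the
published group mean/SD; ACC is `100·Binomial(15, p)/15` with p the
published mean — accuracy lives on the 15-trial grid. All randomness
derives from one master seed via spawned seed sequences; identical
seeds reproduce cohorts bit-for-bit.

**Why a hub network with demand-scaled extent?** The binarized-GE
readout constrains the generative design in two ways that less
structured designs fail. First, with ~105 samples per stimulus, only
eigenvalues above the Marchenko–Pastur bulk (~1.9) are estimable, so a
*detectable* network must concentrate spectral weight — sparse
ring-like graphs have flat spectra and vanish into the noise bulk.
Second, low-rank reconstructions of flat communities binarize into
cliques, whose GE is *lower* than that of pure-noise reconstructions;
a hub-graded factor instead binarizes into a hub-and-spoke graph whose
GE grows with the recruited extent. The combination yields the intended
phenotype: a strongly coupled network is recovered and scores high,
demand-sensitive GE_CM; a weakly coupled one (patients) drops below the
noise floor and leaves concentrated, noise-dominated reconstructions
with low GE_CM. Healthy-vs-patient differences in GE_CM thus emerge
from recoverability, not from hard-coding group outcomes.

**What the generator does not model:** motion artifacts,
cardiac/respiratory aliasing, optode-coupling drift, spatial probe
geometry (channel adjacency carries no physical meaning), inter-subject
variability in network layout, and any raw-intensity physics (the
pipeline starts from [HbO]). Passing tests on this generator
demonstrate that the pipeline recovers the statistical structure it
assumes; they do not certify performance on real recordings.

## Default study conditions used by tests and the acceptance script

* Parameter recovery: 13 controls (c = 0.70) vs. 67 pooled patients
  (c = 0.30), behavioral tables from the control and schizophrenia
  rows, 20 replicate cohorts.
* Null calibration: both groups share c = 0.55 and control behavior,
  20 replicates.
* Type-I error: two-way ANOVA on pure-noise 2 × 3 designs with five
  observations per cell, 1000 simulations, α = 0.05.
* Component-search recovery: a 6-channel instance with the stimulus
  effect planted in components {1, 2} through their interference
  pattern (singles are stimulus-flat because a rank-1 reconstruction's
  ranking is scale-invariant), searched exhaustively and greedily over
  a fixed Θ.

These sizes keep the full test suite around half a minute.

## Known limitations

* The component search optimizes in-sample; its p-values are biased by
  selection and the spectral pool only bounds, not removes, that bias.
* GE_DM at the common reporting budget is computed from the complement
  of a small subset (nearly full rank) and is therefore high and
  relatively uninformative; R and NCR inherit their discrimination
  mostly from GE_CM and CQ.
* The half-up sample-rounding convention and the zero-phase filter are
  choices among defensible alternatives; both are configurable, and
  switching them changes third-decimal details of FC entries.
* With 13 subjects per group the stimulus-wise ANOVAs are low-powered;
  the pipeline reports them as in the original design rather than
  recommending them.
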