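# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `framefp`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Frame representation

### Phase-coherence connectivity

Node time series are assumed band-limited before phase extraction; the
instantaneous phase θ(i, t) is the angle of the analytic signal
(`scipy.signal.hilbert`) of the demeaned node series. The per-volume
connectivity is `dFC(i, j, t) = cos(θ(i, t) − θ(j, t))`. With
c = cos θ(·, t), s = sin θ(·, t) this is c cᵀ + s sᵀ, hence symmetric, PSD,
unit-diagonal, trace N, rank ≤ 2. Because λ₁ + λ₂ = N and λ₁ ≥ λ₂ ≥ 0, the
leading eigenvector always explains λ₁/N ≥ 1/2 of the total variance. This
is an identity, not an empirical observation; the suite asserts it with zero
violations over 1000 random phase configurations, and the acceptance script
reports the observed minimum.

### Leading eigenpair: closed form vs dense solve

`leading_eigen_series` never materialises the N×N matrices: the nonzero
spectrum of c cᵀ + s sᵀ equals that of the 2×2 Gram matrix
[[c·c, c·s], [c·s, s·s]], and the eigenvector lies in span{c, s}. This is
algebraically exact and O(N) per volume. The dense symmetric solver
(`scipy.linalg.eigh`) backs the single-matrix API and serves as the
independent oracle in tests. Degenerate cases (λ₁ = λ₂, which requires
c·s = 0 and c·c = s·s exactly) are resolved toward the cosine direction; they
have measure zero for continuous phases.

**Sign convention.** Eigenvector sign is fixed by making the
largest-magnitude entry positive. This only affects serialisation;
similarity uses |Pearson r|, which is sign-invariant (asserted by property
test).

**Edge trim.** The Hilbert transform distorts phases at the series
boundaries; the first and last 5 volumes are removed after the transform
(configurable, default 5). With the study presets this reproduces the
803 / 106 / 259 / 197 retained-volume bookkeeping of the three cohorts'
scan lengths.

### Temporal collapse and the static network

The time-collapsed matrix is Σₜ λ₁(t) V1(t) V1(t)ᵀ — eigenvalue-weighted by
default, because the weighting preserves per-volume energy; the raw
(unweighted) sum is available behind a flag. On full-length synthetic rest
scans (818 volumes, 100 nodes) the off-diagonal entries of the weighted
collapse correlate with the Pearson static network at r ≈ 0.94 (the suite
asserts r ≥ 0.9). The correlation grows with scan length; at a few hundred
volumes it sits near 0.9, which is why the check is run at the full
preset-scale scan length the claim concerns.

## 2. Preprocessing

Fixed order: steady-state drop → band-pass → confound regression. Motion
flags and tSNR are computed on the raw post-drop series, before filtering.

- **Steady-state drop**: 5 volumes for the 2.2 s-TR presets, 10 for the
  2.0 s-TR preset (first ~11–20 s of acquisition).
- **Band-pass**: zero-phase (forward–backward) 2nd-order Butterworth,
  0.009–0.08 Hz, applied via second-order sections. Zero-phase filtering is
  essential: phase distortion would corrupt the Hilbert phases (a property
  test asserts zero lag for in-band sinusoids). Minimum stable length is 16
  volumes. The output is exactly demeaned per node.
- **Confound regression**: least-squares residual against an intercept, the
  global-signal trace (toggleable — global-signal regression is debated in
  the field), the framewise-displacement trace, and one indicator column per
  motion-flagged volume. Collinear columns are dropped with a warning via
  pivoted QR. Residuals are orthogonal to all retained regressors and the
  operation is idempotent.
- **Motion flagging**: volume t is flagged iff FD(t) ≥ 0.5 mm AND the global
  signal changed by ≥ 5 % from the previous volume. The 5 % reference is the
  scan's mean global signal: a previous-frame-relative denominator is
  unstable near zero once series are demeaned. Whether the change is signed
  is unspecified in common descriptions; the absolute change is used. The
  first volume is never flagged.
- **tSNR**: temporal mean / temporal sd on the raw series, so the value is
  comparable across filter configurations; zero-variance nodes are undefined
  (NaN) and excluded from averages.
- FD is consumed as a given per-volume trace. A helper converts 6 rigid-body
  parameters to FD (rotations as arc length on a 50 mm sphere) for users who
  have parameter files rather than FD traces.

## 3. Synthetic cohort model

For subject s, task k, session e, the node signal is

x(t) = √w_g·G u_g(t) + √w_s·S_s u_s(t) + √w_k·K_k u_k(t) + √w_sk·I_sk u_sk(t) + σ ε(t)

where each loading matrix (N × latent_rank) is drawn once per cohort from a
seeded standard normal, the latent series u and noise ε are drawn fresh per
session, and the sum is band-limited with the same filter implementation the
preprocessing uses, then offset by a constant baseline (1000 a.u.) so that
percent-signal-change flagging and tSNR are well defined. The implied node
covariance is w_g GGᵀ + w_s S_sSᵀ + w_k K_kKᵀ + w_sk I_skIᵀ + σ²I.

What this emulates: subject-stable, session-varying correlation structure —
the premise that identity drives frame similarity — plus task and
subject-specific-task structure, shared group structure, and session noise.
Setting the subject, task, and subject×task weights to zero makes scans
exchangeable across subjects, so identification is at chance by
construction.

What it does **not** emulate: hemodynamics, spatial maps or voxel-level
images, non-stationary state switching, physiological rhythms, scanner
drift, or realistic motion mechanics. Passing tests therefore demonstrate
that the pipeline recovers the structure this model encodes, not that real
cohorts carry that structure.

**Defaults** (chosen once as a moderately identifiable regime): weights
group 1.0, subject 0.6, task 0.3, subject×task 0.15, noise sd 1.0, latent
rank 10, TR 2.2 s, N = 50, T = 200. The mixture weights are free parameters
of the synthetic model, not estimates of real effect sizes. The
"strong-subject" conditions used in the recovery tests are group 0.5,
subject 3.0, noise 0.3, rank 5 — subject variance an order of magnitude
above the noise floor.

**Presets** mirror the three demonstration cohorts' dimensions so the chance
arithmetic matches exactly: `msc` 10 subjects × 10 sessions, 818-volume rest
and 121-volume task runs at TR 2.2 s, drop 5 (→ 803 / 106 retained);
`ncanda` 100 × 6, 274 volumes, TR 2.2 s, drop 5 (→ 259); `bnet` 173 × 2,
217 volumes, TR 2.0 s, drop 10 (→ 197). Preset volume counts are raw
(pre-drop) so the drop + trim bookkeeping reproduces the printed retained
counts.

**Motion spikes** (rate per volume, default 0): a spike volume receives
FD ≥ 0.5 mm, a common signal step of 6–12 % of baseline across all nodes
(so the joint flag fires), and per-node noise at 5× the scan's temporal sd.
The data corruption goes beyond what flagging alone needs; it exists so that
motion-split analyses have a real effect to measure. Consecutive same-sign
steps can mask each other's global change — isolated spikes always satisfy
the joint flag. Non-spike volumes keep FD in [0.02, 0.3] mm.

**Voxel budget** (optional): when set, each node is treated as the average
of `voxel_budget / n_nodes` voxels carrying independent per-voxel noise of
sd `session_noise_weight`, so finer parcellations are noisier per node and
mean tSNR decreases with node count — the mechanism behind
coarse-vs-fine-atlas tSNR comparisons.

## 4. Identification engine

- **Similarity**: |Pearson r| between eigenvectors, computed as a dot
  product of centred unit-normalised vectors; the database is scored in
  blocks of 4096 volumes so the full target×database similarity matrix is
  never materialised.
- **Ties**: exact argmax ties are broken toward the lowest
  (subject, session, task, volume) in lexicographic order with a warning
  (measure zero on continuous data). Scan-level vote ties are broken by the
  larger summed similarity across the tied label's winning volumes, then
  lexicographically.
- **Degenerate frames**: a fully phase-aligned frame has a constant
  eigenvector with undefined correlation. The scalar `similarity` raises;
  the batch matcher zeroes such rows with a warning so they match nothing
  preferentially and the tie rule resolves them deterministically.
- **Sweeps**: `run_identification` iterates every target session ×
  every size-k subset of the remaining sessions (all C(n, k) subsets in
  deterministic order; for the 10-session preset this gives the 90
  single-database and 126 five-database iteration counts). A cap on subsets
  per target is available for large grids and is deterministic (first
  subsets in lexicographic order).
- **Task identification**: scans are first truncated to a common volume
  count (rest cut to the task length) so each task contributes equally;
  truncation happens before phase extraction in the pipeline helper. Within
  mode: database = target subject's other sessions, all tasks. Between mode:
  database = other subjects' scans from sessions other than the target
  session; all scans of the target's owner are excluded. (Which sessions of
  the other subjects to include is a genuinely open choice; excluding the
  target session mirrors the within-mode session structure.)
- **Permutation null**: database scan labels are permuted as a multiset
  (label counts preserved), volumes inherit their scan's permuted label.
  Since the best-matching database volume does not depend on labels, match
  indices are cached once and each permutation only re-labels them —
  mathematically identical to re-running the identification per permutation.
  p = count(null ≥ observed) / n_perm; a zero count is reported as the upper
  bound "< 1/n_perm" rather than 0. Significance testing via linear
  mixed-effects models is deliberately out of scope; permutation p-values
  and percentile-bootstrap CIs over target scans (2000 resamples, seeded)
  are reported instead, since the permutation scheme is the
  procedure-defined null.
- **Static baseline**: classical whole-scan fingerprinting — signed Pearson
  correlation between vectorised upper triangles of static networks,
  scan-level accuracy only.

## 5. Statistical calibration details

Band-limited series are strongly autocorrelated across consecutive volumes,
so volume counts overstate the number of independent frames. Chance-band
checks on null cohorts therefore use an effective sample size
n_eff = n_volumes × 2·bandwidth·TR (≈ 0.31 × n at the default band and TR)
in the binomial band around 1/n_labels. The permutation test needs no such
correction: permuting scan labels preserves within-scan autocorrelation, so
its null is exact under exchangeability (verified by a type-I-error
calibration test over 20 independent null cohorts).

## 6. Problem sizes

The test suite and experiment defaults use scaled-down cohorts (tens of
scans, 20–100 nodes, 80–200 volumes; full 818-volume scans only where the
claim concerns full-length scans). These sizes already separate the tested
effects cleanly; the presets carry the full study dimensions for users who
want them, and all code paths are size-agnostic.

## 7. Known limitations

- The downsampling experiment cannot reproduce one real-data ordering: in
  this generator a stratified node subset of a fine-parcellation cohort is
  statistically exchangeable with a native coarse cohort of the same size,
  so "downsampled-from-fine beats native coarse" has no generative
  mechanism here (it relies on real parcels' spatial heterogeneity). The
  suite asserts the reproducible parts: the subset does not beat the fine
  atlas, tracks the native coarse atlas, and the tSNR direction under a
  voxel budget.
- The motion-split direction (flagged frames identified less accurately) is
  only expressed in identifiable cohorts; near chance the split is
  uninformative.
- Volume-level accuracies on synthetic cohorts are qualitative analogues,
  not predictions of real-data accuracy figures; the mixture weights are
  free parameters.
- No clustering of frames into discrete brain states is provided — the
  method's point is that frame-level matching needs no state discretisation.
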