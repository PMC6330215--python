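# Methods

This note documents the models, estimators and numerical choices behind
`dynsubgraphs`, what the synthetic-cohort generator does and does not
emulate, and the known limitations.

## Windowed wavelet-coherence networks

Each subject contributes a regions × samples array (default emulation:
120 samples at TR = 3 s, a ~6-minute acquisition).  Sliding windows are
20 samples long with 90% overlap (step = `round(20 × 0.1)` = 2 samples);
120 samples therefore yield 51 windows, and trailing samples that do not
fill a window are dropped.

Edges are the magnitude-squared wavelet coherence

    R² = |S(W_xy / s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) ),

computed from the complex Morlet CWT (center frequency ω₀ = 6, the
standard trade-off between time and frequency resolution; in PyWavelets
parameterization `cmor2.0-C` with C = ω₀/2π).  The smoothing operator S is
a Gaussian along time with standard deviation equal to the scale, and a
0.6-octave boxcar across scales (Grinsted-style).  Scales are geometric at
1/12 octave covering the analysis band 0.02–0.08 Hz widened by a factor
1.5 on each side so the smoothing has support at the band edges.  The
estimator is pluggable behind `wavelet_coherence_map`; nothing downstream
depends on its internals.

The transform is computed once on the full series and the coherence map
is then averaged over in-band scales and the samples of each window.  At
these frequencies one 20-sample window is shorter than a single period of
the slowest in-band oscillation, so a per-window transform would be
ill-posed.  The same argument sets the temporal resolution of the whole
pipeline: coherence changes faster than roughly a wavelet scale
(~20–50 samples) are not resolvable, which is why validation of
"coherence increases with planted coefficient" is done across expression
levels rather than window by window.

Constant (zero-power) input series are flagged degenerate and define
coherence 0.  Each layer of the multilayer stack is divided by the mean
of its upper-triangle entries (the diagonal is structurally zero and is
excluded); normalization is idempotent and a nonpositive layer mean is an
error.  Unfolding uses fixed lexicographic (i < j) edge order; fold∘unfold
is the identity.

## Motion regression

The temporal-average RMS motion of each subject is regressed out of every
(edge, window) cell across subjects by OLS, subtracting
`b·(motion − mean(motion))` and clipping negatives at zero.  Two choices
here matter:

* **Centering.** The slope-estimation error enters each subject's series
  multiplied by the motion regressor.  Subtracting `b·motion` raw makes
  that jitter grow monotonically with motion, which leaks a strong
  spurious motion dependence into nonlinear summaries (histogram entropy
  in particular — we measured r ≈ 0.9 at desk scale before centering).
  With centering the jitter scales with |motion − mean|, which is not
  monotone in motion, and the measured leakage drops to |r| < 0.05.
* **Level retention.** Centering retains each cell's value at the cohort's
  mean motion, so the nonnegative scale that the factorization needs
  survives; pure residuals would center edges at zero.

With zero motion variance the step is skipped (identity) with a warning.

## Sparse NMF

The cohort matrix X (edges × windows·subjects, entrywise ≥ 0) is
factorized by minimizing

    ½‖X − WH‖²_F + η‖W‖²_F + β Σ_j (Σ_i H_ij)²,  W, H ≥ 0.

η bounds subgraph edge weights and defaults to `max(X)²`; β promotes
sparse expression columns; defaults tol = 1e−6 (relative objective
change), max_iter = 200, all exposed in the configuration.

Both subproblems are solved exactly via their augmented least-squares
forms — `H ← argmin ‖[W; √(2β)·1ᵀ] H − [X; 0]‖²` and
`W ← argmin ‖[Hᵀ; √(2η)·I] Wᵀ − [Xᵀ; 0]‖²` — whose stationary objective
equals the printed objective.  The inner solver is block principal
pivoting on the normal equations, vectorized over columns with grouped
Cholesky solves, Murty's single-exchange backup rule for finite
termination, and a classical active-set fallback for any unresolved
column.  Exact subproblem solutions are what make every alternating sweep
weakly decrease the objective — a contract the test suite asserts on
every run, together with a KKT residual check at exit.  Each sweep
updates W first and H last, so the stored H is always the exact solution
given the final W; projecting a training subject's own data onto the
fitted basis therefore reproduces its H block.

Initialization is plain NNDSVD (deterministic; zero blocks kept, no
mean fill): the leading component from the absolute leading singular
vectors scaled by √σ₁, later components from whichever sign section of
each singular-vector pair carries more mass (ties to the positive
section), components beyond the numerical rank zero-padded with a
warning.  For reporting, subgraphs are sorted by descending total
expression, since NMF is permutation-invariant and a fixed order makes
runs comparable.

**Model selection.** The default is masked holdout: 10% of entries chosen
uniformly at random are replaced by their column means during fitting and
the (k, β) minimizing mean-squared error on the hidden entries wins.
Training error alone cannot produce an interior optimum in k (it is
non-increasing), which is why a holdout criterion is the default; a
maximum-curvature elbow on the training error is available as an
alternative.

**Projection.** New connectivity matrices are projected onto a fixed
basis by the same augmented nonnegative least-squares step used for H
(β participates, η does not), giving deterministic per-window weights.

## System mapping

A subgraph column folds to a symmetric zero-diagonal V.  Over a partition
into m labeled systems, within-system connectivity is
`R_s = Σ_{i,j∈P_s} V_ij / |P_s|²` (both orientations counted; because the
diagonal is zero the formula saturates at 1 − 1/|P_s| for a complete
system — the denominator is kept literal deliberately) and between-system
connectivity is `I_st = Σ_{i∈P_s,j∈P_t} V_ij /(|P_s||P_t|)`.  Locality is
the bias-uncorrected sample skewness of the m(m−1)/2 off-diagonal
upper-triangle entries (0 by convention for zero variance).

Per-system importance uses the column sum of the full symmetric system
matrix (diagonal included) as the statistic, with a null built from
uniform permutations of the node labels (sizes preserved).  A system is
flagged when its statistic exceeds the one-sided 95th percentile of its
null, uncorrected across systems; flags are for reporting and
visualization, not for thresholding the matrices themselves.  Calibration
is asserted in the acceptance suite: on structureless graphs the flag
rate stays within 0.05 ± 0.02.

## Expression dynamics

For one (subject, subgraph) coefficient series S₁..S_L (L = number of
windows): energy `Σ S_n²`; histogram entropy with 10 equal-width bins over
the series' own [min, max], natural log, empty bins skipped, constant
series defined as 0 (the limiting value); mean absolute first difference
as an alternative transience measure.  Entropy is invariant to affine
rescaling of a series and energy scales quadratically — both are asserted
as properties.  The bin count is exposed in configuration and all
cross-group comparisons use one setting.

Standardization divides each (subject, subgraph) series by its own mean
(zero-mean series are marked missing rather than divided), making energy
comparisons relative rather than absolute.  The per-subject-and-subgraph
convention is the primary definition; a per-subject-only variant would
conflate subgraphs of different scale and is not used by the pipeline.

The energy–entropy relationship is the Pearson correlation between
log mean energy and mean entropy across subgraphs, after averaging over
subjects within each subgraph.  Its null shuffles all elements of the
coefficient matrix jointly (shape preserved) and recomputes the
correlation; p values use add-one smoothing, `(1 + c)/(n_perm + 1)`.

Group comparisons use the Wilcoxon rank-sum z with tie-corrected variance
and continuity correction; z is negative when the second-listed group has
larger ranks, so with groups ordered (child, adult) an adult increase
appears as z < 0.  For small samples an exact p (Mann–Whitney exact
distribution) is available and is checked against full enumeration in the
tests.

The behavior association residualizes both flexibility and behavior on
age by OLS (with intercept), correlates the residuals, and permutes the
residualized behavior for the null.  Flexibility defaults to the
histogram entropy of the projected executive-subgraph weights; the mean
absolute derivative is available as an option, and the two are reported
side by side by the CLI.

## Synthetic cohorts: what is emulated, and what is not

The generator plants a nonnegative basis W* and coefficients H* so that
every stage has a recoverable answer.

* **Supports.** Subgraph 1 (the "executive-like" effect subgraph) lives on
  the cross-system edges of systems 1–2, emulating between-system
  integration; remaining subgraphs are within-system, then further system
  pairs.  Node loadings are uniform on [0.7, 1]; edge weights are loading
  products.  Off-support edges carry a weak uniform background (0.05):
  real coherence networks have no exactly-zero edges, and a zero floor
  interacts pathologically with clip-at-zero steps (rectified estimation
  noise acquires a systematic motion correlation).
* **Coefficients.** Symmetric two-state (high/low) Markov chains, toggle
  probability `switching_prob` per window; a toggle window passes through
  a silent zero state with probability 0.3 ("transition silence").  The
  silence serves two purposes: it mimics transient disengagement while a
  subgraph reconfigures, and it makes the planted factorization
  identifiable — without near-zero coefficients a nonnegative
  factorization is unique only up to component mixing of order low/high,
  and exact recovery would be impossible in principle, not just in
  practice.  State levels are high 1.0, low 0.3.
* **Group effect.** Adults have the effect subgraph's high state scaled by
  `energy_ratio` (default 1.5) and its toggle probability raised by 0.15.
  Defaults were fixed once, at design time, by a pilot power analysis of
  the Wilcoxon comparison at 50 subjects per group and T = 51 (power ≈ 1.0
  for standardized energy and ≈ 1.0 for entropy, size ≈ 0.05), and satisfy
  the raw-energy scaling band expected at `energy_ratio = 2`.
* **Per-subgraph scale/switching arrays** allow coupling expression scale
  with switching rate across subgraphs (producing the strong
  log-energy/entropy correlation) or decoupling them (a negative
  control).
* **BOLD-like rendering.** Each subgraph drives one band-limited latent
  oscillator per subject; a region's series is the loading-weighted sum of
  its subgraphs' latents with per-window amplitude √coefficient
  (interpolated between window centers) plus white noise (default SD 1.0,
  chosen so in-band coherence sits mid-range rather than saturating).
  Coherence rises monotonically with the planted coefficient across
  expression levels.
* **Covariates.** Ages are uniform on the two study brackets
  (8.17–11.42 and 19.58–22.58 years); motion is drawn at group-dependent
  means (children 0.078, adults 0.060, SD 0.015, clipped at 0), children
  moving more; the optional confound adds `slope × motion` to every edge.
  Behavior is `flexibility + 0.05 × age + noise(0.1)`, where flexibility
  is the entropy of the planted effect-subgraph coefficients — enough
  structure to exercise the age-residualized association.

What the generator does **not** emulate: hemodynamics, realistic fMRI
artifacts, spatial geometry of any real parcellation, continuous age
effects, or the empirical distribution of real expression coefficients
(the two-state chain is an explicit stand-in chosen because it makes
energy and entropy separately tunable, not an inference about real data).
Passing tests therefore demonstrate correctness and calibration of the
estimators under a known generative model, not fidelity to any particular
dataset.

## Numerical and design notes

* Desk-scale defaults: N = 40 regions, 4 systems, k = 4, T = 51 windows,
  S = 40 subjects — small enough for minutes-scale runs while keeping the
  window count at its canonical value.  The acceptance script uses up to
  S = 200 where a check needs it.
* The noiseless-recovery check iterates ANLS to ~4000 sweeps: the shared
  background direction in the planted basis is nearly collinear across
  components, which makes the tail of the convergence slow (the objective
  still decreases monotonically and the recovered basis is already
  correct at correlation ≥ 0.99 within a few hundred sweeps).
* Estimation noise in the coefficients can *invert* the entropy group
  contrast through the full pipeline at desk scale: children's narrower
  coefficient range makes additive noise fill relatively more histogram
  bins.  The coefficient-level contrast is recovered with high power; the
  pipeline-level group test is therefore asserted on standardized energy.
  This is a real caveat for histogram-entropy comparisons whenever noise
  is non-negligible relative to the expression range.
* Permutation p values are never zero (add-one smoothing); permutation
  counts are configurable and seeded everywhere; reruns of the pipeline
  with one seed are bit-identical, and the run manifest hashes dataset
  contents (not container bytes) so the check is independent of HDF5
  serialization details.
* Degenerate inputs: constant series (coherence 0, entropy 0), zero-mean
  layers (error naming the layer), zero-variance motion (skip with
  warning), zero-mean coefficient series (marked missing), rank-deficient
  NNDSVD (zero-padded with warning), ties in the rank-sum test (corrected
  variance).

## Limitations

The wavelet estimator's smoothing parameters (Gaussian width, 0.6-octave
boxcar) follow common practice but are not tuned; different choices shift
absolute coherence levels (the layer normalization absorbs much of this).
Window-resolution limits mean fast expression switching is attenuated by
the coherence path; analyses of switching should be read at the
coefficient level.  The NMF objective is non-convex: ANLS guarantees
monotone descent to a stationary point, not a global optimum, and
uniqueness of the factorization depends on the data (the generator's
silent dips are what license exact-recovery claims).  Holdout model
selection assumes entries are missing-at-random, which mean-imputation
only approximates.
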