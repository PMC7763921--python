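# Methods

## Estimator conventions

All estimators operate on a univariate series `x(1..N)` embedded as
overlapping templates `X_i = (x(i), ..., x(i+len-1))` compared under
the Chebyshev (max-component) distance. A pair matches when
`d ≤ r` — the comparison is *inclusive*, so the single-tolerance
estimators agree exactly with the cumulative-histogram profile, whose
bins are defined by `P(d ≤ range(q))`.

* **ApEn(m, r)**: `N−m+1` templates at dimension m, `N−m` at m+1,
  self-matches included. `C_i = B_i / count` with `B_i` counting
  matches including `j = i`, so `C_i > 0` always and
  `ApEn = Φ^m − Φ^{m+1}` with `Φ` the mean of `ln C_i`. Requires
  `r > 0`.
* **SampEn(m, r)**: `N−m` templates at *both* dimensions, self-matches
  excluded. `C_i` is the fraction of the `N−m−1` other templates within
  r; `Φ` is the plain mean of the `C_i`, and
  `SampEn = ln(Φ^m / Φ^{m+1})`. When no (m+1)-dimension matches exist
  the value is *undefined*: the package returns the sentinel `nan`
  (`entroprof.UNDEFINED`), never raises, so downstream code can mask
  it. The per-template denominator `N−m−1` makes `C_i` identical to the
  profile's cdf fraction; any common normalizer cancels in the
  log-ratio, so this choice only fixes the internal arithmetic.
* **FuzzyEn(m, r)**: same template convention as SampEn, but the hard
  threshold is replaced by the similarity degree
  `D_ij = exp(−(d_ij/r)²)`, hence always finite. Defaults m=2,
  r = 0.15·SD. Templates are compared as recorded; no per-vector
  baseline (local mean) removal is applied, keeping the statistic a
  direct graded analogue of SampEn.

Standard deviation is always the population SD (`ddof=0`); tolerances
written `k·SD` use it everywhere.

`max_apen_search` evaluates ApEn on the grid `r = i·SD/100`,
`i = 1..100` (overridable) and reports the maximum and its tolerance
`rmax`; on ties the smallest tolerance wins, a deterministic
"first-crossing" rule.

## The CHM profile

`sampen_profile` pools all inter-template distances at dimensions m and
m+1, takes their sorted unique values as the tolerance axis
(`range`, `nbin = |range|`; uniqueness by exact float equality — ties
only arise from genuinely repeated sample differences, and no epsilon
collapsing keeps `nbin` reproducible), and computes the mean match
probabilities `θ_m(q)`, `θ_{m+1}(q)` for every bin at once from the two
pooled sorted arrays (rows have equal length, so the mean of per-row
fractions equals the pooled fraction). This costs
`O((N−m)² log(N−m))` independent of `nbin`, versus `O(nbin · N²)` for
the per-tolerance loop it replaces; memory is `O((N−m)²)` for the
distance pool, comfortable to N = 5000. The `cdf_matrix` /
`theta_curves` operations materialise the intermediate
`(N−m) × nbin` matrices for callers that want them; both routes give
identical results, and the test suite asserts it.

Bins below the smallest (m+1)-dimension distance have `θ_{m+1} = 0`
and the log-ratio is undefined; every non-degenerate series has such
bins. They are masked, and:

* **TotalSampEn** = sum of the profile over *defined* bins;
* **AvgSampEn** = TotalSampEn / number of defined bins.

Including the undefined bins would make the sum divergent; excluding
them while reporting their count keeps the measures finite and the
exclusion auditable (`ProfileSummary.n_undefined_bins`). A strict
variant dividing by the full `nbin` is available
(`avg_sampen(..., strict_nbin=True)`) for sensitivity analysis; since
undefined bins are typically few (tens out of tens of thousands for
continuous data), the two differ negligibly except on heavily
quantized, very short series.

Both summaries are invariant under affine rescaling of the input
(distances and the range axis scale together, θ-curves unchanged), so
they measure temporal structure, not amplitude. A consequence worth
knowing: a shuffled surrogate — whose coarse-grained versions are
maximally irregular at every scale — cannot be ranked below its
original by multiscale TotalSampEn, unlike fixed-tolerance multiscale
SampEn whose amplitude anchoring produces the classic crossing (see
below).

## Multiscale analysis

`coarse_grain` replaces non-overlapping blocks of `scale` samples by
their means, truncating the remainder (`floor(N/scale)` output
samples). `multiscale_curve` applies any estimator independently per
scale (defaults: scales 1–20, m=2, k=0.15). For the fixed-tolerance
estimators the default anchors `r = k·SD` to the *original* series' SD
(`r_mode="scale1_sd"`), the classical multiscale-entropy convention:
coarse-graining shrinks uncorrelated variability by ~√scale relative to
the fixed tolerance, which is exactly the mechanism that separates
white from long-range-correlated noise at high scales. The alternative
(`per_scale_sd`) re-derives r from each coarse series' own SD and
deliberately removes that amplitude effect; it is provided as a switch.
Scales whose coarse series is too short for the embedding are reported
undefined with a reason, never raised. Constant (zero-SD) coarse series
score 0 for every estimator: a constant signal is perfectly regular.

## Synthetic generators

* **Noisy logistic map** `x_{n+1} = a·x_n·(1−x_n)`: presets periodic
  (a=3.5), intermediate (a=3.75), chaotic (a=4.0); x0 = 0.5; 1000
  transient iterations discarded; default length 1000. Noise is
  additive Gaussian applied after generation, with "level" 0.1 meaning
  0.1 × the clean signal's SD (the convention of the classic MATLAB
  chaotic-signal generators); absolute-SD noise is a switch.
  Because x0 = 0.5 sits on the absorbing orbit 0.5→1→0→0... of the
  a=4 map, a seeded micro-jitter is added to x0. Its default scale is
  1e−7 with magnitude clamped to [jitter/2, jitter]: for a perturbation
  e the first iterate is `1 − 4e²`, which rounds back to exactly 1.0 in
  IEEE double (re-entering the absorbing orbit) whenever `4e²` is below
  the spacing of doubles near 1 (~2.2e−16), so perturbations under
  ~1e−8 are silently erased; 1e−7 is the smallest decade that reliably
  survives. `jitter=0` reproduces the degenerate trajectory.
* **White noise** and **power-law (1/f^α) noise** (spectral synthesis,
  standardised to mean 0 and the requested SD) form the
  uncorrelated/long-range-correlated pair for multiscale experiments.
* **Shuffled surrogates** permute the samples uniformly at random,
  preserving the value multiset exactly.

Everything is a pure function of its configuration including the seed.

What these signals do and do not emulate: they reproduce the
irregularity regimes, noise contamination and correlation structure
that drive tolerance selection and multiscale behaviour, but not the
nonstationarity, ectopic beats or measurement quantization of clinical
RR data — results on them demonstrate algorithmic correctness and the
documented qualitative orderings, not clinical performance. Test
fixtures round the synthetic signals to 2–3 decimals to mimic
recording resolution; this also creates tied distances, the stress
case for the data-driven range set.

## Benchmark reproduction

`scripts/acceptance.py` reruns the tolerance-search study: 10
realizations per preset, N = 1000 (the length used by the package's
multiscale case-study conditions; the per-realization seeds derive from
`--seed`), ApEn grid i·SD/100, m = 2. Reported: mean MaxApEn per regime
and the chaotic regime's mean rmax. The rmax means order
periodic < intermediate < chaotic — lower irregularity peaks at a
smaller tolerance.

## Evaluation statistics

`mann_whitney_p` is two-sided; with both groups ≤ 8 and a tie-free
pooled sample it uses the exact enumeration null, otherwise the
tie-corrected normal approximation (delegated to
`scipy.stats.mannwhitneyu`). `auc` is the tie-credited pair-win
fraction, computed from ranks and equal by construction to
`U / (n_a·n_b)`. Undefined feature values are excluded pairwise with
counts carried into the report; a group emptied by exclusion produces
NA cells. `truncation_report` truncates every series from its start to
each requested length and tabulates p / AUC (plus the orientation-free
`max(AUC, 1−AUC)`) per measure and group pair; subjects shorter than a
requested length are counted in `n_short`, never dropped silently.
Significance is flagged at p < 0.05.

## Numerical notes and limitations

* Profile values at defined bins satisfy `SampEn(q) ≥ 0` exactly
  (pooled integer counts give `θ_m ≥ θ_{m+1}`).
* The CHM–traditional agreement is asserted to 1e−12; the residual is
  pure floating-point summation-order noise.
* Distance computation builds the full `N × N` sample-difference
  matrix and takes running maxima over shifted views, so memory grows
  quadratically: ~200 MB at N = 5000, the practical ceiling.
* `TimeSeries` requires finite samples and length ≥ 1; estimators
  require `N > m + 1` and report the minimum length in the error.
* UNDEFINED is serialized as an empty CSV cell plus an explicit
  `defined` column, never as a bare NaN.
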