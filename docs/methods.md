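# Methods

## The operator model

A functional connectome at one session is a symmetric matrix
`G ∈ ℝ^{n×n}` with unit diagonal and entries in [−1, 1] (Pearson
correlations between ROI time series). Change between a reference session
`G` and a later session `G^k` is written as the action of an operator,
`K G = G^k`. Because the pair `(G, G^k)` underdetermines `K` until a
product is fixed, the package implements the candidate constructions side
by side:

| form | definition | properties |
|---|---|---|
| row-by-column `K^@` | `G^k G^{-1}` | exact (`K^@ G = G^k`); asymmetric in general |
| mixed `K^*` | `G^k ∘ G^{-1}` | symmetric for symmetric inputs; interpretable per connection |
| ratio `K` | `K_ij = G^k_ij / G_ij` | exact element-wise action; no inversion; composes along time |
| kernel `K` (experimental) | `exp(−‖row_i(G^k) − row_j(G)‖²/2σ²)` | similarity, not change; entries in (0, 1] |

`K^@ = K^* + T` holds by construction, and `t_matrix` returns the exact
difference. For a 2×2 decomposition `[[a,b],[c,d]] + [[e,f],[g,h]]` the
characteristic polynomial gives the closed-form eigenvalues implemented in
`eigen_2x2_closed_form`; dropping terms beyond first order in the
perturbation leaves the eigenvalues of `[[a,b],[c,d]]` shifted by
`(e+h)/2` (`eigen_approx_first_order`). The approximation error is O(ε) in
the perturbation scale, which the tests verify by a halving sweep.

Assumptions: matrices are real, finite, at least 2×2, with matched label
sets; inversion-based forms additionally assume `G` is well conditioned.

## Numerical choices

- **Inversion gate.** `invert` estimates the 2-norm condition number and
  refuses input beyond `max_condition` (default 1e12) instead of
  regularising; a silently damped inverse would bias every downstream K.
- **Ratio floor.** `k_ratio` replaces denominators with magnitude below
  `zero_floor` (default 1e-6) by the floor carrying the denominator's sign
  (positive for exact zeros). Division by zero is therefore impossible; the
  cost is that near-zero reference correlations yield very large |K|, which
  is why pair selection by |K| is a screening step.
- **Kernel bandwidth.** The kernel form is under-determined as a
  change-operator concept; it is implemented as a Gaussian kernel Gram
  matrix between the rows of the two inputs, bandwidth defaulting to the
  median pairwise row distance (median heuristic), and is flagged
  experimental throughout.
- **Spectra.** Symmetric input (tolerance 1e-12) is routed through the
  symmetric eigensolver so its spectrum is exactly real; the default
  eigenvalue ordering is by descending real part, with ties broken by
  descending imaginary part. Spectrum comparison uses the L2 distance and
  Pearson correlation of sorted real parts — deliberately simple summaries,
  since spectral similarity is a necessary, not sufficient, indicator of
  matrix similarity.
- **Modularity.** Newman's Q is computed by our own vectorised formula
  (verified against a literal double loop and, for n ≤ 6, against the
  exhaustive best partition); partition search is delegated to
  greedy modularity maximisation (Clauset–Newman–Moore, networkx) with
  deterministic tie-breaking by lowest node index and a singleton fallback
  for edgeless graphs. Signed matrices must be shifted non-negative first;
  the pipeline defaults to +1 for connectivity matrices and +1000 for
  ratio-K matrices, whose entries can be large.
- **Thresholding** defaults to absolute mode (|a_ij| < τ → 0), since
  connectivity entries are signed; the diagonal is treated like any entry.
- **Asymmetry** is defined here as `‖A − Aᵀ‖_F / ‖A‖_F` — an artifact
  definition chosen for scale invariance and exact zero on symmetric input.
- **File formats.** Matrices and time series are delimited text with a
  header row of labels (CSV/TSV by extension; `float_precision="round_trip"`
  on read and `%.17g` on write make I/O bit-exact), or `.npy` with a
  companion `.labels.json`.

## Synthetic data: what it emulates and what it does not

Two generators stand in for access-restricted clinical fMRI:

- `synth_timeseries` draws multivariate-Gaussian ROI series with a
  prescribed correlation structure (eigen-factorisation of the target, so
  PSD-boundary targets are accepted). It reproduces the statistical shape
  of connectivity estimation — sampling error ~ 1/√T — but none of fMRI's
  autocorrelation, non-stationarity, scanner drift or preprocessing
  artefacts. Tests passing on it show the estimator and operator algebra
  are correct, not that the pipeline is robust to real fMRI noise.
- `simulate_model` generates the four dynamics models as 10 symmetric 4×4
  matrices (defaults match the stated simulation scale): *null* redraws
  every entry uniform(0, 1) each step; *increasing* starts uniform(0, 1)
  and adds per-entry, per-step increments uniform(0.01, 0.05), mirrored
  across the diagonal, without clipping at 1 (clipping would create K = 1
  plateaus); *decreasing* starts uniform(0.55, 1) and subtracts the same
  kind of increments — the 0.55 lower edge guarantees 9 worst-case 0.05
  decrements stay positive, and parameters violating that bound raise;
  *varying* rises for the first `steps//2` transitions, then falls. Time
  labels are the natural numbers 1…steps.

The ratio-K trajectory of these models satisfies provable bands: with
entries `g > 0` and increments `δ > 0`, `(g+δ)/g > 1` and `0 < (g−δ)/g < 1`.
`classify_dynamics` exploits this with strict step-mean rules (all means
above 1 → increasing; all inside (0, 1) → decreasing; a prefix above then a
suffix below → varying; everything else, including the all-ones boundary, →
null). Recovery is 100% over seeds for the three constrained models. The
null model has no guaranteed band: ratios of independent uniforms are
heavy-tailed (the mean of `U₁/U₂` has no finite expectation), so a null run
can land in the increasing pattern by chance; "null" is the fallback label,
not a detected class.

## Pipeline and reproducibility

`run_pipeline` composes the modules over two or more time-ordered sessions
(connectivity matrices, or time-series tables from which connectivity is
computed): per-transition K (default: ratio form), spectrum CSV and
measure report; per-session measure report; top-|K| ROI pairs (default 5);
2×2 trajectory extraction with linear and quadratic fits (the quadratic
interpolates exactly when only three sessions exist — with three points and
three coefficients the residual is zero, so it demonstrates consistency,
not predictive power); recurrence reports (ε = 0.3 on z-scored series) when
time series are available. All outputs are declared in a manifest; the log
carries no wall-clock timestamps, so reruns of one config are
byte-identical.

Recurrence plots use the scalar, no-embedding definition
`R_ij = Θ(ε − |x_i − x_j|)` with `Θ(0) = 1` (a distance exactly ε counts
as recurrent — the convention must be fixed for bit-exact tests), default
ε = 0.3 on z-scored series. The joint RP is the Hadamard product of two
RPs and the rates include the diagonal: `RR = N⁻² Σ R_ij`, so
`1/N ≤ RR ≤ 1` and `0 < JRR ≤ min(RR_a, RR_b)`, with `JRR = RR` for
identical systems.

Problem sizes in the test-suite and acceptance computations (4×4 to 16×16
matrices, series of 40–200 samples, 50–1000 seeded repetitions) were chosen
so each property is exercised at the scale at which it is stated while the
whole suite runs in seconds.

## Known limitations

- Real clinical reference values (sparsity/modularity tables and RR/JRR
  trajectories from longitudinal Alzheimer-type and Parkinson-type fMRI)
  derive from access-restricted datasets with unstated preprocessing; they
  are context for interpreting the measures, not reproduction targets, and
  no fMRI preprocessing (detrending, band-pass, motion correction) is
  implemented here.
- The |K|-descending ROI-pair ranking is sensitive to near-zero reference
  correlations under the ratio form (screening, not inference).
- Only eigenvalues are analysed; eigenvector-based localisation is out of
  scope, as are line-structure recurrence measures (determinism,
  laminarity) beyond the recurrence rates.
- The kernel form and the first-eigenvalue-dominance observation are
  heuristic; neither is asserted as a universal property in the tests.
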