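# Methods

This note documents the models, algorithms, and conventions implemented in
`contactcalls`, the choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate.

## Scientific setting

Monk parakeets (*Myiopsitta monachus*) are open-ended vocal learners whose
contact calls may carry group- or region-level signatures. In their European
invasive range, populations are concentrated in city parks with little
movement between cities, which makes a two-level comparison possible: do
calls differ between parks within a city (active group convergence), or only
between cities (cultural founder effects and drift)? The package implements
the full analysis chain for this question, from fundamental-frequency (f0)
traces to a posterior decomposition of acoustic variance by spatial level,
together with a simulation framework that generates data with known truth.

## Trace conditioning

Input traces are f0 time series per call, with occasional tracker dropouts.
Conditioning has two steps, in a fixed order:

1. **Gap filling.** Undetected samples inside a trace are replaced by linear
   interpolation between the flanking detected points, on a uniform grid
   (default 1 ms). Leading and trailing undetected regions are dropped —
   extrapolation would invent signal. The operation is idempotent, and
   inserted samples stay marked in `gap_mask`.
2. **Spline smoothing.** A cubic smoothing spline with penalty parameterized
   by `spar` (default 0.4) removes single-sample tracking outliers. The
   penalty is λ = r·256^(3·spar − 1) with r = tr(XᵀX)/tr(Ω), computed with
   the time axis rescaled to [0, 1], where X is the cubic B-spline basis with
   knots at the data sites and Ω the Gram matrix of second derivatives
   (integrated exactly by 2-point Gauss quadrature per knot interval). This
   is the standard spar→λ mapping of the widely used reference smoother, so
   `spar = 0.4` means the same thing here as it does there; on a frozen
   fixture the two agree to ~0.2% (the reference thins knots for long series,
   so exact parity is not expected).

Measured behaviour at `spar = 0.4`: a single-sample 500 Hz spike is
attenuated by ≈ 59% (stable across trace lengths of 200–2000 samples in the
reference implementation as well), while a slow two-cycle modulation is
preserved to better than 5% relative RMS. One pass does not fully flatten an
isolated spike; it reduces it below typical modulation depths. There is no
explicit outlier rejection; `qc_report` gives per-trace residual RMS so that
visibly broken traces can be screened by thresholding.

Uniform resampling to the 1 ms grid is a package convention (the upstream
tracer's export step is not standardized); it makes the DTW step semantics
comparable across calls.

## Acoustic distances

Pairwise distances between conditioned f0 contours use dynamic time warping
with the symmetric step pattern with diagonal weight 2 ("symmetric2"):

    D[i,j] = min(D[i−1,j−1] + 2d(i,j), D[i−1,j] + d(i,j), D[i,j−1] + d(i,j))

with d(i,j) = |a_i − b_j| in Hz, D[0,0] = d(0,0), and normalization by
len(a) + len(b) (the total path weight of this pattern). Distances are
computed on raw Hz, not per-trace z-scores: absolute frequency offsets are
part of the dialect signal. The DP kernel is verified exactly against
brute-force enumeration of all warping paths on short sequences.

The full matrix is then log-transformed, off-diagonal entries becoming
log(d + ε) with ε defaulting to 10⁻³ times the smallest positive distance
(guards exact duplicates), and shifted so the minimum off-diagonal entry is
nonnegative — a requirement of the downstream ordination, which monotone
transformations do not disturb. "Normalization" here means DTW path-length
normalization; min-max scaling is deliberately not applied. No windowing
constraint is imposed by default; a Sakoe–Chiba band is available in
`DtwConfig`. All of these defaults are echoed into the pipeline run log.

DTW violates the triangle inequality, so the matrix is generally
non-Euclidean; nothing downstream assumes otherwise.

## Ordination

Classical Torgerson scaling: B = −½·J·D⁽²⁾·J, eigendecomposition, axis m =
eigenvector·√λ_m for the k = 2 largest positive eigenvalues. Negative
eigenvalues (expected with log-DTW input) are dropped without Cailliez or
Lingoes correction, matching common practice; the full spectrum is retained
on the result object so the distortion is inspectable. Eigenvector signs are
fixed by orienting each axis so its largest-magnitude coordinate is positive —
otherwise city contrasts could flip sign between runs. Both retained axes are
standardized (mean 0, SD 1, denominator n − 1) before modelling.

## The multilevel model

For a standardized axis score y per call:

    y_i     ~ normal(α_city[c_i] + α_park[p_i] + α_ind[k_i], σ_obs)
    α_city  ~ normal(μ_city, σ_city)
    α_park  ~ normal(0, σ_park)
    α_ind   ~ normal(0, σ_ind)
    μ_city  ~ normal(0, 1)
    σ_*     ~ exponential(2)

σ_city and σ_park are the quantities of interest; σ_ind absorbs repeated
calls from one bird (pseudoreplication). Parks are keyed by (city, park) so
shared park names never collide; individuals are keyed by (recording, label),
where the label is a field annotation when available and otherwise a
pseudo-ID pooling all unlabeled calls of a recording within fixed 5-minute
windows ([0, 300 s), [300 s, 600 s), … from recording start; fixed rather
than sliding windows keep the assignment reproducible).

Fitting uses an in-package No-U-Turn sampler (slice-variant dynamic HMC with
dual-averaging step-size adaptation and windowed diagonal mass-matrix
estimation). The model is non-centered (effects sampled as σ·z, z ~ normal(0,1))
to avoid funnel geometry at small σ, and scale parameters are sampled on the
log scale with the Jacobian included. The likelihood is evaluated through
per-individual sufficient statistics (count, sum, sum of squares), an exact
rewrite that makes each gradient evaluation O(#individuals) rather than
O(#calls). The sampler is validated three ways: gradients against finite
differences, a prior-predictive fit against the analytic prior, and full
posteriors against an independent affine-invariant ensemble sampler run on
the identical log density.

Defaults: 4 chains × 1000 warmup × 1000 kept draws, target acceptance 0.9,
maximum tree depth 10. `fit` raises a `ConvergenceError` whenever any split
R-hat (computed with arviz) exceeds 1.01; the threshold and all sampler
settings are recorded in the run log. The model is only softly identified —
a constant can move between μ_city and the α_city's — which inflates
autocorrelation for μ_city; the hierarchical prior anchors it and the R-hat
contract is the guard. Posterior summaries use equal-tailed percentile
intervals of pooled post-warmup draws: 89% for scale parameters and city
contrasts, nested 50/90/95% for city and park means. A park's mean is
α_city + α_park, so park intervals straddle their city's location. Pairwise
city contrasts are α_city[a] − α_city[b] per axis, flagged when the 89%
interval excludes zero, with one-axis and both-axes flags kept distinct. PC1
and PC2 are fitted independently.

Degenerate inputs are rejected rather than guessed at: a zero-variance
response, non-finite scores, or calls lacking city/park/individual raise
errors naming the offending calls.

## Synthetic data

The generator has two tiers:

* **Model-level** (`simulate_model_level`): responses drawn exactly from the
  model equations above, plus the field structure around them: parks covered
  by 20-minute recording sessions of 2 birds each, call offsets uniform over
  the session, and an individual annotation present with probability
  `p_labeled` (default 0.3 — most field calls are unlabeled).
* **Contour-level** (`simulate_contours`): full f0 contours built from
  parametric templates of the six contact-call variants (typical,
  four_triangle, ladder_start, ladder_middle, ladder_multiple, mix_alarm),
  rendered as trains of ≥3 frequency-modulated components around a base
  frequency of 2 kHz — the species' contact-call range. Hierarchical
  city/park/individual offsets act on the template's base frequency
  (200 Hz per response-scale unit) and modulation depth (60 Hz per unit),
  plus per-call jitter (σ_obs) and 10 Hz sample-wise measurement noise. This
  maps the model's one-dimensional truth onto a single acoustic axis, so the
  full pipeline (smoothing → DTW → PCoA → model) should recover the
  configured variance hierarchy on PC1.

Default SDs (σ_city 0.40, σ_park 0.21) mirror the estimates published for
the European city populations so that recovery experiments run in a
realistic signal-to-noise regime. Default sampling effort (8 cities, a few
parks per city, handful of birds per park, ~10 calls per bird) is a balanced
idealization of the field design; the real survey is strongly unbalanced
(2–756 calls per park), and the shipped sampling-effort table preserves that
reality for the summary statistics.

What the generator does **not** emulate: amplitude information, harmonics and
their tracking errors beyond white noise, within-call duration variation,
behavioural context, unbalanced designs (unless configured), and any spatial
arrangement of parks (clinal structure is out of scope). Passing recovery
tests therefore show that the estimator chain is correct under the model's
own assumptions — not that real recordings satisfy those assumptions.

`corrupt_ids` reproduces the field protocol (pseudo-ID pooling) and two
error processes for sensitivity analysis: *split* (a bird's calls scattered
to fresh IDs with a given rate) and *merge* (random ID pairs within a
recording collapsed with a given rate). City and park assignments are never
altered.

## Sensitivity analysis

`run_scenario` simulates data with known truth — by default σ_park = σ_city = 0,
so any apparent geographic signal is spurious — and fits the model twice per
replicate with identical sampler settings: once with true IDs, once with
corrupted IDs. Reported per replicate: posterior mean and 89% interval of
σ_park and σ_city, and the number of parks whose 95% interval excludes their
city mean. Replicates failing the R-hat check are flagged, never dropped.
`compare_to_fit` places an observed estimate within the corrupted-null
distribution; "above the spurious range" means exceeding the null's 97.5%
quantile — a package convention, since the underlying comparison is
qualitative. The corruption rates and replicate counts of the original
sensitivity experiment are not published; they are scenario parameters here.

## Variant tables and agreement

Variant composition is a city × variant count table with row percentages
(closed vocabulary of the six variants plus `other`; unlabeled calls are
excluded and counted). Sampling-effort summaries give per-park and per-city
call counts with medians and ranges; the package ships the published
per-park table (28 parks, 8 cities). Note an internal inconsistency of the
source material: the narrative summary reports the city range as 100–701
calls, while the printed table yields 110 (Verona) to 756 (Pavia), with
Brussels at exactly 701; the table is treated as authoritative, and both the
median (459) and the Brussels total (701) check out against it. Inter-observer
agreement uses unweighted Cohen's kappa with percent agreement; the 0/0 case
(both raters constant) resolves to 1 under perfect agreement and 0 otherwise.
No Z statistic is reported — its variance estimator is not standardized.

## Problem sizes in the test and acceptance runs

The validation experiments are sized to what their statistics require:
parameter recovery uses 20 replicates of an 8 × 5 × 8 × 10 design (3200
calls) at default sampler settings, checking that 89% intervals cover each
true σ in ≥ 70% of replicates (a loose bound: at 20 replicates, binomial
noise around the nominal 89% makes 14/20 a ~3.5-sigma floor). The
incorrect-pooling experiment uses 10 replicates of a 4 × 4 × 4 × 6 null
design with merge rate 0.5 and shorter chains (2 × 400/400) — its claim is an
ordering of means, not a calibrated interval. The acceptance script repeats
these computations at 8 and 10 replicates with 2 × 500/500 chains and runs a
6-city end-to-end contour pipeline; all sizes are stated in its output.

## Known limitations

* The sampler is single-threaded and tuned for this model family; it is not
  a general-purpose PPL. Tree depth averages ~7 on the recovery design
  because the soft identification of μ_city versus the city effects leaves
  long-range posterior correlation that diagonal preconditioning cannot
  remove.
* "Normalized" DTW and the log-shift convention are declared interpretations;
  both are configurable and logged, but results are only comparable across
  runs sharing those settings.
* PCoA axes are standardized per dataset; σ estimates are therefore on the
  scale of that dataset's axis SD and not directly transferable between
  datasets.
* The contour templates are stylized: they encode the published structural
  definitions of the six variants, not measured exemplars.
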