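# Methods

## Measurand and design

The reportable quantity is the aggregate total HCP mass per injection:
the sum over inferred protein groups of Hi3 masses
`m = (I_HCP/RF)·MW·10⁻⁶` ng, optionally expressed as ppm (ng HCP per mg
product). The unit of all validation statistics is the *replicate block*:
one independent preparation's arithmetic mean over its technical
injections, indexed by assay `a`, spike level `j`, and block `k`.

The reference design (`hcpval.core.default_design`) has seven spike levels
(20–80 ng) and four independent assays; assay 1 runs all seven levels,
assays 2–4 run five (L1, L2, L4, L6, L7), each included level as three
preparations in technical triplicate. Levels present in all four assays
yield twelve replicate blocks with between-assay df 3; the two
single-assay levels (40, 60 ng) carry repeatability information only.

## Statistical model

Validation statistics operate on percent relative errors
`RE_ajk = 100·(Y_ajk − μ_j)/μ_j`, modeled per level as a one-way
random-effects layout with assay as the grouping factor:

* `σ_W²` (repeatability) = pooled within-assay mean square,
* `σ_B²` = max((MS_between − MS_within)/m_h, 0) by the method of moments,
  with `m_h` the harmonic-mean blocks-per-assay; negative moment estimates
  are truncated to zero and flagged,
* `σ_T = √(σ_W² + σ_B²)` (intermediate precision).

Truncation must be read against the design's resolving power: with
between-assay df 3, a true `σ_B` below roughly 1.4·σ_W is statistically
indistinguishable from zero, so a zero estimate means "not resolvable",
not "absent".

Per-level total SDs are smoothed by `log σ_T,j = a + b·log μ_j`, fitted by
weighted least squares with degrees-of-freedom weights `n_j − 1`. This
weighting is deliberate: it reproduces the published smoothed-SD column
exactly from the published per-level SDs, which an inverse-`n_j` reading
does not. Predictions are invariant to the logarithm base; levels with
`σ_T = 0` carry no information on the log scale and are excluded with a
warning.

The β-expectation tolerance interval at each level is
`Bias_j ± t_{(1+β)/2, ν_eff}·σ̂_pred,j` with Welch–Satterthwaite

    ν_eff = (c_W·MS_W + c_B·MS_B)² / [(c_W·MS_W)²/df_W + (c_B·MS_B)²/df_B],

`c_W = 1 − 1/m_h`, `c_B = 1/m_h`, floored at 3. When `σ_B` is truncated or
not estimable the total variance is a pure within-assay quantity and
`ν_eff = max(df_W, 3)`; this rule (rather than pushing zeros through the
formula) reproduces the published effective df at the truncated levels. A
level is validated when the interval lies inside the closed ±30 % limits
(±35 % for stratified profiles); the validated range is the contiguous
span of passing levels and its lowest level is the LLOQ. An interior
failure fragments the range, and no LLOQ is reported without an explicit
override.

## 95/95 content interval

The content interval `Bias_j ± HW_j` is built by a hierarchical cluster
bootstrap with parametric simulation of future errors: per outer
iteration, assays are resampled with replacement (among assays carrying
the level) and blocks are resampled within each sampled assay; bias and
the log–log variance model are refitted; M standard-normal future errors
`e* = Bias* + Z·σ̂*_pred` are simulated; the inner half-width is the 95th
percentile of `|e* − Bias_obs|`; and `HW_j` is the 95th percentile of the
inner half-widths over B iterations.

Three numerical choices matter here:

1. **Deviations are measured from the observed bias** (the interval
   center), so the bootstrap shift of the center contributes to the
   half-width. Measuring from the per-iteration bootstrap bias would
   cancel the bias refit entirely and the interval could not approach its
   nominal content.
2. **Resampling shrinkage is corrected.** Case resampling of A assays and
   m blocks deflates the resampled between- and within-group sums of
   squares by (A−1)/A and (m−1)/m; the refitted components are rescaled by
   the inverse factors (fixed design constants) so they are unbiased for
   the sample's components.
3. The inner |Z|-sample is drawn once per outer iteration and shared
   across levels (scaled by each level's refitted σ̂_pred); the per-level
   marginal half-width distribution is unchanged, only the joint across
   levels — which the per-level outer percentile never uses — differs.
   This keeps B = 4000, M = 1000 (the defaults) cheap.

**Known limitation.** Even with these corrections, four assays provide too
little replication for the bootstrap's 95th percentile to represent the
full sampling uncertainty of the variance components. On synthetic ground
truth with `σ_B` below the detectability floor, the acceptance test suite
measures a meta-coverage of ≈0.87 (fraction of repetitions in which the
interval truly contains ≥95 % of future errors) against the nominal 0.95;
a parametric-bootstrap variant is worse (≈0.77) because truncated `σ_B`
estimates collapse its between-assay spread. The β-expectation interval,
whose t-quantile handles finite df analytically, measures ≈0.96 expected
coverage under the same conditions and is the primary acceptance
criterion; the content interval is confirmatory.

## Calibration and its inference

Measured total HCP is regressed on nominal spike amount by WLS with
inverse empirical per-level variance weights (pooled across assays,
denominator n−1; a zero-variance level borrows the smallest positive
level variance) and HC3 sandwich standard errors, testing β₀ = 0 and
β₁ = 1. The implied relative bias `100·(β₀/x + β₁ − 1)` links the fitted
compression (slope < 1) and offset (intercept > 0) to the trueness
profile; it decreases monotonically in x toward `100·(β₁ − 1)`.

**Known limitation.** HC3 assumes independent errors. Replicate blocks
within an (assay, level) cell share a between-assay effect, and the
weights are themselves estimated (with only 2 df at single-assay levels),
so HC3 intervals undercover in this design: on synthetic truth the
acceptance suite measures ≈83 %/76 % coverage for intercept/slope (and
≈80–90 % for stratified slopes) against the nominal 95 %. Point estimates
are unbiased (mean slope error ≈0.03 % over hundreds of repetitions). The
robust-sandwich convention is kept because it is the convention of the
procedure being implemented; users needing calibrated interval coverage
at A = 4 should prefer cluster-aware inference.

## Identification error

Entrapment peptides are generated by shuffling each target peptide's
residues while fixing the C-terminal residue — the tryptic cleavage site;
the N-terminus is a cleavage product of the *preceding* residue and is
free to vary. Collisions with the target peptidome are redrawn up to 20
times, then dropped, and `r` is the achieved (not nominal)
entrapment-to-target ratio. Foreign-proteome entrapment is a set
difference against the target peptidome, with no length or composition
matching. `FDP(τ) = N_E(τ)·(1+1/r)/N_D(τ)` (0 when nothing is accepted);
uncertainty by peptide-level bootstrap percentile bands (default B = 1000)
and, at τ = 0.01, a Wilson 95 % interval scaled by (1+1/r). Requiring k
concordant peptides per quantified group attenuates protein-level error to
FDP^k under an independence approximation (≈10⁻⁷ at FDP 0.009, k = 3).

## Hi3 quantification and filtering

The filter chain order is single-hit exclusion → TIC normalization →
intensity-deviation screening (10× from the peptide's cross-run median,
both directions) → modified Z-score (cutoff 3.5; MAD scale 0.6745, mean-AD
fallback 1/1.2533) → replicate-CV filter (20 %). Normalization precedes
all outlier statistics so run-scale differences never masquerade as
outliers. Because removals can unbalance run totals or leave a peptide
newly single-hit, the sweep repeats until the kept row set is stable; at
the fixed point run totals are equal and the chain is exactly idempotent.
All thresholds are config-held and logged; "intensity deviation
screening" is this package's documented 10×-median interpretation of an
otherwise unspecified step. Hi3 selection takes the three
highest-mean-intensity peptides (ties broken by sequence); groups with
fewer than three quantifiable peptides are excluded with a reason code.
Molecular weights use average isotopic masses, the convention for
protein-level mass conversion.

## Parsimony inference

Greedy set cover with deterministic tie-breaks: most unassigned peptides,
then most total peptides, then lexicographically smallest accession.
Unclaimed accessions whose peptide sets are subsets of a selected
accession's set join that group as members; shared peptides belong to the
group selected earliest. The output is invariant to input order. On small
instances an exhaustive minimal-cover oracle bounds the greedy solution;
`greedy_excess` reports any excess over the optimum (≈4 % of random
instances, never silently accepted).

## Abundance-stratified analysis

Strata Q1–Q4 are fixed once from per-protein mean abundance at the anchor
level (L4), with cutpoints at the 5/25/50/75/100th percentiles (linear
interpolation; ties resolved by value then accession); proteins below the
5th percentile are excluded as unstable, and ≥120 proteins are required so
strata can clear the 30-protein cell floor. Cell reportables are bootstrap
expectations of cell means (default 10⁴ resamples; the expectation equals
the cell mean in the limit — the bootstrap is kept for fidelity to the
procedure and for its role in cell-level dispersion summaries). Relative
errors are taken on the ratio scale against the stratum's pooled L4
anchor, which forces zero mean bias at the anchor by construction;
stratified bias is therefore deviation from the anchor's systematic
component, not from ground truth. Stratum tolerance intervals reuse the
aggregate machinery with the variance model in the theoretical spike
ratio; the validated domain is the intersection of passing levels over
strata; LLOQ is the 95th percentile of Q1 reportables at the lowest
validated level (conservative; the mean is also reported), ULOQ the 5th
percentile of Q4 at the highest.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed). Defaults encode
the reference study conditions: calibration β₀ = 1.25 ng, β₁ = 0.798;
within-assay SD 2.3 % (the scale of the published median repeatability);
between-assay SD 1.5 % (the scale of the two non-truncated published
between-assay estimates — deliberately below the design's detectability
floor, so truncation behavior is exercised); stratum calibrations with
slopes 1.0588/0.9906/0.9029/0.7986 and intercepts 0.26/0.81/3.71/29.57
ppm; a log-normal abundance population (log-mean ln 20 ppm, log-SD 1.5,
spanning roughly 1–300 ppm as realistic for an HCP population); 5 %
per-protein residual CV; true FDP 0.009.

Noise is multiplicative on the ng scale (`Y = (β₀+β₁μ)·(1+(u+e)/100)`), so
the relative-error SD against nominal is the component SD scaled by the
recovery factor `(β₀+β₁μ)/μ`. The between-assay effect `u` is drawn per
(assay, level) and shared by that assay's blocks at the level — exactly
the grouping structure every per-level decomposition sees. It is *not*
shared across levels of an assay: cross-level sharing would act as an
assay-level random slope on the pooled calibration, which the reference
residual diagnostics (a common regression function without assay-specific
displacement) do not show.

What the generators do **not** emulate: spectra, retention times, ion
mobility, peptide-level missingness that is abundance-dependent,
correlated protein responses, or matrix effects. Passing tests therefore
demonstrate the correctness and calibration of the *statistical*
machinery under the stated error model, not the performance of any
laboratory workflow on real data.

## Entrapment score generator

True target peptides receive q ~ U(0, 0.005); false matches receive
q ~ U(0, 1) and are split between target and entrapment space in
proportion 1 : r, sized so the expected false fraction among acceptances
at q = 0.01 equals the requested FDP. The estimator is then unbiased by
construction at the operating threshold (measured mean 0.0091 vs truth
0.009 over 200 seeds), and invariant to r.

## Numerical conventions

Percentages are stored as percent, never fractions. Percentiles use
linear interpolation on order statistics. Acceptance bounds are closed.
Bracket recoveries of exactly 70 % or 130 % pass. I–MR charts use the
standard constants 2.66 (individuals limits) and 3.267 (moving-range UCL)
and withhold control limits below 10 observations (specification checks
still run). Deming regression defaults to error-variance ratio λ = 1
(both measurement systems treated as equally noisy); Bland–Altman
relative differences use the pairwise mean as denominator. Content
intervals are computed at single-assay levels too (resampling the one
assay that carries them), since the procedure reports them there;
their confidence statement is correspondingly weaker. All bootstrap sizes
(B, M, resamples) are configurable and seeded; reported runs in the test
suite use reduced sizes (B = M = 500, cell bootstrap ≤ 500) chosen as the
smallest sizes at which the Monte-Carlo error is negligible next to the
tolerances being tested.
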