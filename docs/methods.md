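# Methods

## Selection model

The unit of selection is a treatment round, not a day. One dose kills a
fraction `a_mut` of mutant cells and `a_wt` of wild-type cells, so the live
mutant:WT ratio multiplies by `r = (1 − a_mut)/(1 − a_wt)` per dose; the
dose schedule carries the timing. Two compounding conventions are exposed
and every output labels which produced it:

* **naive**: `f_n = min(f0 · rⁿ, 1)`. This treats a ratio multiplier as
  acting directly on a proportion. It is not self-consistent (the implicit
  denominator stays at 1) but it is the convention in which headline
  endpoint numbers for competition assays are usually quoted, so it is kept
  as a first-class model, clamped at 1.
* **normalized** (default): the odds update `odds_n = odds_0 · rⁿ`,
  `f_n = odds_n/(1 + odds_n)`. This is the exact expectation of the
  two-clone process when both clones regrow identically between doses, and
  it composes: n steps at r equal one step at rⁿ.

For r ≥ 1 the naive value dominates the normalized one pointwise; both
equal `f0` at n = 0. Compounding is always done at full floating-point
precision; rounding (ratio to 2 decimals, percentages to the nearest
integer) is applied only for display. This matters: 0.2 · 1.457⁴ = 0.902
prints as 90%, whereas compounding the already-rounded 1.46 gives 0.909,
which would print as 91%.

The key assumption, supported by cell-cycle data in this system, is that
proliferation is clone-neutral: the entire fitness difference is carried by
differential per-dose survival. An optional growth-advantage multiplier for
the untreated arm exists in the simulator spec (`growth` applies to both
clones; an asymmetric variant was deliberately left out of scope — see
Limitations).

## Stochastic simulator

`simulate_competition` tracks integer cell counts `(n_mut, n_wt)`. Per
dose: independent binomial survival draws with probabilities `1 − a_mut`,
`1 − a_wt`, then deterministic clone-neutral regrowth by the factor
`growth` (rounded to integers). Measurements are binomial draws of
`sample_size` cells at the current population fraction; on a dose day the
measurement precedes the dose. Zero counts are absorbing. If the whole
population dies the trajectory is truncated and flagged in
`meta["extinct_day"]` instead of raising, so batch simulations never abort.

Because regrowth is clone-neutral it cancels from the expected fraction;
its only role is to keep population sizes (and hence demographic noise)
realistic between doses. The default `growth = 2.0` per interval mirrors a
1:2 culture-split-and-regrow routine. With `n0 = 10⁶` cells, demographic
noise is small and the mean simulated endpoint agrees with the normalized
deterministic model to within Monte Carlo error (verified at 2,000
replicates, 3 MC SE).

Default study conditions (the `CompetitionSpec` defaults): starting mix
20:80 mutant:WT (`f0 = 0.20`), apoptotic fractions 0.49 / 0.65, doses every
4 days, 4 doses (days 0, 4, 8, 12 — the dosing count under a 15-day horizon
is not uniquely determined by "every 4 days", so 4 is the default and is
configurable), measurements on days 0/4/8/12/15 of 10,000 cells, 3
replicates. The simulated horizon is `n_doses · dose_interval_days`;
requesting a measurement beyond it is an error.

## Fitness estimation

`fit_fitness` maximizes the binomial log-likelihood
`Σᵢ log Bin(kᵢ | nᵢ, p(f0, r; dᵢ))` where `dᵢ` is the cumulative dose count
before measurement i and `p` is the chosen compounding model. The search is
a bounded 1-D minimization on `log r ∈ [ln 0.2, ln 5]` (tolerance 10⁻⁶ on
log r) with the baseline fraction profiled out by an inner bounded search
on `f0 ∈ (10⁻⁶, 1 − 10⁻⁶)`. The 95% CI is the profile-likelihood interval
at the χ²₁ cutoff 3.84, found by root bracketing on each side and clipped
to the search box when the likelihood never drops below the cutoff.
Degenerate data (all measurements at fraction 0 or all at 1) return a
flagged non-converged estimate with infinite bounds.

Replicates are pooled by summing counts at matching times
(`pool_trajectories`). Pooling averages out per-replicate demographic noise
that the pure-binomial likelihood does not model; at the default population
size this residual misspecification is small, and measured CI coverage at
the study conditions is ≈95% (asserted ≥90% over 100 seeded experiments).

`normalize_foldchange` re-expresses a trajectory as fold change over a
chosen baseline time (the standard presentation for post-transplant
chimerism, where the engraftment baseline varies per animal); the value at
the baseline is exactly 1 and a zero baseline fraction is an error.

## Cohort statistics

* 2×2 tables have fixed orientation a = factor⁺/outcome⁺, b = factor⁻/
  outcome⁺, c = factor⁺/outcome⁻, d = factor⁻/outcome⁻; rows with missing
  values are excluded listwise per comparison and the exclusion count is
  carried on the table (clinical chart data are routinely incomplete).
* Odds ratio ad/bc with the Woolf log-scale CI
  `exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))`, z fixed at 1.959964. Zero
  cells get the Haldane–Anscombe +0.5 added to every cell, applied only
  when needed and always flagged; this keeps log-ORs finite for
  co-occurrence displays. The exact p is always computed on uncorrected
  counts.
* Fisher's exact test uses the two-sided "sum of tables no more probable
  than the observed" convention (conventions differ; this is the most
  common and the one scipy implements). The test suite checks it
  exhaustively against an independent enumeration oracle on all tables with
  total ≤ 12.
* FDR is Benjamini–Hochberg step-up by default; Benjamini–Yekutieli is
  selectable where dependence is a concern. The co-occurrence matrix
  adjusts over all unordered pairs; the exposure scan adjusts over the
  estimable exposures only (zero- or full-prevalence exposures are flagged
  non-estimable and kept out of the family).
* Co-occurrence sign convention: positive log-OR = co-occurrence, negative
  = mutual exclusivity. Derived strata such as "GENE clonal" (cases whose
  variant in GENE exceeds a VAF threshold, default 0.2 strict) can be added
  as extra items.

## Variant-level conventions

* VAF retention filter: keep `vaf ≥ 0.02` (inclusive), the conventional
  detection floor for targeted sequencing; idempotent and monotone in the
  threshold.
* Clonal classification: `vaf > threshold` strictly, default 0.2.
* CCF = `vaf · (purity·cn_tumor + (1 − purity)·cn_normal) / (purity·
  multiplicity)`, clamped to [0, 1], flagged when the raw value exceeds
  1.05. The formula is the standard purity/copy-number adjustment;
  multiplicity defaults to 1 (heterozygous point mutations, the consistent
  state for *PPM1D* in clonal hematopoiesis). Copy number is an input, not
  computed.
* HGVS-p parsing accepts bare and `p.`-prefixed forms and both `X` and `*`
  stop notations; `fs` marks frameshifts; truncating ⇔ nonsense or
  frameshift; non-protein notation returns `unparsed` rather than raising.
  Exon assignment uses a user-supplied residue-range map; a provisional
  *PPM1D* map ships with the package (exon boundaries approximate).
* Lineage concordance: a variant at or above the limit of detection
  (default 0.02, mirroring the retention filter) in both lymphoid and
  non-lymphoid sorted fractions is called multilineage, consistent with a
  stem/progenitor origin.

## Synthetic data

The generators define the study conditions rather than fitting any real
dataset:

* **Cohort**: `n_case` therapy-related and `n_control` de-novo-like
  samples. Exposure flags are Bernoulli at the configured prevalence for
  every sample. Per-gene mutation probability starts at `base_rate` on the
  logit scale and shifts additively by the planted
  `effect_log_or[(exposure, gene)]` per positive exposure and
  `cooccur_log_or[(g1, g2)]` per already-mutated earlier gene (genes drawn
  in list order); the logistic form matches the odds-ratio analyses
  downstream. One variant per mutated (sample, gene); multi-hit samples are
  out of scope.
* **VAF**: Beta(0.262, 1.048) rescaled to [0.02, 0.47]. The shapes were
  solved by moment/quantile matching so the scaled mean is 0.11 and the
  scaled median 0.05, the reported cohort summary; only range/mean/median
  are constrained, so the shape family is a modeling choice.
* **Competition / chimerism**: replicates run the selection simulator on
  streams spawned from one root `SeedSequence`, so replicate k is
  individually reproducible and reruns are byte-identical. The chimerism
  generator first thins each clone's initial pool independently by a
  binomial draw at `engraft_frac`, modeling the transplant engraftment
  bottleneck; this widens the baseline spread around `f0` (some replicates
  start well below the mixed-in fraction, as observed post-transplant)
  without shifting its mean. At `engraft_frac = 1` it is exactly the
  plain competition generator.

What the generators deliberately do not emulate: sequencing reads and their
error modes, copy-number profiles, covariate structure between exposures
(each is drawn independently), clone-specific engraftment deficits, and any
baseline proliferation advantage. Tests passing on synthetic data therefore
validate the statistical machinery and its calibration under the stated
model, not robustness to those real-data features.

## Numerical choices

* 95% z fixed at 1.959964; χ²₁ cutoff 3.841459.
* Model fractions clamped to [10⁻¹², 1 − 10⁻¹²] inside likelihoods.
* Integer regrowth rounding uses round-half-even via `round`; exact for the
  default integer growth factor.
* Problem sizes used by the shipped checks — 2,000 replicates for
  simulator/deterministic agreement, 100 seeded experiments for CI
  coverage, 200 seeded cohorts for null FDR control, exhaustive 2×2 sweep
  to total 12 — were chosen to make Monte Carlo error comfortably smaller
  than the asserted tolerances while keeping the suite quick.

## Known limitations

* The binomial likelihood ignores between-dose demographic noise; at small
  population sizes (strong bottlenecks, near-extinction) the CI will
  undercover. Pool replicates or enlarge `n0` when this regime matters.
* Exactly two clones; no multi-clone competition, no spatial structure, no
  cell-cycle phase modeling.
* The naive compounding model is intentionally unnormalized and should not
  be used for simulation or fitting, only for reproducing proportion-times-
  ratio style calculations.
* The exposure scan is unadjusted (no covariate regression); planted-truth
  recovery says nothing about confounding in real cohorts.
* The provisional *PPM1D* exon map is approximate and should be replaced
  with authoritative coordinates for any real annotation use.
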