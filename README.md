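# cskit — clonal selection under cytotoxic therapy

`cskit` is a toolkit for quantifying how a drug-resistant hematopoietic
clone expands under repeated chemotherapy dosing, built around the dynamics
of *PPM1D*-mutant clonal hematopoiesis. Truncating *PPM1D* mutations dampen
the p53 DNA-damage response, so mutant cells die less readily under
DNA-damaging agents such as cisplatin; over repeated treatment cycles this
modest per-dose survival difference compounds into clonal dominance. The
package is aimed at researchers analyzing clonal hematopoiesis cohorts and
in vitro / in vivo competition assays.

## The model

With per-dose apoptotic fractions `a_mut` and `a_wt`, one dose shifts the
live mutant:WT cell ratio by

```
r = (1 − a_mut) / (1 − a_wt)
```

e.g. 49% vs 65% apoptosis gives r = 0.51/0.35 ≈ 1.46 per dose. Over n
doses the mutant fraction f evolves two ways, both exposed:

* **naive** — `min(f0 · rⁿ, 1)`: the ratio applied directly to a
  proportion, the usual back-of-envelope form (0.20 · 1.457⁴ ≈ 0.90);
* **normalized** (default) — the consistent two-clone odds update
  `odds_n = [f0/(1−f0)] · rⁿ`, returned as `odds_n / (1 + odds_n)`.

A stochastic simulator draws binomial survival per clone per dose with
clone-neutral regrowth in between and binomial counting noise at each
measurement, and a maximum-likelihood estimator inverts the model: given a
measured trajectory and the cumulative dose count at each time, it fits r by
profile likelihood with a χ²₁ 95% confidence interval.

Around the core model the package provides cohort statistics (2×2
enrichment with Woolf CIs and Haldane–Anscombe correction, Fisher's exact
test, Benjamini–Hochberg FDR, pairwise co-occurrence / mutual-exclusivity
matrices, exposure scans), variant-level utilities (VAF retention filter,
clonal classification, cancer-cell-fraction conversion, HGVS-p consequence
parsing, lineage concordance), and synthetic-data generators that plant
known ground truth so every stage is testable without patient data.

## Worked example

```python
from cskit.selection import (CompetitionSpec, fit_fitness, pool_trajectories,
                             predict_trajectory, SelectionParams, survival_ratio)
from cskit.synthetic import generate_competition

r = survival_ratio(0.49, 0.65)
print(f"per-dose ratio r = {r:.3f}")

params = SelectionParams(f0=0.20, r=r, model="normalized")
print("expected mutant fraction per dose:",
      [round(f, 3) for f in predict_trajectory(params, 4)])

spec = CompetitionSpec(replicates=3, seed=7)   # 20:80 mix, 4 doses, triplicate
trajs = generate_competition(spec)
pooled = pool_trajectories(trajs)
est = fit_fitness(pooled, {0.0: 0, 4.0: 1, 8.0: 2, 12.0: 3, 15.0: 4})
print(f"fitted r = {est.r_hat:.3f}  (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
```

prints

```
per-dose ratio r = 1.457
expected mutant fraction per dose: [0.2, 0.267, 0.347, 0.436, 0.53]
fitted r = 1.461  (95% CI 1.449-1.473)
```

A mutant clone starting at 20% of the culture is expected to reach ~53% of
cells after four doses under the odds update, and the estimator recovers
the generating per-dose ratio (1.457) from three simulated flow-cytometry
trajectories, with the truth inside the profile-likelihood interval.

The same operations are available from the shell:

```
cskit predict --f0 0.2 --r 1.46 --n-doses 4 --model naive
cskit simulate --seed 7 --out run/
cskit enrich --cohort cohort.tsv --gene PPM1D --exposures cisplatin,etoposide
```

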