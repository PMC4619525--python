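# Methods

## The evaluation procedure

The package evaluates sampling strategies by Monte Carlo simulation on a
finite population of hospitals for which strata (academic / teaching /
general), region, bed count and the outcome counts (RBC, FFP, PLT issues)
are known. One evaluation replicate is:

1. draw a sample with the strategy under study (stratified 1:1:1 by type);
2. fit, per product, a Poisson regression with log link on the sample
   (terms: intercept, academic and teaching indicators with `general` as
   reference, beds);
3. predict the expected count for every hospital in the population —
   sampled hospitals included;
4. score the prediction with the hospital-level error
   (summed absolute errors as % of the population total) and the
   national-level error (absolute deviation of the summed estimate, same
   denominator).

Errors are computed over *all* hospitals. The alternative reading — score
only the non-sampled hospitals — is available via `holdout_only=True`
(`--holdout-only` on the CLI); it barely changes the rankings but shifts
levels, since in-sample hospitals are predicted comparatively well.

Deterministic strategies (LARG, MAXVAR) are pure functions of the
population, so they are evaluated once per scenario and the result is
replicated logically. For 2REG, each replicate first draws one of the 21
region pairs uniformly, so the reported distribution pools over pairs; a
fixed pair can be passed to inspect pairs separately (the between-pair
differences are large, because pairs differ in how well their hospitals
span the national size range).

## The Poisson fit

Maximum likelihood via iteratively reweighted least squares: initialization
at the null model with intercept `log(mean(y) + 0.5)`, convergence when the
relative deviance change falls below 1e-8, cap of 100 iterations. The fit
is a compact numpy implementation because a full comparison performs on the
order of 10^5 fits on 6–18 observations; it is verified in the test suite
against closed-form MLEs, a derivative-free maximizer of the explicit
log-likelihood, and statsmodels' Poisson GLM. Two contracts follow from the
log-link score equations and are asserted throughout: in-sample fitted sums
equal observed sums (hence the national error of a full-population "sample"
is ~0), and the national error never exceeds the hospital-level error.

Rank-deficient designs (e.g. a stratum missing from a sample) raise an
error naming the offending term; strategies stratify by type, so this
cannot arise in the standard workflow. Non-converged fits mark the
replicate as failed; failed replicates are excluded from summaries and
their count is reported, since silently including them would corrupt the
centiles. No overdispersion correction is applied in fitting — the error
metrics use point predictions only. One joint model with additive type
indicators is fitted rather than three per-stratum models: every scenario
samples all strata, so the indicators are always estimable, while 12
observations cannot support interactions. Per-type beds slopes are exposed
(`per_type_slopes=True`) for sensitivity analysis.

## The synthetic population generator

Real blood-bank issue data are proprietary, so experiments run on synthetic
populations emulating the documented structure: 89 hospitals
(8 academic / 28 teaching / 53 general), 7 regions with one academic centre
each except Noord-Holland with two, and counts that grow exponentially with
beds within a stratum. For hospital *h* and product *p*:

```
beds_h ~ DiscreteUniform(range of type(h))
count_{p,h} ~ Poisson(mu),
log mu = a[p, type(h)] + b[p]·beds_h + σ·Z_h + s_p·W_{p,h} − (σ² + s_p²)/2
```

with `Z_h` (shared across products) and `W_{p,h}` independent standard
normals; the half-variance term makes `E[count | beds] = exp(a + b·beds)`,
so the generating coefficients are recoverable by the fitted model.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| beds ranges | academic 700–1350, teaching 400–900, general 150–600 | size-separates strata with partial overlap; no public bed tabulation exists, so these are plausible Dutch magnitudes |
| intercepts `a`, slopes `b` | see `GeneratorConfig` | give mid-stratum mean counts of ≈2000/5000/14000 (RBC), ≈300/900/3500 (FFP), ≈350/1100/5000 (PLT) per year |
| `latent_sd` σ | 0.25 | shared hospital effect; raises all cross-product correlations (monotonically — a tested property) |
| `product_sd` s_p | RBC 0.10, FFP 0.35, PLT 0.26 | per-product case-mix noise; lowers cross-product correlations |
| `seed` | 0 | generation is deterministic given config + seed, byte-for-byte after CSV round-trip |

A shared latent effect alone cannot *lower* correlations, and at realistic
count magnitudes Poisson noise is negligible on the rank scale — without
per-product noise the cross-product Spearman correlations would sit near
.99. The `product_sd` terms, representing case-mix differences between
hospitals (e.g. platelet use concentrating in hospitals with intensive
haemato-oncology), are therefore part of the generating model, and their
defaults were set by grid search so that the default population reproduces
the observed calibration targets: Spearman(FFP, RBC) ≈ .88 and
Spearman(PLT, RBC) ≈ .92 (mean over repeated generation; a tested
property). With this calibration the resulting inference difficulty is
realistic too: a stratified random sample of 12 hospitals yields a median
hospital-level RBC error around 19 %.

### What the generator does not emulate

The generated counts deviate from the fitted log-linear Poisson model only
through *i.i.d.* log-normal hospital effects. Real hospital data
additionally carry **structured** deviations — curvature in the size–use
relationship, regional practice styles, a right-skewed size distribution —
and it is exactly such structure that gives maximum-variation sampling its
documented advantage: anchoring the extremes of the covariate range
protects model-based extrapolation when the model is imperfect at the
extremes. On populations from this generator the fitted model is correctly
specified by construction, so that mechanism cannot operate; worse,
selecting hospitals by extreme RBC counts partly selects extreme latent
effects, which biases the fit. Consequently MAXVAR does *not* outperform
random sampling here (it wins in a small minority of generated
populations), whereas analyses of real data report the opposite ranking.
Passing simulations on this generator therefore validate the machinery —
selection rules, inference, error metrics, replication — not the
substantive superiority of any strategy on real data; to compare strategies
for a concrete study, run the package on that study's own proxy data.

## Numerical and design choices

* **Tie-breaks.** Equal beds (LARG) or equal RBC counts (MAXVAR) resolve by
  ascending hospital id — reproducibility over arbitrariness. MAXVAR's odd
  seat goes to the high-use end by default (`high_end_extra=False` flips
  it).
* **2REG seat split.** The scenario's per-stratum n is split evenly over
  the two regions, the odd seat assigned to a random region; a region with
  too few hospitals contributes all of them and the remaining seats move to
  the other region; a joint shortfall is recorded on the selection. The
  academic stratum is not governed by the scenario: it is whatever academic
  centres the two regions host (2, or 3 with Noord-Holland).
* **Centiles.** 2.5th/97.5th with linear interpolation between order
  statistics (numpy's `linear` method).
* **Head-to-head ties** count as *not* outperforming — conservative toward
  the purposive strategy.
* **Batching.** Random strategies run in independent batches
  (default 10 × 1000); the report averages per-batch summary statistics and
  also reports the between-batch spread of the median. `n_batches=1`
  reduces exactly to a single replicate run.
* **Seeding.** One top-level seed; substreams derive from
  `SeedSequence(seed, spawn_key)` with strategy/batch/replicate keys
  (strings CRC-32-mapped), so adding a strategy or product never perturbs
  another's draws.
* **Rounding.** Percentages are carried at full precision everywhere and
  rounded to whole percent only in the human-readable table.
* **Problem sizes.** Defaults mirror the replication design above
  (10 × 1000 replicates per random strategy and scenario); the bundled
  tests and the acceptance script use the same sizes for the scenario-A
  comparison and smaller replicate counts (200–400) where only a median's
  location is needed.

## Known limitations

* Strategy comparisons on synthetic populations inherit every generator
  assumption; see above.
* Prediction uncertainty (intervals) is out of scope — the metrics are
  functions of point predictions.
* The generator draws non-academic regions uniformly, so regional effects
  on blood use are absent by construction; REGVAR can show no advantage
  over RAND here even in principle.
* The distance-maximizing variant of maximum-variation sampling (spreading
  hospitals evenly along the outcome range rather than taking the two
  extremes) is not implemented.
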