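# Methods

This note records the statistical model each stage implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want spelled out.

## Censoring model and data layout

A qPCR run of `max_cycles` (default 40) right-censors every species whose
fluorescence never crosses threshold. `CqMatrix` keeps the censoring
explicit: a boolean `detected` mask alongside the C_q values, with every
censored cell held at the sentinel `max_cycles`. Imputation is idempotent
and re-applied on construction, so a matrix can never carry a stale
sentinel. Downstream stages interpret the censoring differently on
purpose: the continuous DE branch drops censored cells (treating the
sentinel as missing, not as a measurement), the detection branch uses the
mask itself as the response, and the signature stage maps the sentinel to
a feature value of exactly zero (F = max_cycles − C_q), which encodes
"nothing measurable" as "zero concentration contribution".

## Normalization

For each sample and panel the factor is the mean C_q of that panel's
reference species (three miRNAs, three small RNAs), replicate wells
averaged first, references below detection dropped from that sample's
factor rather than imputed — imputing the sentinel would corrupt the
factor by design. Normalized C_q = raw − (factor − grand mean of the
panel's factors across samples); centering at the grand mean keeps values
on the cycle scale. The centering convention (grand mean rather than the
spike-in) is recorded in `NormalizedCq.method_tag` as
`panel-mean-centered`. This removes any additive per-sample offset
applied to all species exactly; what remains is the factor's estimation
noise, of order noise_sd/sqrt(#references), which is shared across
species within a sample (see "known limitations").

Fold changes use FC = 2^(−ΔΔC_q) with ΔΔC_q = ΔC_q(miRNA) −
ΔC_q(UniSp3). The spike-in's own group difference is estimated once from
its posterior median and subtracted from every species' effect draws.
No amplification-efficiency correction (non-base-2 models) is applied.

## Two-branch Bayesian differential expression

Routing: species detected in strictly more than 65% of samples
(`threshold=0.65`) take the continuous branch, all others the detection
branch.

**Continuous branch.** Normalized C_q of detected samples is regressed on
an MA indicator and a sex indicator (the sex column is dropped when only
one sex is present). Priors: uniform(−80, +80) cycles on each location
effect — the widest difference expressible over a 40-cycle run — and the
Jeffreys prior 1/σ² on the residual variance. Under these priors the
posterior of the coefficient vector is a scaled multivariate Student-t
truncated at the bound, so the sampler draws exact i.i.d. posterior
samples (normal–inverse-χ² draw, rejection at the bound; the rejected
mass is negligible at these data sizes). This replaces MCMC for this
branch: i.i.d. exact draws trivially satisfy any convergence criterion
and make 722-species panels run in seconds.

**Detection branch.** The detect indicator is regressed on the same
design via Bayesian logistic regression. The intercept prior is standard
logistic, equivalent to a uniform(0,1) prior on the baseline detection
probability; effect priors are Normal(0, 5²) on the log-odds scale,
proper enough that complete separation yields a finite posterior (flagged
`separation:<group>` in the record, never an error). Sampling is adaptive
random-walk Metropolis, 4 chains × 2500 kept draws after 1000 warmup
(scale tuned every 50 warmup iterations toward 30% acceptance), with a
split-R̂ check; R̂ > 1.01 flags the record.

**Posterior odds and grading.** For draws of a signed effect,
p = (k + 0.5)/(S + 1) where k is the number of draws agreeing with the
sign of the posterior median — a Jeffreys-style continuity correction so
finite draws never produce infinite odds — and POR = p/(1−p), floored at
1. With the default 10 000 draws the ceiling is 20 001. Grades:
[1,3) bare mention, [3,20) positive, [20,150] strong, strictly above 150
very strong (the upper boundary is honored strictly; lower boundaries are
closed on the left). Effects are graded on the expression scale, so for
the continuous branch the sign of −ΔC_q is used ("up" = more abundant in
the first contrast arm).

Null calibration of this directional POR is a property of the t tail,
not of the sampler: with flat priors a null species crosses POR = 150
when its |t| statistic exceeds t_{n−3}(150/151) ≈ 2.67, probability
≈ 1.3% at n = 27. On a 722-species null panel roughly 9 ± 3 species
therefore reach "very strong" by chance; the test suite asserts rates
against this calibration. A POR defined as a Bayes factor against a point
null would be far more conservative, but it is not the directional
quantity implemented here.

Per-species failures (confounded designs, empty groups after censoring)
become flagged null records; a batch never aborts. All randomness derives
from `default_rng([seed, species_index])`, so results are reproducible
and independent of evaluation order.

## Targets, enrichment, biclustering

Consensus targets require agreement of ≥2 sources (set semantics;
monotone in added sources). The enrichment universe defaults to the union
of all source-predicted genes, configurable — the alternative (a full
gene catalog) would silently depend on an external resource. P-values are
upper-tail hypergeometric (scipy), adjusted by Benjamini–Hochberg
(statsmodels), significance at q ≤ fdr (default 0.05). The packaged
demo target tables, renal list and GMT under `mirualb/data/demo/` are
synthetic stand-ins generated for offline testing, not excerpts of any
real prediction database.

The evidence × target matrix holds log-POR where a consensus relation
exists and the floor log(1) = 0 — "lowest possible evidence" — elsewhere.
Extraction is greedy alternating selection maximizing the within-mean:
from a start cell, keep columns whose mean over the current rows is
within a factor (1 − tol) of the best column, then rows symmetrically,
to a fixed point; multistarted from the best cell plus seeded random
cells; ties broken toward larger area then earlier start. At `tol = 0`
selection cannot dip below the best single cell (the strict guarantee
tested at that setting) but also cannot grow past exact ties; the default
`tol = 0.25` trades the guarantee (worst case (1 − tol) × best cell) for
recovery of noisy blocks. Published bicluster dimensions from real data
are descriptive and not reproduction targets.

## Prognostic signature

Design: P main features F = max_cycles − C_q, one women indicator, P
sex-by-feature interactions — 2P + 1 predictors, named with an
`" X Women"` suffix for interactions. Features are not standardized: they
share the cycle scale, and the published coefficient convention is
log-odds per cycle-unit of F.

Objective: −(1/n)·loglik + λ Σ_j w_j (α|β_j| + (1−α)/2 β_j²), intercept
unpenalized. α defaults to 0.5 (neutral between ridge grouping — miRNA
families are correlated — and lasso sparsity), exposed. Penalty factors
w_j = (1 + renal count)^(−γ) apply identically to a miRNA's main and
interaction columns; the sex indicator keeps weight 1; γ = 0 recovers the
concentration-only model. γ is tuned on the grid {0, 0.25, …, 2} jointly
with λ by LOCV. The direction (more renal targets ⇒ less shrinkage)
implements the prior that kidney-relevant miRNAs should be favored.

Solver: IRLS with cyclic coordinate descent and soft-thresholding
(numba-compiled), active-set iteration with full-sweep violation checks,
fitted probabilities saturated at 10⁻⁵ from the boundaries so working
residuals stay bounded near separation, convergence at 10⁻⁷ maximum
coefficient change within the working problem and 10⁻⁶ across IRLS
reweightings (≤10 reweightings). The λ path (20 values, geometric, from
just above the smallest all-zero λ down to 1% of it) is warm-started.
The solver agrees with scikit-learn's saga elastic net to ~10⁻⁹ at
uniform weights (tested); per-feature penalty factors, which sklearn's
logistic elastic net does not expose, are the reason it is in-package.

LOCV refits the path on each n−1 subset and predicts the held-out sample
at probability threshold 0.5; a training fold collapsing to one class
predicts that class (so the held-out sample of the other class counts as
an error — never an abort). Hyperparameter ties at the optimal
misclassification break toward larger λ (sparser), then smaller γ; all
tied settings are refit on the full data and coefficient-averaged into
the reported composite (`averaged_from` records how many). LOCV equality
with cold brute-force refits is exact and tested at n ≤ 8.

Scoring is affine: log-odds = intercept + Σ coef·feature, probability its
logistic transform. Missing features score as 0 with a warning; for men
every interaction feature is 0 by construction. Membership strips the
interaction suffix and deduplicates. Per-feature AUC is the rank-based
(Mann–Whitney) area with midrank ties, via scikit-learn.

The packaged coefficient table lists 14 distinct miRNAs in the
concentration-binding column although the accompanying text counts 13;
the membership operation reports what it counts (the two columns share 9
miRNAs either way). The published LOCV rates of the original cohort are
not reproduction targets: they require the original 27 × 722 matrix,
which is external supplementary data.

## Synthetic generator

`SynthConfig` defaults mirror the realized study design: 27 samples —
10 never-progressors (5 women) and 17 future-MA (8 women) — and 722
assay species. Latent C_q = species baseline (Normal(28, 3²) across
species) + per-sample global offset (Normal(0, 1), emulating input and
extraction variation; removed exactly by reference normalization) +
planted MA shift + planted sex shift + well noise (Normal(0, 0.5²));
values above 40 become non-detects, implementing censoring on the latent
scale. Reference species sit at baseline ≈ 22 with 3 replicate wells
(replicate noise 0.15); the spike-in at 20 shares only the per-sample
offset, as an exogenous control should. Planted effects default to ±2
cycles (4-fold), an effect size recoverable at n = 27. The truth record
returns every planted parameter for scoring recovery.

What the generator does **not** emulate: correlation among miRNA family
members (each species' noise is independent), heavy-tailed or
heteroscedastic well noise, plate/batch structure beyond a single global
offset per sample, and any dependence of expression on age, duration or
HbA1c. Passing recovery tests therefore show the pipeline recovers
additive shifts under independent Gaussian noise at the study's n — not
that it would perform identically on real urine profiles, where
family-level correlation makes selection among correlated markers harder
(the elastic net's grouping behavior is motivated by exactly that case).

Problem sizes in the test suite are scaled for single-CPU runs: the
planted-recovery study uses 100-species panels (201 predictors) over 10
generator seeds, and the null-calibration study one 722-species panel.

## Determinism

Every stochastic stage takes a seed; per-species generators derive from
`(seed, species index)`; the pipeline runner hashes every artifact and
writes headers carrying version, seed and a config hash (excluding output
paths), so reruns with the same seed are byte-identical.
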