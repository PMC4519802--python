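# mirualb

Urinary microRNA qPCR analysis for prognosis of microalbuminuria in Type 1
diabetes: censoring-aware normalization, Bayesian differential expression
ranked by posterior odds, target/pathway annotation with renal-gene
weighting, and a penalty-weighted elastic-net prognostic signature.

## The problem

Microalbuminuria (urinary albumin 20–200 μg/min) is the earliest clinical
marker of diabetic nephropathy, but it appears only after structural kidney
damage has begun. Urinary microRNAs are stable, abundant and mechanistically
tied to renal disease, making them candidate biomarkers that could flag
future progressors while they are still normoalbuminuric. `mirualb`
implements the full analysis pipeline for a small prospective qPCR panel
study of this kind — normoalbuminuric urine from patients who never
progressed (N) versus patients who later developed intermittent or
persistent microalbuminuria (MA) — and ships a synthetic-data generator
that emulates the study design so every stage runs and is tested offline.

## The model

**Censored qPCR data.** Each species yields a quantification cycle
C_q ∈ (0, 40]; species that never cross threshold within 40 cycles are
right-censored and imputed at C_q = 40. Per-sample, per-panel
normalization factors (the mean C_q of reference species miR-423-5p,
miR-103, miR-191, U6, SNORD38B, SNORD38A) absorb loading and extraction
offsets; fold changes follow the delta-delta rule
FC = 2^(−ΔΔC_q), ΔΔC_q = ΔC_q(miRNA) − ΔC_q(UniSp3 spike-in).

**Two-branch Bayesian differential expression.** Species detected in >65%
of samples enter a Bayesian linear regression of normalized C_q on group
and sex (uniform priors on ±80 cycles; exact posterior sampling); the
rest enter a Bayesian logistic regression of the detect/non-detect
indicator (uniform prior on the baseline detection probability;
random-walk Metropolis). Each species is ranked by the posterior odds
(POR) that its effect lies in the direction of the posterior median,
graded 1–3 (bare mention), 3–20 (positive), 20–150 (strong), >150 (very
strong).

**Targets and biclustering.** Consensus targets are genes predicted by ≥2
of ≥3 sources; per-miRNA renal-target counts intersect the consensus with
a curated kidney-gene list; pathway over-representation uses the
hypergeometric upper tail with Benjamini–Hochberg FDR; a greedy
alternating row/column search extracts the dominant bicluster from the
log-POR × target-incidence matrix.

**Prognostic signature.** Each miRNA contributes the feature
F = 40 − C_q (zero when censored), plus a women indicator and
sex-by-feature interactions (2P+1 predictors for P species; 1445 for the
722-species panel). An elastic-net logistic regression (in-package
coordinate-descent solver with per-feature penalty factors) selects the
signature; penalty weights (1 + renal targets)^(−γ) shrink
kidney-relevant miRNAs less, with λ and γ tuned by leave-one-out
cross-validated misclassification and tied settings coefficient-averaged.
A sample's score is intercept + Σ coef·feature; its logistic transform is
the probability of future microalbuminuria.

## Worked example

```python
import mirualb as m

cfg = m.SynthConfig(seed=7, n_species=100)
planted = [cfg.species_name(i) for i in (4, 17, 33, 58, 91)]
cfg = m.plant_signature(cfg, planted, -2.0)       # 4-fold higher in MA
cq, samples, _ = m.generate(cfg)

panel = cfg.reference_panel()
de = m.DifferentialExpression(cq, samples, panel).fit(seed=7)
print(de.category_counts().to_dict())
print(de.summary().head(5)[["species", "expression", "por", "category"]])

controls = sorted({r for ref in panel.reference_species
                   for r in panel.members[ref]} | {panel.spike_in})
model = m.ElasticNetSignature.from_cq(cq, samples, exclude=controls).fit(seed=7)
print(f"LOCV misclassification: {model.locv_misclassification:.3f}")
print("signature:", sorted(m.signature_membership(model) & set(planted)))
```

prints

```
{'bare_mention': 41, 'positive': 45, 'strong': 8, 'very_strong': 6}
        species  expression      por     category
0  miR-sim-0005    3.757185  20001.0  very_strong
1  miR-sim-0018    3.583544  20001.0  very_strong
2  miR-sim-0034    4.364996  20001.0  very_strong
3  miR-sim-0059    3.472709  20001.0  very_strong
4  miR-sim-0092    4.323676  20001.0  very_strong
LOCV misclassification: 0.037
signature: ['miR-sim-0005', 'miR-sim-0018', 'miR-sim-0034', 'miR-sim-0059', 'miR-sim-0092']
```

The five planted species (a −2-cycle shift in the MA group, i.e. 4-fold
higher concentration) are exactly the top five by posterior odds, with
estimated fold changes 3.5–4.4 around the true 4, they saturate the
posterior-odds grade, and the elastic net recovers all five into the
signature with 1/27 held-out samples misclassified.

The same stages are scriptable from a shell:

```bash
mirualb synth --seed 7 --out-prefix sim/
mirualb io validate sim/cq.tsv sim/samples.tsv
mirualb de --cq sim/cq.tsv --samples sim/samples.tsv --seed 7 --out evidence.tsv
mirualb signature fit --cq sim/cq.tsv --samples sim/samples.tsv --seed 7 --out signature.tsv
mirualb run --config pipeline.yaml      # full chain + hashed manifest
```

Cq tables are TSV/CSV with species in the first column and one column per
sample; `NA`, `ND`, `Undetermined` or empty cells mark non-detects.
Sample tables carry `id, group (N|IMA|PMA), sex, age, hba1c, duration,
cycle` plus comorbidity flags. Target tables are `mirna<TAB>gene<TAB>source`,
renal lists one gene per line, pathways GMT. Small synthetic demo files
for the target stage ship under `mirualb/data/demo/`.

## Packaged study tables

`load_table1_fixture()` returns the 27-patient cohort annotation table
(10 N / 17 MA) and `load_table2_models()` the two published prognostic
models ("concentration-only" and "concentration-binding") as scoreable
`SignatureModel` objects.

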