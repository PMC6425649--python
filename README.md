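# breedgwas

Cross-breed GWAS meta-analysis and penalized risk modeling for
case/control SNP studies in closed populations.

## The problem

Purebred dog breeds are genetic isolates: a disease-risk allele that
segregates in one breed is often *fixed* (frequency 0 or 1) in another, so
a within-breed GWAS can only map loci that happen to vary in that breed,
and modest shared effects sink below genome-wide thresholds in every
single cohort. Canine osteosarcoma is the motivating case — a highly
polygenic bone cancer with case/control cohorts in Greyhounds, Irish
Wolfhounds and Rottweilers — but the machinery applies to any multi-cohort
case/control SNP study.

`breedgwas` implements the full analysis chain:

1. **Per-breed association scan** — the 1-df allelic chi-square on the
   2×2 allele-count table, χ² = N(ad − bc)² / (r₁r₂c₁c₂), no continuity
   correction; monomorphic/degenerate markers are kept with a validity
   flag.
2. **Intersection-union test (IUT) meta-analysis** — for every breed
   subset of size ≥ 2, a marker is a *valid* IUT test only if each member
   breed yields a defined p-value. The IUT omnibus p is max(p₁,…,p_k); in
   parallel, Fisher's combined probability X = −2·Σ ln pᵢ ~ χ²(2k) merges
   the independent cohorts. Significance is called on the Fisher p at a
   per-set Bonferroni threshold α / n_valid (comparison ≤), with Manhattan
   panels per breed set.
3. **Firth-penalized logistic risk models** — genotypes recoded 0/1/2
   (AA/AB/BB) enter as class variables (separate heterozygote and
   homozygote indicator levels, optional explicit "missing" level), no
   intercept. Estimation maximizes l(β) + ½·ln det I(β) via Newton steps
   on the modified score, which stays finite under the quasi-complete
   separation that small, strongly associated cohorts routinely produce;
   separated terms are detected by linear programming and flagged rather
   than silently reported.
4. **Model selection** — stepwise-forward at α = 0.05 in/out with
   whole-marker blocks tested by constrained penalized likelihood-ratio
   tests, or an L1 (LASSO) logistic path with the model chosen by lowest
   AIC = 2k − 2l and refitted by plain Firth.
5. **Evaluation and validation** — Cox–Snell and max-rescaled
   (Nagelkerke) R², AIC, Hosmer–Lemeshow calibration over deciles of risk,
   percent correct calls at a 0.5 cutoff; independent-cohort validation
   refits the fixed term set on the new cohort.
6. **Epistasis scan** — Wald test of the dosage-product coefficient in a
   per-pair logistic model over all candidate pairs, Bonferroni over
   testable pairs.
7. **Breed clustering** — UPGMA (arithmetic average linkage) on Euclidean
   distances between breed allele-frequency vectors at the candidate
   markers, with a ≥ 5-individuals filter and Newick export.
8. **Synthetic multi-breed cohorts** — a generator that emulates the
   study design (cohort sizes 153/114, 28/62, 80/55; Hardy–Weinberg
   genotypes from breed-specific Beta-distributed frequencies with
   breed-specific fixation; per-genotype-level logistic disease model at
   planted loci; case/control quota ascertainment; random missing calls),
   so every stage is testable without access rights to real genotypes.

## Worked example

```python
import breedgwas as bg
from breedgwas.iut import run_iut

breeds = ("Greyhound", "IrishWolfhound", "Rottweiler")
cfg = bg.SimConfig(
    seed=7, n_markers=2000,
    planted=(bg.PlantedLocus(0, {b: (2.5, 6.0) for b in breeds},
                             freq={b: 0.3 for b in breeds}),),
)
cohorts, truth = bg.simulate_cohort(cfg)
scans = {b: bg.scan_breed(c, b) for b, c in cohorts.items()}
results, thresholds = run_iut(scans, alpha=0.05)
print(thresholds[["breed_set", "n_valid", "threshold", "n_significant"]])
```

prints

```
                             breed_set  n_valid  threshold  n_significant
0             Greyhound∩IrishWolfhound     1999   0.000025              0
1                 Greyhound∩Rottweiler     2000   0.000025              1
2            IrishWolfhound∩Rottweiler     1999   0.000025              0
3  Greyhound∩IrishWolfhound∩Rottweiler     1999   0.000025              1
```

One locus (per-genotype odds ratios 2.5 / 6.0 in all three breeds at
risk-allele frequency 0.3) is planted among 1999 nulls. The significant
marker in the Greyhound∩Rottweiler pair and in the three-breed set is that
locus: the two larger cohorts carry enough signal for their pairwise
Fisher combination, the pairs involving the 90-dog Irish Wolfhound cohort
do not, and the three-breed combination recovers it — pooling evidence
across breeds detects what underpowered subsets miss. (n_valid drops
below 2000 where a marker happens to be monomorphic in a member breed;
each set's Bonferroni threshold is 0.05 over its own valid-test count.)
Fitting the locus as a risk model:

```python
from breedgwas.selection import stepwise_forward
from breedgwas.evaluate import evaluate_fit

gh = cohorts["Greyhound"]
spec, fit, design = stepwise_forward(gh, [gh.marker_ids[0]])
rep = evaluate_fit(fit, y=design.y)
print(spec.selected_terms, round(rep.max_rescaled_r2, 3), round(rep.hl_p, 3))
```

```
['SNP000000'] 0.106 0.189
```

The marker is selected; the single-locus model explains a modest share of
case/control status (max-rescaled R² = 0.106) with no evidence of lack of
fit (Hosmer–Lemeshow p = 0.189) — individual common variants of this
effect size carry real but limited predictive power, which is why the
risk models pool many loci.

A YAML-driven CLI runs the chain end to end
(`breedgwas run-all --config config.yaml`), with one subcommand per stage
(`simulate`, `assoc`, `iut`, `model`, `validate`, `epistasis`,
`cluster`).

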