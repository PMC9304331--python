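# jointgp

Joint-learning genomic prediction for complex polyploid grasses (sugarcane,
*Urochloa*, *Megathyrsus*) and other species with noisy, dosage-ambiguous
genotyping. Standard genomic selection models struggle in these crops:
genotyping-by-sequencing on high polyploids yields sparse, depth-variable
markers whose effects are diluted across unknown allele dosages, and
all-marker models often fail to find the signal. `jointgp` implements a
marker-engineering strategy around that problem: an ensemble of
classification and regression feature-selection techniques votes on every
SNP, and the combined marker sets feed Bayesian kernel genomic prediction.

## What is inside

* **Genotype encoding** (`jointgp.genodata`) — allele proportions
  (ref reads / total reads) from a VCF with `FORMAT/AD` or a marker TSV;
  depth ≥ 50 per call, ≤ 25% missing per marker, mean imputation; min-max
  trait normalization `f(v) = (v − min v)/(max v − min v)`.
* **Bayesian GP** (`jointgp.gibbs`, `jointgp.kernels`) — Gibbs samplers for
  Bayesian ridge regression (BRR), the single-environment Gaussian-kernel
  model (SM-GK, `K[i,i'] = exp{−(h/p) Σ_k (x_ik − x_i'k)²}`, h = 1) and
  RKHS kernel averaging (bandwidths 15/5/1 on median-scaled distances),
  with optional feature-selected fixed-effect marker blocks
  (`y = 1μ + Xα + Zγ + e`) and masked-response prediction for held-out
  individuals.
* **ML predictors** (`jointgp.ml`) — the configured baselines: KNN (k = 5),
  RBF-SVR with `θ = 1/(p·σ²_Z)`, random forest (100 trees), AdaBoost;
  SVC/RF/MLP/GNB for interval classification.
* **Phenotypic intervals** (`jointgp.intervals`) — nine clustering
  strategies with a cluster-number consensus over eight indices, k ∈ [2,10].
* **Feature selection** (`jointgp.featsel`) — classification trio
  (L1 linear SVC, ANOVA F p < 0.05, gradient tree boosting) and regression
  trio (L1 linear SVR, Pearson p < 0.05, GTB); marker sets C2/C3/R2/R3 and
  the combinations ICR2, CR2, CR3.
* **Evaluation** (`jointgp.evaluation`) — repeated (stratified) k-fold and
  LOO cross-validation, MSE + Pearson R, ANOVA + Tukey HSD model
  comparison, nested and non-nested FS protocols.
* **Breeding-program simulator** (`jointgp.breedsim`) — a wheat-style
  program (21 × 1000 SNPs, 70 founders, doubled haploids, nursery → PYT →
  AYT → EYT selection at heritabilities 0.1/0.2/0.5/0.67) producing 10,000
  PYT lines with known QTL architecture, so the whole pipeline is testable
  without any external data.

## Worked example

Simulate a breeding program, sample 100 PYT lines, run the joint
feature-selection stage and contrast SM-GK on all 21,000 markers with
SM-GK on the CR3 subset (10-fold CV, 4,000-iteration chain):

```python
from jointgp import SimConfig, run_breeding_program
from jointgp.workflows import select_markers_for_sample, smgk_accuracy_contrast

ds = run_breeding_program(SimConfig(qtl_per_chrom=100, seed=7))   # ~25 s
g, y, res = select_markers_for_sample(ds, 100, seed=7)
smgk_accuracy_contrast(g, y, res, seed=7)
print(f"intervals: k={res.interval_k}")
print(f"|C3|={len(res.sets['C3'])}  |R3|={len(res.sets['R3'])}  |CR3|={len(res.sets['CR3'])}")
print(f"marker reduction: {res.reduction_pct:.2f}%")
print(f"SM-GK all markers   R = {res.r_all:.3f}")
print(f"SM-GK / CR3 subset  R = {res.r_cr3:.3f}  (x{res.accuracy_ratio:.2f})")
```

```
intervals: k=9
|C3|=40  |R3|=31  |CR3|=71
marker reduction: 99.66%
SM-GK all markers   R = 0.263
SM-GK / CR3 subset  R = 0.834  (x3.17)
```

The 71 CR3 markers (0.34% of the panel) carry nearly all of the usable
signal at this sample size: the all-marker kernel model reaches R = 0.26
while the same model on the selected subset reaches R = 0.83. Note that the
default protocol selects markers on the full sample before cross-validating
(the reference procedure), so part of this gain is selection bias; use
`jointgp.evaluation.run_cv_joint(..., nested=True)` for leakage-free
estimates. See `docs/methods.md` for the models, defaults and the
simulator's fidelity limits.

A command-line interface mirrors the library for file-based workflows:

```bash
jointgp encode --vcf in.vcf --min-depth 50 --max-missing 0.25 -o markers.tsv
jointgp intervals --pheno pheno.csv --trait SH -o intervals.csv
jointgp select --markers markers.tsv --pheno pheno.csv --trait SH -o sets/
jointgp predict --model smgk --markers markers.tsv --pheno pheno.csv --trait SH
jointgp simulate --qtl-per-chrom 100 --sample 500 --seed 7 -o simdir/
```

## Acceptance script

`scripts/acceptance.py` recomputes the simulation-study quantities from
scratch: it runs the breeding program for several independent seeds,
samples 100/500/1000 PYT lines, performs the joint feature selection, and
measures the CR3 marker-reduction percentages and the SM-GK/CR3 versus
SM-GK accuracy contrast under 10-fold CV.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is roughly 15 minutes on one CPU; progress is logged to stderr and
the results are written as JSON.
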