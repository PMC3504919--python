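# iqspred

Predict the quality of genotype imputation for SNPs whose true alleles are
unknown.

## The problem

Genome-wide association studies genotyped on older arrays can be pooled with
newer data by imputing the missing markers, but imputation quality varies
wildly between loci, and the posterior probabilities reported by imputation
engines overstate it. The **imputation quality score (IQS)** fixes this by
applying Cohen's kappa to the imputed-vs-true genotype cross-classification
of a SNP: with `n_ij` the (posterior-weighted) number of individuals with
imputed genotype *i* and true genotype *j*,

```
Po  = Σ_i n_ii / n..                (observed agreement, = imputation accuracy)
Pc  = Σ_i n_i. · n_.i / n..²        (agreement expected by chance)
IQS = (Po − Pc) / (1 − Pc)          (Cohen's kappa)
```

IQS requires the truth, so it cannot be computed for the very SNPs one
actually imputes. `iqspred` closes that gap: it masks a fraction of typed
SNPs to create truth-labelled imputation examples, describes every imputed
SNP by 12 features (position, platform and reference-panel allele
frequencies, panel genotype ratios, distances to the nearest typed SNP and
recombination hotspot, the hotspot's rate in cM/Mb, mean best-guess
posterior and mean B-allele dosage), and trains a **ν-support-vector
regression** (RBF kernel, γ = 1/12, ν selected from {0.1, …, 1.0} by
10-fold cross-validation) to estimate IQS — or its components Po and Pc —
for SNPs without truth. Predicted IQS can then drive ROC-style filtering of
probable false-positive associations at imputed SNPs.

The package is aimed at statistical geneticists who post-process imputation
output (Beagle 3 style `.gprobs`/`.dose` text files) and want a per-SNP
quality estimate without an external truth set. A synthetic-data module
generates complete scenarios — a mosaic haplotype reference panel with
hotspot-concentrated recombination, study genotypes, platform SNP sets and
a surrogate imputer — so the entire pipeline is testable without downloads.

## Worked example

```python
>>> import numpy as np
>>> from iqspred import build_contingency, iqs
>>> truth = [0]*4 + [1]*4 + [2]*2            # 0=AA, 1=AB, 2=BB
>>> post = np.array([[1,0,0]]*5 + [[0,1,0]]*3 + [[0,0,1]]*2, float)
>>> s = iqs(build_contingency(truth, post))
>>> round(s.po, 2), round(s.pc, 2), s.iqs
(0.9, 0.36, 0.84375)
```

Nine of ten genotypes are correct (Po = 0.9), but margins alone would agree
36% of the time (Pc = 0.36), so the chance-corrected quality is 0.84375.

The end-to-end experiment (`python examples/03_full_scenario.py`) builds the
reference synthetic scenario — 4,000 SNPs on a 10 Mb chromosome, a
200-haplotype panel, 300 individuals, 40 hotspots — trains on 200 masked
old-platform SNPs and evaluates on 2,000 new-platform SNPs, printing:

```
IQS: test MSE = 0.0203  Pearson r = 0.766  (nu = 0.9)
 Po: test MSE = 0.0005  Pearson r = 0.987  (nu = 1.0)
 Pc: test MSE = 0.0006  Pearson r = 0.988  (nu = 0.8)
threshold 0.5: AUC(pred IQS) = 0.897, AUC(pred accuracy) = 0.852, AUC(true accuracy) = 0.874
```

Predicted IQS ranks poorly imputed SNPs (true IQS < 0.5) ahead of predicted
accuracy (Po), i.e. chance correction also helps when the quality itself is
only estimated.

Other examples: `01_iqs_from_posteriors.py` (the scoring arithmetic),
`02_train_quality_model.py` (feature table, ν selection, model
serialization), `04_file_pipeline.py` (file formats and the CLI path).

## Command line

```bash
iqspred simulate --preset reference --out fixture/
iqspred run-scenario --config fixture/scenario.yaml
iqspred iqs --truth truth.tsv --gprobs imputed.gprobs
iqspred features/train/predict/evaluate --help
```

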