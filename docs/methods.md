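# Methods

## The quality score

For one biallelic SNP imputed in N individuals, the 3×3 table `n[i, j]`
cross-classifies imputed genotype *i* against true genotype *j* (order AA,
AB, BB). In **soft** mode (the default) each individual contributes its full
posterior triple to the column of its true genotype, so cells are
fractional and every piece of the imputation output is used; in **hard**
mode each individual contributes 1 to its maximum-posterior genotype, with
ties resolved deterministically toward the lower genotype code (AA < AB <
BB). Individuals with missing truth are dropped, never imputed; `n..` is
the informative count. From the table, Po = trace/n.., Pc = Σ n_i·n_·i/n..²
and IQS = (Po − Pc)/(1 − Pc). When Pc = 1 within 1e−12 — a monomorphic
table — kappa is undefined; the score is reported as NaN rather than
silently 0, and such SNPs are excluded from training and evaluation
(upstream the reference-panel MAF ≥ 1% filter makes them rare). IQS is
never clipped: values below 0 mean worse-than-chance imputation and carry
information.

## The 12 features

Per imputed SNP, in frozen order: chromosome code (1–22, fed to the kernel
as a number — a deliberate modelling quirk kept for comparability), bp
position, platform-annotation MAF, mean B-allele frequency of an
ethnic-matched sample, reference-panel MAF, panel genotype-count ratios
AA/AB and BB/AB (additive pseudocount 1 on all three counts keeps them
finite without reordering), distance to the nearest typed SNP, distance to
the nearest recombination hotspot and that hotspot's rate (cM/Mb,
equidistant ties going to the lower position), mean per-individual maximum
posterior, and mean B-allele dosage 0·P(AA)+1·P(AB)+2·P(BB).

Two definitions were genuinely open. The B-allele frequency is derived from
array intensity data in the original setting; intensity processing is out
of scope here, so BAF is the mean b-count/2 over genotype calls of an
ethnic-matched sample (in the synthetic scenarios, reference-panel
haplotype pairs — never the test truth), and a pre-computed BAF column can
be supplied instead. The "mean posterior" feature does not name which
posterior; we use the per-individual maximum, the only single summary
monotone in call confidence. Coordinates are 1-based bp on a single build;
no liftover.

## The regression

ν-SVR with an RBF kernel, γ fixed at 1/d for d = 12. Features are min–max
scaled to [0, 1] on training data only (constant features map to 0);
without scaling, bp positions would dominate a shared-γ kernel. ν is chosen
from {0.1, …, 1.0} by 10-fold cross-validated MSE with a seeded fold
shuffle (default seed 42); ties go to the smaller ν; the scaler is refit
inside each fold. The penalty C is not part of the search protocol and
stays at the libsvm default 1.0, overridable in config. The quadratic
program is solved by scikit-learn's `NuSVR` (libsvm). Predictions are raw —
clipping to [0, 1] is a display decision, and kappa can be negative.
Targets: IQS directly, or Po and Pc separately; the combination
(Pô − Pĉ)/(1 − Pĉ) is also reported (NaN when Pĉ ≥ 1 − 1e−6).

Model files are JSON key–value containers holding the scaler bounds,
hyperparameters, support vectors, dual coefficients and intercept; a loaded
model predicts through an explicit RBF kernel expansion that matches the
in-memory solver to machine precision.

## Scenario evaluation

A scenario bundles imputed SNPs with truth, posteriors, typed positions,
annotation, panel genotype counts and a hotspot map; typed and imputed sets
must be disjoint. Before modelling, SNPs are filtered: reference-panel MAF
strictly below 1% is dropped (equality is kept); platform/panel allele
pairs are reconciled directly, then by strand complement; strand-ambiguous
A/T and C/G SNPs are resolved by allele-frequency proximity and dropped
when either frequency is within 0.1 of 0.5; undefined-IQS SNPs are removed.
All removals are logged per rule.

Training examples come from masking exactly round(10% · n) of the typed
SNPs (seeded, reproducible partition) and imputing them from the rest.
Metrics are MSE and Pearson r (Pearson, to match scatter-plot reading of
raw values; NaN if either vector is constant). For false-positive
filtering, a SNP with true IQS strictly below a threshold (0.5 or 0.9) is a
presumed false positive; ROC curves score SNPs by negated predicted quality
so low quality ranks first, and AUC equals the Mann–Whitney statistic with
ties averaged. "Imputation accuracy" as a comparator is identified with Po,
so the predicted-accuracy curve uses the Po-target model.

## The synthetic generator

The generator emulates the data a platform-upgrade study needs, at desk
scale. K = 20 founder haplotypes are drawn site-wise from Beta(0.5, 0.5)
allele frequencies truncated to MAF ≥ 1% (U-shaped spectrum, compatible
with the pipeline's filter). H = 200 panel haplotypes and every study
haplotype are founder/panel mosaics: a crossover fires in an inter-SNP
interval with probability 0.003, multiplied by 100 (capped at 0.5) in the
40 intervals containing a hotspot, whose rates follow Gamma(2, 10) cM/Mb.
Study individuals (N = 300) are sums of two panel mosaics. The old platform
covers a uniform random half of the M = 4,000 SNPs; training masks 10% of
it; the test set is the new-platform-only half.

The surrogate imputer replaces an HMM engine with a transparent
matching-mixture rule: panel haplotype pairs agreeing with an individual's
genotypes at the w = 4 nearest typed SNPs **per side** vote on the masked
genotype, and the vote is mixed with the panel Hardy–Weinberg distribution
with weight α = exp(−D/λ)·exp(−r/20), where D is the distance to the
nearest typed SNP, λ = 10 kb, and r is the largest hotspot rate lying
between the masked SNP and that typed SNP (no hotspot → no penalty). No
matching pair → Hardy–Weinberg alone. This reproduces the qualitative error
structure of model-based imputation — worse far from typed SNPs, at low
MAF, and across hotspots — which is exactly the signal the regression
features are built to capture. λ = 10 kb was set so that, at the reference
SNP density (≈2.5 kb spacing), distance to the nearest typed SNP retains a
clear monotone effect on quality (Spearman ρ ≈ −0.36 with true IQS) while
the true IQS distribution still spans both filtering thresholds
(62% below 0.5, ~2% above 0.9 at seed 7). Everything derives from one seed
via spawned substreams; the annotation MAF comes from an independent
100-individual mosaic cohort so no test-truth statistic leaks into the
features.

What the generator does **not** emulate: coalescent genealogy and
demography, genotyping error, multi-allelic and sex-chromosome sites,
strand-annotation errors (the allele-reconciliation filter is exercised
with hand-built cases instead), and the long-range haplotype sharing a real
HMM imputer exploits. Passing tests therefore demonstrate that the pipeline
recovers quality structure an imputer's error process induces, not that a
specific real cohort would reach the same numbers.

## Problem sizes and numerical choices

The reference scenario (M = 4,000, H = 200, N = 300, one 10 Mb chromosome)
builds in a few seconds and the full train/evaluate cycle adds a few more,
so examples, tests and the acceptance script all run it directly; unit
tests use a quarter-scale variant. Posterior triples are renormalized on
ingest when their sum is off by more than 1e−9 (hard error beyond 1e−3);
writers emit shortest-exact float representations so write→read→write is
token-identical. Fold assignment, masking and platform sampling use seeded
NumPy generators; reports serialize with sorted keys so identical seeds
give byte-identical JSON.

## Known limitations

Chromosome-as-number in an RBF kernel is a kept quirk, not a
recommendation. The combined Po/Pc route can blow up when predicted Pc
approaches 1 and is reported for comparison only. The ν-bound diagnostics
count margin errors from dual coefficients at the box bound, which is exact
for the solver but assumes the default shrinking heuristics converged. The
surrogate imputer's genotype-key matching saturates for very long flank
windows (key collisions vanish but in-window crossovers dominate), so its
accuracy ceiling is structural, not tunable to 1.
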