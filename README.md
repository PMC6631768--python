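# samfc — hybrid robust SAM-FC differential expression for paired samples

`samfc` identifies differentially expressed genes (DEGs) between two
biological conditions measured on **paired samples** (each subject
contributes one sample per condition), for bulk microarray/RNA expression
profiles on the log scale. It is aimed at the small-replicate regime
(n = 3–15 pairs) where a handful of outlying expressions can wreck both
fold-change and p-value based rankings.

## The method

For gene *g* with paired differences `d_gk = x_g1k − x_g2k`
(k = 1..n, modelled `N(μ_g, σ_g²)`), the pipeline computes:

1. **Classical estimates** `μ̂_g = mean(d_g)`, `σ̂_g = sd(d_g)`, and a
   **robust minimum β-divergence fit** `(μ̂_{g,β}, σ̂_{g,β})` via the
   weighted fixed point

   ```
   μ ← Σ w_k d_k / Σ w_k,    σ² ← (1+β) Σ w_k (d_k − μ)² / Σ w_k,
   w_k = exp(−β (d_k − μ)² / 2σ²)          (β = 0.2 by default)
   ```

   The β-weight `w_k ∈ (0, 1]` is ≈1 for typical observations and ≈0 for
   gross outliers, so the robust fit simply ignores them; β = 0 recovers
   the classical estimates.

2. **Outlier flagging.** Weights of all genes and replicates are pooled
   into the adaptive cutoff `δ = min(0.2, min w + 0.1·(max w − min w))`;
   a gene with any `w_k ≤ δ` is *outlying* and is scored with its robust
   estimates, all other genes with their classical ones (the unified
   estimates).

3. **β-SAM statistic** `u_{g,β} = μ̂_{g,β} / (σ̂_{g,β}/√n + s0)`, with the
   fudge factor `s0` chosen from percentiles of the scaled standard
   deviations so that the statistic's coefficient of variation across the
   genome is minimized, and the **β-FC** (the unified location).

4. **P-values** from a pooled sign-flip permutation null (exhaustive over
   all 2ⁿ patterns when feasible), BH-adjusted.

5. **Hybrid ranking:** genes are ranked by |β-FC| and |β-SAM| separately
   and ordered by the *average* of the two ranks, so a top gene must show
   both a biologically meaningful fold change and statistical evidence.
   The leading run of this ordering with p < 0.1 is selected.

The package also ships the simulation machinery (synthetic paired genomes
with known DEG labels and one-sided `x* = d + 2·max(...)` outlier
contamination), confusion-matrix/ROC/pAUC evaluation, and paired t-test and
Wilcoxon signed-rank baselines, so the method's operating characteristics
are reproducible without external data.

## Worked example

Simulate a contaminated genome (2,000 genes, 3% DEGs, n = 3 pairs, one
outlying expression per gene), run the pipeline, and score the result:

```
$ samfc simulate --config sim.yaml --seed 11 --out data
INFO samfc: wrote 2000 genes x 6 samples to data (60 DEGs, 2000 outlying entries)

$ samfc run --input data/matrix.tsv --seed 11 --out results.tsv
INFO samfc: delta=0.092 s0=0.5639 outlying=2000 selected=153 -> results.tsv

$ samfc evaluate --truth data/truth.tsv --results results.tsv
 tpr      tnr      fpr  fnr  fdr     for_  mer      auc     pauc  n_top
 0.5 0.984536 0.015464  0.5  0.5 0.015464 0.03 0.840597 0.127934     60
```

`delta` is the adaptive β-weight cutoff (here 0.092: every gene carries an
injected outlier, so the pool's smallest weights are ≈0), `s0` the fudge
factor, `outlying` the number of genes scored with robust estimates, and
`selected` the leading-run selection at p < 0.1. `evaluate` calls the top
N = 60 genes (the true DEG count): half of the true DEGs are recovered at
AUC 0.84 despite every gene being contaminated — the classical β = 0
pipeline on the same data recovers almost none (see the robustness test in
`tests/test_acceptance.py`).

The same pipeline is available as a scikit-learn estimator:

```python
from samfc import SAMFCDetector, SimulationConfig, generate

ds = generate(SimulationConfig(n_genes=2000, n=3, seed=11))
det = SAMFCDetector(beta=0.2, random_state=0).fit(ds.experiment.values.T)
det.results(ds.experiment.gene_ids)   # per-gene table
det.transform(ds.experiment.values.T) # expression restricted to selected genes
```

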