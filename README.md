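# ecprograms

Discovery and downstream analysis of endothelial gene expression
programs in tumor single-nucleus RNA-seq, for computational biologists
studying how therapy remodels the tumor vasculature.

Tumor endothelial cells (ECs) occupy a continuum of states — capillary,
arterial, venous, lymphatic, and reactive phenotypes such as
endothelial-to-mesenchymal transition — that shift under chemoradiation
and anti-fibrotic co-treatment. `ecprograms` implements the full
analysis chain for such studies:

* **Consensus NMF program discovery.** The expression matrix X
  (nuclei × genes, CP10K + log1p, high-variance genes, unit gene
  variance) is factorized as X ≈ WH with W, H ≥ 0; because a single NMF
  run depends on its random start, the factorization is repeated
  (default 50×), all replicate spectra are pooled, density-filtered,
  k-means clustered and summarized by component-wise medians. Stability
  (mean silhouette of the component clustering) and reconstruction
  error drive the choice of k.
* **Program annotation** by two-sided hypergeometric overlap of each
  program's top-200 weighted genes with reference signatures or GMT
  pathway sets, BH-corrected.
* **Mixed-effects Poisson differential expression**:
  log E[y] = β·group + covariates + b_patient + offset, b ~ N(0, σ²),
  fit by Laplace-approximated maximum likelihood with Wald inference
  and Bonferroni correction.
* **Patient-level association tests**: program proportions vs treatment
  arm / radiation dose / modality (Mann–Whitney U + BH at FDR 0.1),
  top- vs bottom-quartile microenvironment comparisons,
  stromal-to-EC ratios, and paired targeted-panel scoring (Wilcoxon
  signed-rank + Bonferroni).
* **Bulk cohort analysis**: marker-based cell-type deconvolution,
  summed top-200 program scores z-normalized within cohorts,
  multivariable Cox regression (Efron ties) of overall survival and
  time to progression, and nodal-status associations.
* **Synthetic data generators** with planted ground truth (program
  spectra and usages, treatment-dependent prevalence, proportional-
  hazards survival, paired panel effects) so every stage is testable
  without any external download.

## Worked example

```python
import ecprograms as ep

# simulate a cohort with known ground truth: 37 patients
# (18 untreated / 14 CRT / 5 CRTL), ~3,000 EC nuclei, 1,500 genes,
# 7 planted programs
cfg = ep.SimulationConfig(seed=0)
X, metadata, truth = ep.simulate_snrnaseq(cfg)

# normalize, factorize over a grid of k, select k
prep = ep.prepare_matrix(X, n_hvg=1500)
results = {
    k: ep.ConsensusNMF(k=k, n_replicates=20, random_state=0)
        .fit(prep.matrix).result_
    for k in range(4, 11)
}
best_k, diagnostics = ep.select_k(results)
print(diagnostics.round(3))
print("selected k:", best_k)
```

```
   k  stability  reconstruction_error  score
0  4      0.814              1874.336  0.464
1  5      0.925              1788.635  0.913
2  6      0.886              1721.081  0.756
3  7      0.947              1661.931  0.995
4  8      0.872              1661.457  0.699
5  9      0.792              1660.797  0.377
6 10      0.699              1660.626  0.000
selected k: 7
```

Stability peaks at the planted k = 7 while the reconstruction error
plateaus, so the combined score selects 7 — the number of programs the
simulator planted. The consensus spectra at k = 7 match the planted
programs at a mean Hungarian-matched cosine similarity of 0.97, and
per-nucleus argmax labels recover the planted program labels.

Downstream, with a fitted model `m = ep.ConsensusNMF(k=7, ...)`:

```python
import pandas as pd
ps = ep.ProgramSet.from_spectra(m.spectra_, prep.genes,
                                names=truth.program_names,
                                classes=truth.program_classes)
usage = pd.DataFrame(m.usage_, index=prep.barcodes, columns=ps.names)
assignments = ep.assign_nuclei(usage, ps)
table = ep.program_proportions(assignments, metadata)
print(ep.compare_strata(table, "arm").query("significant"))
```

flags the treatment-enriched reactive program (untreated vs CRT,
BH-adjusted p < 0.05) exactly where the simulator planted the
prevalence shift.

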