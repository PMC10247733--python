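# haplocycle

Cell-cycle-resolved dosage and essentiality analysis for near-haploid vs
diploidized leukemia cells.

Near-haploid leukemia cells (one copy of most autosomes) that spontaneously
diploidize offer a clean natural experiment in genome dosage: under a pure
whole-genome doubling, every gene's expression should follow a 2:1
diploid:haploid ratio (log2 ratio = 1), and deviations from that
expectation — especially deviations confined to particular cell-cycle
stages — point at dosage-sensitive biology such as DNA-damage repair in
G2/M. `haplocycle` implements the computational side of such a study as a
tested, reusable pipeline:

- **Cell-cycle phase inference** from single-cell expression: five metagene
  scores (G1S, S, G2, G2M, MG1) over dataset-filtered signature gene lists
  (detected in ≥ 5% of cells, Pearson *r* ≥ 0.5 with the signature mean);
  each cell is assigned the argmax phase.
- **Elliptical pseudo-time**: a direct least-squares ellipse fit to cells in
  the (G1S, G2M) score plane, and rolling-circle smoothing (radius 0.5 in
  score units) of expression along the manifold with 95% CI bands
  (mean ± 1.96 × SEM).
- **Graph-diffusion imputation** (Markov-affinity kNN graph, adaptive
  Gaussian kernel, *M*ᵗ·*X* with t = 3 by default) ahead of all
  correlation-based analyses, with de-scaled output that preserves
  absolute dosage structure.
- **Stage-specific dosage ratios and DE**: per-gene diploid/haploid log2
  ratios per stage, Wilcoxon rank-sum tests with Benjamini–Hochberg
  *q*-values, and a census of genes falling below a log2 cutoff of 0.5
  (~1.4-fold) per stage; ERCC top-5 spike-in normalization for bulk tables.
- **Co-expression signatures**: anchor-gene signatures (members with
  *r* ≥ 0.5 to the anchor), per-cell scores, hypergeometric overlap tests.
- **Screen essentiality calls**: guide-level log2 fold changes, a
  control-calibrated median-guide depletion rule, and the deterministic
  intersection that nominates ploidy-specific essential genes.
- **DNA-damage foci**: DAPI-based cell-cycle binning, diploid:haploid
  foci-count ratios tested against the dosage expectation (one-sample
  Student's t), and two γ-H2AX/RAD51 co-localization occupancy metrics.
- **Growth kinetics**: doubling times, stage-duration allocation from phase
  proportions, competition-assay fitness per doubling.
- **Synthetic data generators** for every input, with planted ground truth
  (dosage factor, dwell fractions, cyclic programs, essential genes,
  co-localization fraction) so each stage is testable end to end without
  any external download.

## Worked example

```python
from haplocycle import (SimConfig, simulate_cells, impute_counts,
                        drop_constant_genes, filter_signature, score_phases,
                        phase_proportions, stage_ratio_table, cutoff_census,
                        DEParams)
from haplocycle.pipeline import global_dosage_ratio

cfg = SimConfig(seed=1, n_cells_per_group=1000, n_genes=1000)
adata, truth = simulate_cells(cfg)
print(f"global diploid:haploid expression ratio = {global_dosage_ratio(adata):.3f}")

adata = drop_constant_genes(impute_counts(adata))
signatures = [filter_signature(adata, s) for s in truth.phase_gene_sets()]
scores = score_phases(adata, signatures)
acc = (scores["phase"] == adata.obs["true_phase"]).mean()
print(f"phase assignment accuracy vs ground truth = {acc:.3f}")
print(phase_proportions(scores, adata.obs["group"]).round(3))

table = stage_ratio_table(adata, scores["phase"], min_cells=10)
census, ecdf, linear = cutoff_census(table, DEParams())
print(f"log2 cutoff 0.5 = {linear:.2f}-fold in linear space")
```

prints

```
global diploid:haploid expression ratio = 2.003
phase assignment accuracy vs ground truth = 0.939
           G1S      S     G2    G2M    MG1  unassigned  n_cells
group
haploid  0.241  0.183  0.188  0.232  0.156         0.0   1000.0
diploid  0.297  0.249  0.147  0.139  0.168         0.0   1000.0
log2 cutoff 0.5 = 1.41-fold in linear space
```

The simulated diploid cells carry twice the haploid transcript content
(ratio 2.003 vs the generating factor 2.0); phase assignment recovers 94%
of the generating phase labels; the recovered per-group phase occupancies
show the haploid excess in G2/G2M that the generator plants; and the
dosage-deviation census reports its cutoff on both log2 and linear scales.

A command-line interface mirrors the library
(`haplocycle simulate|impute|cycle-score|pseudotime|dosage|signature|screen|foci|kinetics|run-all`);
`haplocycle run-all --out report/` runs every stage on synthetic data and
writes all tables into a report directory.

## Layout

- `src/haplocycle/` — library modules (`synthetic`, `io`, `imputation`,
  `cycle`, `pseudotime`, `dosage`, `signatures`, `screen`, `foci`,
  `kinetics`, `pipeline`, `cli`).
- `docs/methods.md` — the model, parameter choices and limitations.
- `tests/` — unit, property and end-to-end acceptance tests (oracle
  equivalence against brute-force reimplementations throughout).
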