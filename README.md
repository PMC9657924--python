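# tmm-scell

Single-cell typing of **telomere maintenance mechanisms (TMMs)**. Tumor
cells achieve replicative immortality either through telomerase (TEL, ~85%
of tumors) or through the recombination-based alternative lengthening of
telomeres (ALT); at the transcriptome level a cell can show evidence for
one, both, or — notably — neither mechanism. Cells of that last class,
**non-defined TMM (NDTMM)**, are of particular interest in gastric cancer,
where they mark an aggressive, poor-prognosis phenotype. `tmm-scell` assigns
each cell in an scRNA-seq count matrix one of four labels — `TEL`,
`ALT-like`, `TEL+ALT-like`, `NDTMM` — and characterizes the resulting
groups.

The package is aimed at computational biologists who have a 10x-style count
matrix (MTX + gene/cell sidecars), TEL- and ALT-tagged signature gene sets
(GMT + group map), and want reproducible per-cell TMM calls with calibrated
false-discovery control. Because the published cohorts and signature lists
are not redistributable, a synthetic-cohort generator with planted
ground-truth TMM states is a first-class part of the package; every claim
the test suite makes is checked against it.

## Method

1. **QC & normalization** — cells are kept with ≥ 200 detected genes and a
   mitochondrial count percentage below 5% (both configurable, including
   the inverted mito rule); counts are library-size normalized,
   `x → ln(1 + 10⁴·x/total)`.
2. **Markov diffusion imputation** (MAGIC-style) — distances in the top
   principal components define an adaptive Gaussian kernel
   `A_ij = exp(−(d_ij/σ_i)²)` (σ_i = distance to the ka-th neighbor,
   truncated past the k-th), symmetrized and row-normalized to a Markov
   operator `M`; the matrix is denoised as `Mᵗ·X`.
3. **Per-cell ssGSEA** — for each cell, genes are ranked and a gene set G
   scored with the weighted running-sum enrichment statistic
   `ES = Σ_i [P_in(i) − P_out(i)]`, where `P_in` accumulates `rank^α`
   weights over set members and `P_out` the out-of-set ECDF. The package
   evaluates this in closed form,
   `ES = Σ_G r^{α+1} / Σ_G r^α − (T − Σ_G r)/(N−|G|)`.
4. **Permutation significance** — each TMM pathway is tested per cell
   against the null of random same-size gene sets scored in the same cell.
   To make that null calibrated under gene-specific baseline abundances,
   the statistic is computed on *exchangeable ranks*: each gene is first
   rank-transformed across cells (seeded random tie-break), then ranked
   within the cell. Empirical p-values use the add-one rule
   `p = (1 + #{ES_null ≥ ES_obs})/(n_perm + 1)`.
5. **Group decision** — evidence from the TEL-group and ALT-group pathways
   is pooled per cell (Fisher's method by default), Benjamini–Hochberg
   corrected across cells, and thresholded at FDR < 0.01:
   TEL-significant only → `TEL`; ALT only → `ALT-like`; both →
   `TEL+ALT-like`; neither → `NDTMM`.
6. **Characterization** — per-cell-type TMM frequencies, transcriptome
   entropy (`H = −Σ p ln p`, the stemness proxy) by PCA/k-means cluster,
   marker summaries (e.g. MKI67, PML) with rank-sum tests, and two-group
   differential expression under a zero-inflated negative binomial
   (`P(x=0) = π + (1−π)·NB(0; μ, θ)`) with likelihood-ratio tests that
   separate zero-fraction ("status", DEs), abundance (DEa) and general
   (DEg) differences.

## Worked example

```python
import numpy as np
import tmm_scell as t

cfg = t.SimConfig(n_cells=600, n_genes=2000, signature_lfc=1.5, seed=3)
sets = t.demo_tmm_collection(cfg.n_genes)          # 3 TEL + 3 ALT demo pathways
counts, truth = t.simulate_cohort(cfg, sets)

qc = t.compute_qc(counts, [g for g in counts.gene_ids if g.startswith("MT-")])
kept = t.filter_cells(qc)
print(f"{len(kept)} / {counts.n_cells} cells pass QC")
counts = counts.subset_cells(kept)
truth = truth[truth.cell_id.isin(kept)]

imputed = t.impute(t.lognormalize(counts), t.DiffusionParams(seed=4))
calls, qvals = t.call_tmm_types(imputed, counts.gene_ids, counts.cell_ids,
                                sets, t.PermutationParams(n_perm=1000, seed=5))

freq = t.tmm_frequency(calls, truth[["cell_id", "cell_type"]])
print(freq[freq.cell_type == "type0"].to_string(index=False))
```

Output:

```
249 / 600 cells pass QC
cell_type     tmm_type  count   percent
    type0          TEL     21 30.882353
    type0     ALT-like     20 29.411765
    type0 TEL+ALT-like     11 16.176471
    type0        NDTMM     16 23.529412
```

Roughly half the simulated cells fail QC because the generator plants
mitochondrial fractions spanning the 5% threshold. Within each cell type
the four TMM labels appear at close to the 25% each that was planted;
comparing `calls.label` to `truth.tmm_type` on this run gives a
macro-averaged recovery accuracy of 0.895 (1000-cell cohorts, as used by
the acceptance checks, land at ~0.92–0.93).

A YAML-driven end-to-end run (including entropy/cluster and marker tables
plus a manifest with checksums) is available from the command line:

```bash
tmm-scell run --config config.yaml
tmm-scell simulate --out sim/ --n-cells 500 --seed 1
tmm-scell qc --matrix sim/matrix.mtx --genes sim/genes.tsv --cells sim/cells.tsv --out qc.tsv
```

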