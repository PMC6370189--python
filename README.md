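# trmsig

Does in vitro TGF-β stimulation imprint the tissue-resident memory (TRM)
CD8⁺ T-cell transcriptional signature?  `trmsig` implements the complete
downstream analysis for a bulk RNA-seq study designed around that question:
activated CD8⁺ T cells profiled under four conditions (Untreated, TGF-β,
IL-2, IL-2/TGF-β) with three biological replicates each, quantified as a
genes × samples FPKM matrix.

The package is aimed at computational immunologists who want the analysis
to be reproducible end-to-end: every stage runs on synthetic data with
planted ground truth, so each statistical claim the pipeline makes is
backed by a recovery or calibration test.

## What it computes

1. **Preprocessing** — filter lowly expressed genes (mean FPKM > 0.3),
   log₂(FPKM + 1) transform, per-gene z-scoring; PCA over samples and
   Ward hierarchical clustering on the Chebyshev ("maximum") distance
   between sample profiles.
2. **Differential expression** — a moderated two-sample t-test on log₂
   FPKM.  With pooled per-gene variance s²_g (d = n_A + n_B − 2 df) the
   shrunken variance is s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d) with prior
   d₀ = 4 and s₀² = median over genes of s²_g; the statistic
   t = (μ_A − μ_B)/(s̃_g·√(1/n_A + 1/n_B)) is referred to Student t with
   d₀ + d df.  Benjamini–Hochberg FDR < 0.05 defines the DE set; counts
   are tiered at |log₂FC| > 1 and > 2, and the three TGF-β contrasts are
   intersected into common up/down gene lists.
3. **Directional signature overlap** — the count o of signature genes DE
   *in the annotated direction* (a 35-gene TRM signature by default), with
   significance from a bootstrap null: in each of B = 10,000 rounds, k and
   m gene labels are drawn with replacement from the expressed-gene
   universe, deduplicated, and intersected;
   P = (1 + #{o_b ≥ o}) / (B + 1).
4. **Gene set enrichment analysis** — implemented from scratch:
   Signal2Noise ranking r_g = (μ_A − μ_B)/(σ_A + σ_B) with the standard
   σ floors, weighted running-sum enrichment score (weight p = 1), a
   permutation null (phenotype-label splits, exhaustively enumerated for
   small designs, or matched-size random gene sets), NES, nominal P and a
   pooled-NES FDR q; significance at nominal P < 0.05 and q < 0.25 with a
   minimum gene set size of 15.
5. **Synthetic data** — a generator emulating the 12-sample design:
   additive log₂-space signal with sparse TGF-β effects biased toward
   up-regulation, independent IL-2 effects, exponential effect sizes with
   a 0.5-log₂ floor, a directional signature with a controlled concordance
   fraction, and 10 planted direction-consistent gene sets plus negative
   controls — all recorded in a machine-readable truth object.

## Worked example

```python
import trmsig as t

config = t.SimulationConfig(seed=0)           # 11,000 genes, 4 x 3 samples
matrix, design, signature, sets, truth = t.simulate_study(config)

expressed = t.filter_low_expression(matrix, cutoff=0.3)
logged = t.log2_transform(expressed)
print(f"expressed genes: {expressed.shape[0]} / {matrix.shape[0]}")

de = t.differential_expression(logged, design, t.study_comparisons()[0])
print(t.tier_counts(de).to_string(index=False))

obs = t.directional_overlap(signature, de)
boot = t.bootstrap_enrichment(obs, bootstraps=10_000, seed=1)
print(f"signature overlap: {boot.o_obs}/{boot.k} "
      f"({boot.percentage:.0f}%), m={boot.m}, P={boot.pvalue:.2g}")

gsea = t.run_gsea(logged, design, sets, ("TGFb", "IL2_TGFb"),
                  ("Untreated", "IL2"), n_perm=1000, seed=2)
print(gsea.table[["es", "nes", "pvalue", "fdr_q", "significant"]].round(3))
```

prints

```
expressed genes: 10614 / 11000
       comparison  min_abs_log2fc  total  up  down
TGFb_vs_Untreated             0.0    565 345   220
TGFb_vs_Untreated             1.0    554 342   212
TGFb_vs_Untreated             2.0    300 195   105
signature overlap: 16/35 (46%), m=565, P=0.0001
                   es    nes  pvalue  fdr_q  significant
gene_set
planted_up_1    0.931  2.468   0.002  0.000         True
...
planted_down_5 -0.941 -2.438   0.002  0.000         True
control_1       0.212  0.559   0.988  0.982        False
control_2       0.265  0.699   0.885  0.982        False
```

Reading the output: 10,614 of 11,000 simulated genes pass the abundance
filter; the TGF-β vs Untreated contrast calls 565 DE genes at FDR < 0.05
(345 up, 220 down — the planted up-bias shows through); 16 of the 35
signature genes are DE in their annotated direction (46%, power-limited
recovery of the planted 60% concordance) and that overlap is far beyond
what random gene lists produce (P at the 1/(B+1) floor); all ten planted
tissue-specific sets are significantly enriched in the correct direction
while both negative-control sets are not.

The same analysis runs from the shell:

```
trmsig run-all --simulate --seed 0 --out results/run
```

which writes every table plus a JSON run report (schema in
`schemas/run_report.schema.json`).

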