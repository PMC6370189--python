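# Methods

## The analysis in one paragraph

The pipeline asks whether TGF-β stimulation reproduces, in vitro, the
transcriptional program of tissue-resident memory (TRM) CD8⁺ T cells.  It
consumes a genes × samples FPKM matrix from a four-condition design
(Untreated, TGF-β, IL-2, IL-2/TGF-β; three biological replicates each),
identifies genes differentially expressed in the TGF-β-exposed conditions,
measures the directional overlap of those DE genes with a reference TRM
signature against a bootstrap null, and tests tissue-specific TRM gene
sets for enrichment along the TGF-β-response axis with a gene set
enrichment analysis.  Because the original raw data are not redistributed,
the package ships a synthetic-data generator whose planted ground truth
defines what every stage is expected to recover.

## Synthetic data model

Per gene g and sample s in condition c:

    signal_gs = b_g + δ_g·[TGF-β ∈ c] + γ_g·[IL-2 ∈ c] + ε_gs
    FPKM_gs   = max(2^signal_gs − 1, 0)

with baseline b_g ~ N(3.0, 1.5²) (log₂-FPKM units), replicate noise
ε ~ N(0, 0.35²), and sparse effects: 8% of genes respond to TGF-β (60% of
them up-regulated, matching the observed up-bias of TGF-β stimulation) and
an independent 8% respond to IL-2 (symmetric).  Effect magnitudes are
|δ| ~ 0.5 + Exponential(mean 1.5) log₂ units; the 0.5 floor keeps
"responsive" separated from replicate noise at n = 3, so recovery tests
are stable.  Noise is log-normal at the replicate level rather than a
count-level negative binomial because the pipeline consumes FPKM, never
raw fragment counts; consequently the generator does not emulate
count-based mean–variance coupling, length bias or estimation uncertainty
in FPKM itself.

The 35-gene directional signature contains round(0.6·35) = 21 concordant
members (responsive genes whose planted sign matches their annotation,
allocated 18 up / 3 down in proportion to the 30-up/5-down annotation
split) and 14 discordant members drawn from non-responsive genes.  Ten
planted gene sets of 50 genes (five from planted-up, five from
planted-down genes) and two negative-control sets from non-responsive
genes complete the collection; controls may carry IL-2 effects, which
cancel in the treated-vs-untreated contrast because IL-2 is balanced
across its arms.

What passing tests on these data do *not* show: real tissue biology has
correlated co-expression structure, batch effects and heavy-tailed noise
that the generator deliberately omits.  In particular the study's
observation that the first three principal components carry >80% of the
variance reflects real correlated structure; on the independence-based
synthetic data the top three components carry ~35%, and the package makes
no claim to reproduce published PCA coordinates.

## Preprocessing

Genes are kept when their **mean FPKM across all samples** exceeds 0.3
(an "every sample above cutoff" mode is available); then log₂(FPKM + 1)
(pseudocount 1 keeps zeros at zero); then per-gene z-scoring (ddof = 1,
zero-variance rows set to zero and flagged).  The orchestrator applies
exactly this order — the steps do not commute.

PCA is computed over samples from the SVD of the column-centred
samples × genes matrix of z-scores (zero-variance genes excluded);
variance fractions equal the normalised eigenvalues of the sample
covariance, and a test asserts that equivalence to 1e−6.

Hierarchical clustering uses Ward linkage on a precomputed Chebyshev
("maximum") dissimilarity matrix between sample profiles.  Ward on a
non-Euclidean dissimilarity is a recognised heuristic; merge heights can
be non-monotone in rare cases, and monotonicity is asserted only for
Euclidean input.  The pipeline clusters on the **log₂** matrix, not the
z-scored one: z-scoring caps every gene's between-sample range, so the
maximum-difference metric is then dominated by whichever noise gene
happens to be most extreme and carries no treatment information; on log₂
values the largest planted effects dominate the metric and the
dendrogram's 2-cut separates TGF-β-exposed from unexposed samples.
Because the generator plants IL-2 effects of the same magnitude
distribution as TGF-β effects, the Chebyshev 2-cut can split on IL-2
instead in some random realisations; under the default seed it splits on
TGF-β with purity 1.0.

## Differential expression

FPKM-only input rules out count-model tests, so the package uses a fully
specified moderated two-sample t on log₂(FPKM + 1): pooled variance s²_g
with d = n_A + n_B − 2 df, shrunken toward s₀² = median_g(s²_g) with prior
weight d₀ = 4, statistic referred to t with d₀ + d df.  At the study's
n = 3 per arm this is calibrated (type-I error 0.044 at nominal 0.05 on a
2000-gene null simulation) and has >0.9 power for 4-fold effects.  BH
adjustment is delegated to statsmodels and verified against an exhaustive
step-up oracle.  Directions: up/down require FDR < 0.05 and a nonzero
log₂FC; a gene at exactly log₂FC = 0 is never directional.  Swapping
treated and reference negates every log₂FC and leaves P unchanged.

The four pairwise contrasts are TGF-β vs Untreated, IL-2/TGF-β vs
Untreated, IL-2/TGF-β vs IL-2 (these three feed the signature stage) and
IL-2/TGF-β vs TGF-β (tier table only, isolating the IL-2 effect).

## Directional overlap and its bootstrap null

o_obs counts signature genes significantly DE in their annotated
direction; each signature gene is reported as concordant, discordant,
not-DE or not-measured.  The null redraws both lists: k and m labels with
replacement from the universe, each draw reduced to its unique members
before intersecting (multiset intersection is ill-defined for gene lists;
for k, m ≪ N duplicates are rare and the null matches the hypergeometric
upper tail, which a test verifies across a (k, m, N, o) grid within
Monte-Carlo error).  P = (1 + #{o_b ≥ o_obs})/(B + 1) — the add-one term
keeps P strictly positive with a floor of 1/(B + 1) ≈ 1e−4 at B = 10,000,
consistent with reporting "P < 0.001".

The null is direction-blind while o_obs is direction-constrained, which
makes P conservative; a direction-aware option lets null draws inherit
up/down marks (Bernoulli with the observed up-fractions) so only
same-direction collisions count.  The default universe is the
expressed-gene set after filtering (~10,900 genes); the full annotated
universe (~24,000-gene analogue) is selectable, and the choice is
recorded in the run report.

Calibration of the rejection rate is tested under a wide null
(k = m = 1000, N = 2000, B = 199): the overlap statistic is integer-valued
and P lives on a lattice, so with narrow nulls rejection at α is
substantially conservative; the wide-null design makes the lattice fine
enough that the empirical rate (0.049) is informative.

## GSEA

Signal2Noise r_g = (μ_A − μ_B)/(σ_A + σ_B) with each σ floored at
max(0.2·|μ|, 0.2); genes ranked descending with a lexicographic gene-id
tie-break for cross-platform determinism.  The metric is computed on log₂
values by default: per-gene z-scoring forces every gene's total variance
to the same value across all 12 samples, which distorts the
between-group/within-group decomposition Signal2Noise relies on;
standardised input remains supported.

The enrichment score is the signed extremum of P_hit − P_miss, where
P_hit accumulates |r_g|^p (p = 1, the standard weighted scheme) over set
members and P_miss accumulates uniformly over non-members
(denominator N − N_h).  ES values are verified to 1e−12 against an
independently coded exhaustive running sum and cross-checked against
gseapy's prerank ES.  Null ES values are computed at hit boundaries only
(the running sum is linear between hits), which reproduces the full
profile's extremum exactly and makes 1,000 permutations on an
11,000-gene list run in well under a minute.

Permutation null: a 3v3 phenotype design admits only C(6,3)/2 = 10
distinct label splits and the 6v6 treated-vs-untreated contrast 462 —
nowhere near the 100,000 permutations a desktop GSEA run would use — so
distinct splits are enumerated exhaustively when few, and the default
P/q estimation uses the gene-set mode (random member sets of matched
size, one shared null pool per size).  Phenotype mode is retained for
fidelity but is under-powered at this design size (its P floor is
1/11 resp. 1/463).

Nominal P is the add-one tail frequency among same-sign null ES;
NES = ES / mean(|same-sign null ES|); FDR q compares the pooled null-NES
tail fraction with the observed-NES tail fraction at each set's NES,
caps at 1, and is monotonised over thresholds so a stronger NES never
has a larger q.  Sets whose same-sign null is empty are flagged rather
than dropped.  Significance requires nominal P < 0.05 **and** q < 0.25;
sets with fewer than 15 members in the ranked universe are excluded with
a recorded reason.

## Numerical and degenerate-input conventions

- Genes with zero variance on both sides and zero difference: P = 1 by
  convention (zero variance with a nonzero difference: P = 0).
- All member metrics zero in a gene set: ES = 0 with a warning.
- A gene set equal to the whole universe: error (P_miss undefined).
- First-occurrence tie-break at equal |running-sum| extrema (ties break
  the reversal antisymmetry of ES; the magnitude is still invariant).
- Signature genes missing from the tested universe: reported as
  not-measured with a warning, never fatal.
- Every resampling routine requires an explicit seed; the pipeline fans
  all stage seeds out of one root seed via deterministic seed sequences.

## Problem sizes used by the test suite

The shipped tests run the full 11,000-gene, 12-sample study for the
end-to-end checks (GSEA with 1,000 gene-set permutations, bootstrap
B = 10,000) and smaller simulations (800–2,000 genes, B ≈ 200–4,000,
400 permutations) for calibration sweeps; these sizes make the whole
suite complete in well under a minute while leaving every statistical
band meaningful.

## Known limitations

- Estimated log₂FC on log₂(FPKM + 1) is attenuated for genes whose FPKM
  is near zero (the pseudocount compresses their scale, and clipping at
  FPKM = 0 truncates negative excursions).  Parameter-recovery checks
  therefore evaluate the correlation with planted effects over the
  responsive genes (0.95–0.97 at default noise); pooled over all genes,
  dilution by ~10,000 null genes reduces it to ~0.89.
- At n = 3 per arm the DE stage misses planted effects near the 0.5-log₂
  floor, so the observed signature concordance (~46–49%) underestimates
  the planted 60% — an expected power effect, not a defect; it mirrors
  the lower end of the 46–60% range such analyses report.
- The bootstrap and GSEA stages inherit whatever biases the DE list
  carries; they test enrichment, not causality.
- The generator's independence assumptions make its null sharper than
  real transcriptomes; calibration results on synthetic nulls are a
  necessary, not sufficient, condition for calibration on real data.
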