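# Methods

This document specifies the statistical methods implemented by `pathgwas`,
in pipeline order. Notation: the cohort has `n` samples and `m` biallelic
SNPs; genotypes are counts of the A1 (minor) allele in `{0, 1, 2}` with a
distinct missing code; the phenotype is case/control.

## Genotype I/O

Genotypes are read and written in the PLINK v1 binary format (BED/BIM/FAM)
in SNP-major orientation. Each byte packs four samples, two bits per
genotype, with the first sample of the group in the two *low-order* bits;
the bit pairs decode as `00` → two A1 copies, `10` → one copy, `11` → zero
copies, `01` → missing. The reader validates the three-byte magic/mode
header and the exact payload length, and rejects sample-major files.

Gene sets are flat lists of Entrez gene IDs exchanged in GMT format (set
name, description, then gene IDs, tab-separated). Sets with fewer than 10
genes are removed before analysis. Gene coordinates are 1-based inclusive
on string-labelled chromosomes.

## Quality control

The cascade applies these filters in a fixed order, recording a reason code
for every removal:

1. **Sample call rate** ≥ 0.98.
2. **Inbreeding coefficient** |F| ≤ 0.2, from the observed versus expected
   heterozygote counts under Hardy–Weinberg proportions.
3. **Marker call rate** ≥ 0.98, within each genotyping batch.
4. **Differential missingness** between cases and controls ≤ 0.02
   (rate difference; the chi-square p-value is reported alongside).
5. **Hardy–Weinberg equilibrium** exact test: markers removed at
   p ≤ 1e-6 in controls or p ≤ 1e-10 in cases, per batch.
6. **Batch-effect scan**: allele-frequency chi-square between every pair of
   control batches; markers with any pairwise p ≤ 1e-6 are removed.
7. **PCA ancestry outliers**: samples beyond 6 standard deviations on any
   of the top 10 principal components, recomputed iteratively (up to 5
   rounds) until no outlier remains.
8. **Relatedness**: pairs with PI_HAT > 0.1875 are resolved by removing the
   member with the lower call rate (exact ties: the lexicographically
   larger sample ID). PI_HAT is the method-of-moments IBD estimate
   `P(IBD=2) + P(IBD=1)/2` from identity-by-state sharing counts and
   allele frequencies, computed on an LD-pruned marker subset
   (greedy r² < 0.2 in 50-SNP windows).

The HWE exact test enumerates the conditional distribution of the
heterozygote count given the minor-allele count: the unnormalized weight of
`h` heterozygotes among `n` genotypes with `n_m` minor alleles is
`2^h · C(n, h) · C(n−h, (n_m−h)/2)`, and the p-value is the total
probability of outcomes no more likely than the observed one. Log-gamma
arithmetic keeps the computation stable for large `n`; the test suite
verifies it against exact rational enumeration for every table with
`n ≤ 50`.

## Population structure

Principal components are computed on the Patterson-normalized matrix:
marker `j` is centered at `2 p̂_j` and scaled by `sqrt(2 p̃_j (1 − p̃_j))`
with `p̃_j = (count_j + 0.5) / (2 n_j + 1)`; missing calls are mean-imputed
and monomorphic markers dropped. The number of statistically meaningful
components is chosen with the Tracy–Widom test: for each leading
eigenvalue, an effective marker count is re-estimated from the moments of
the remaining spectrum, the normalized eigenvalue is centered and scaled
with the Tracy–Widom constants, and components are counted until the first
statistic falls below the critical value (0.9793 at α = 0.05). The leading
PCs (5 by default) enter association models as covariates.

## Single-marker association

Each SNP is tested in an additive logistic model
`logit P(case) = β₀ + β_g·g + Γ'C` fitted by iteratively reweighted least
squares; the Wald z-test of `β_g` gives the reported p-value and odds
ratio `exp(β_g)`. Case/control minor-allele frequencies `F_A`/`F_U` and the
raw allelic odds ratio `(F_A/(1−F_A)) / (F_U/(1−F_U))` accompany each row.
Degenerate fits (monomorphic genotype, separation, collinearity) are
flagged with p = 1 rather than raised.

Inside permutation loops the package instead uses the 1-df efficient-score
test against the covariate-only null: with null fitted probabilities `μ`
and weights `w = μ(1−μ)`, the statistic is `U²/V` with `U = g'(y−μ)` and
`V = g'Wg − g'WX (X'WX)⁻¹ X'Wg`. The null model is fitted once per
phenotype vector, so the per-SNP cost is a dot product. Without covariates
this statistic is algebraically the Cochran–Armitage trend test. Observed
and permuted statistics use the same computation, preserving
exchangeability.

## Self-contained set-based association (SBA)

SNPs are assigned to genes by position within ±10 kb of the gene body, and
each gene set's SNPs are pooled (union, deduplicated). For one phenotype
assignment the set statistic is built as follows:

1. Compute per-SNP score-test p-values.
2. Candidates are set SNPs with p < 0.05 (their count is reported as
   NSIG).
3. Greedily accept candidates in order of increasing p (ties broken by
   ascending position then rsid), skipping any SNP whose squared Pearson
   genotype correlation with an already-accepted SNP is ≥ 0.5, stopping
   after 5 accepted SNPs (the accepted count is ISIG).
4. The set statistic is the mean p-value of the accepted SNPs; if no SNP
   passes the threshold the statistic is the sentinel value 1.

Case/control labels are then permuted R times (10,000 by default) —
covariates stay attached to their samples and the score test is refit per
permutation — and the empirical p-value is

    EMP1 = (1 + #{r : T_r ≤ T_obs}) / (R + 1).

A max(T)-style family-wise empirical p (EMP2) compares `T_obs` to the best
(smallest) statistic across all sets in each permutation. The Bonferroni
family-wise threshold for 45 sets is 0.05/45 ≈ 1.1e-3; reaching it
requires R ≥ 1000 or the test warns. An exhaustive mode enumerates all
`C(n, n_cases)` assignments instead of sampling and then reports
`EMP1 = #{assignments with T ≤ T_obs} / #assignments`, which includes the
observed assignment itself.

Because permutations are label-exchangeable and the observed statistic is
computed identically, `P(EMP1 ≤ α) = floor(α(R+1))/(R+1)` exactly under
the null, for every α — the add-one correction makes EMP1 valid, not
merely approximate. The distribution of EMP1 has an atom at 1 (the event
that no set SNP reaches p < 0.05); calibration checks therefore use the
randomized-rank transform `U = (#{T_r < T_obs} + V·(1 + #{T_r = T_obs}))
/ (R+1)` with `V ~ U(0,1)`, which is exactly uniform under
exchangeability, while type-I error is assessed on EMP1 directly.

`leave_out_retest` re-runs the test for one set after removing named genes
and/or SNPs from it, with the same permutation seed, to attribute a set
signal to specific members.

## Competitive gene-set analysis

Per-gene statistics are the mean of the member SNPs' score chi-squares.
The null of the mean is moment-matched to a scaled chi-square with mean 1
and variance `(2k + 4 Σ_{i<j} r²_ij) / k²`, where `r` is the Pearson
genotype correlation between the gene's `k` SNPs — for a single-SNP gene
this reduces the gene p to the SNP p exactly; for `k` SNPs in perfect LD
it collapses to a single SNP; for independent SNPs the variance is `2/k`.
Gene p-values are probit-transformed to z-scores and regressed on set
membership with gene-level covariates (log SNP count, log gene length,
mean pairwise r²); the one-sided t-test of a positive membership
coefficient is the competitive enrichment p. Family-wise correction
permutes gene labels — the competitive null is exchangeability of genes —
with an adaptive early stop once every set has accumulated enough
exceedances; corrected p-values compare each set's nominal p to the
permutation distribution of the minimum nominal p across sets.

## Synthetic cohorts

The generator emulates a structured case-control cohort with known truth:

* **Allele frequencies** follow the Balding–Nichols model: ancestral
  frequencies are drawn uniformly, and each subpopulation's frequency is
  Beta-distributed around the ancestral value with the requested F_ST.
* **LD** arises from founder-haplotype mosaics: each subpopulation carries
  a pool of founder haplotypes per block (50 SNPs by default), and sample
  haplotypes are switch-process mosaics of founders, giving block-local
  correlation that decays with distance and (near-)independence across
  blocks. The founder pool also induces genuine background kinship.
* **Gene landscape**: genes tile the blocks (12 per block by default, 480
  genes), and 45 gene sets partition the gene universe.
* **Causal effects**: a designated set receives a chosen number of causal
  SNPs (inside member-gene bodies) with a chosen odds ratio; phenotypes
  are drawn from the liability-free logistic model and sampled to exact
  case/control counts. With no causal sets the labels are independent of
  the genotypes.
* **Artifacts** can be implanted afterwards: duplicated samples,
  parent-child pairs, extra sample/marker missingness, HWE violations, and
  batch-associated frequency shifts — each recorded in the truth object so
  QC recovery can be scored.
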