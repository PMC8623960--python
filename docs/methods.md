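# Methods

## Scope and shape

The package reimplements, at desk scale, an excess-heritability analysis:
expected (model-based) relative heritability per variant from a reference
panel, set-level sums with a size-matched permutation null, and two
downstream screens (pathway over-representation, hub genes). Only
*relative, expected* heritability is computed — nothing is estimated from
phenotypes or GWAS summary statistics, and the absolute scale of any
published estimate is not reproduced; every statistic of interest is a
ratio and is provably invariant to the normalization constant (asserted
numerically in the tests).

## Heritability models

Expected contribution: E[h²_j] ∝ [f_j(1−f_j)]^(1+α) · ϖ_j · r_j.

- **α** (default −0.25, the common software default): −1 makes
  heritability MAF-independent; both values are runnable and tested.
- **LDAK weights ϖ**: the qualitative contract is that low-LD variants
  get higher weight. We solve, per connected component of the windowed
  r² graph, the non-negative least-squares system Σ_k ϖ_k r²_jk ≈ 1 and
  select the minimal-norm solution by augmenting the system with a ridge
  term λ = 1e−7 (bias ≪ the 1e−4 oracle tolerance). The minimal-norm
  choice is what makes degenerate systems well-defined: a clique of c
  perfect duplicates receives ϖ = 1/c each rather than an arbitrary
  vertex of the solution set. Isolated variants get ϖ = 1 exactly.
  Solutions are verified against a lexicographic (residual, then norm)
  grid-search oracle on small systems, and the residual Σ_k ϖ_k r²_jk
  stays within [0.8, 1.2] for ≥95% of variants on synthetic panels.
- **LDAK-Thin**: ϖ ∈ {0,1} by greedy position-ordered thinning at
  r² > 0.98 (the conventional near-duplicate threshold), one
  representative per duplicate clique.
- **Normalization**: shares sum to 100 (percent of total expected
  heritability). **Tagging**: q_j = Σ_k r²_jk u_k over the same window as
  the LD computation; contributions beyond the window are truncated, not
  shrunk.

Why the two models diverge on LD-rich sets: LDAK's weight system makes q
approximately flat in local LD (the block shares one unit of weight),
while under Thin every retained variant keeps full weight, so a variant
in a moderate-LD region (below the thin threshold) tags many full-weight
neighbours and its q grows with block size. GWAS hits are
preferentially in such regions, which is why thinning inflates their
set sums relative to random sets.

## Panel, filters, LD

Variants are kept if autosomal (chrom 1–22) and MAF ≥ 0.01, threshold
inclusive. MAF = min(p, 1−p) with p = mean dosage / 2 over non-missing
individuals. r² is the squared Pearson correlation of dosage columns for
same-chromosome pairs within a 1 Mb window (no window is prescribed by
the underlying method description; 1 Mb is common practice and is
configurable). Missing genotypes are handled pairwise-complete.
Coordinates are 1-based throughout.

## Set statistics and the permutation null

G2 = G1 ∪ phenotype set; h² of a set is the plain sum of q over members.
The null draws 100 sets G3 = G1 ∪ (k uniform non-core variants) with
|G3| = |G2|, which controls the inflation that comes from set size alone.
Draws exclude core variants (preserving the exact size) but may include
other phenotypes' variants. Empirical p = (1 + #{draws ≥ observed}) /
(1 + 100); ties count toward the null (conservative), and the add-one
convention avoids p = 0. Calibration is verified directly: over 600
uniformly random phenotype sets the flag fires at the nominal 5% rate
(band 0.03–0.07), and sets planted in the top decile of q are flagged
with power > 0.8.

Guards: n_G2 = n_G1 (no phenotype-specific variants) is a defined error;
h̄²_pheno, AHPV, RHPV require positive sums; report-table rounding is
1 dp for set sums, 2 dp for ratio statistics, mean(sd) for the null.

## Synthetic data

The generators are the study conditions, not fixtures:

- **Panel**: 404 diploid individuals (the reported reference-panel size);
  LD in blocks of 10 variants via a latent Gaussian copula — each
  haplotype is a thresholded equicorrelated multivariate normal, dosage =
  sum of two haplotypes. All variants in a block share one allele
  frequency and the latent correlation is solved numerically (bivariate
  normal orthant mass, Brent's method) so the *realized genotype* r² lands
  near the target; with per-variant frequencies the attainable r² would be
  capped below it. Exact r² matching is not attempted — downstream code
  consumes realized r². Blocks are laid out on chromosomes 1–22
  round-robin, 1-based, 1 kb spacing. Blocks whose realized MAF falls
  below 0.01 are redrawn (bounded retries). Info scores default to 1
  (no data source states them for real catalogs; an option samples them
  in [0.8, 1]).
- **Catalog**: a 363-variant core set plus one set per phenotype with an
  *exact* requested core overlap, mirroring the published per-phenotype
  set sizes and union sizes (e.g. 363 + 98 − 1 = 460 for alcohol
  consumption). Cross-phenotype overlap arises by chance, as in real
  catalogs.
- **Network**: planted-hub model — pairs touching one of the first
  n_hubs nodes wired with p_hub, others with p_background; confidences
  uniform in (0, 1].
- **Gene sets**: random sets plus one planted set containing 80% of the
  interest genes.

What the synthetic data does *not* emulate: population structure,
relatedness, realistic MAF spectra, haplotype-scale LD decay, rare
variants, or the biological clustering of GWAS hits in the genome.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery, not that any real phenotype shows excess
heritability.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ m) via the survival function, checked
exactly against exhaustive enumeration of all C(N, n) draws for N ≤ 12;
BH step-up FDR (statsmodels) with significance at q < 0.05. The universe
defaults to the union of all set members plus the interest list; set
members outside the universe are dropped with a logged count.

## Hub screen

Harmonic closeness (finite under disconnection, which is routine for PPI
subnetworks), stress centrality (geodesic counts via BFS σ-products,
unordered pairs counted once), MNC (largest connected component of the
open neighbourhood) and EPC (Monte-Carlo expectation of the reachable-set
size under independent per-edge retention at the edge confidence, 0.5
fallback; deterministic per seed, standard error ∝ 1/√realizations).
Geodesic methods ignore confidences. Hub genes: per method, cutoff at the
⌈0.25·n⌉-th ranked score, ties at the cutoff included (deterministic;
the upstream tool's tie rule is undocumented, and both the count
convention and inclusivity are parameters); hub set = intersection across
the four methods, possibly empty. Subnetwork wiring is tested by
permuting equal-sized node subsets (add-one p as above) — this is a
topology permutation test, not equivalent to database-specific
interaction-enrichment nulls.

## Problem sizes

Defaults used by the analysis drivers: 404 × 4,000-variant panel (blocks
of 10 at target r² 0.6), the full 16-phenotype catalog at published set
sizes, 100 null replicates, 1,000 EPC realizations, 200-node network with
20 planted hubs, 1,000-gene universe with 40 + 1 sets. These sizes give
stable statistics while keeping every driver in seconds-to-minutes on one
CPU; all are parameters, not constants.

## Known limitations

- The LDAK weight solver is a windowed minimal-norm NNLS formulation of
  the published qualitative contract, not a port of the original solver;
  agreement is established against oracles, not against the original
  software's output.
- Tagging truncates at the window edge; long-range LD beyond 1 Mb is
  invisible.
- The empirical p has resolution 1/101 at 100 replicates; finer claims
  need more replicates.
- EPC is a Monte-Carlo estimate; ranking stability near the hub cutoff
  depends on the realization count.
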