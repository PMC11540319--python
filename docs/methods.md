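# Methods

This note documents the models implemented in `nrhap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Setting

The pipeline targets populations bred from a small panel of inbred
founders in which the Y and mitochondrial (MT) chromosomes are inherited
whole — no recombination, one parent each. Every modern animal therefore
carries a near-exact copy of one founder's nonrecombinant haplotype, and
in practice only a few founder lineages persist, clustering the
population into a small number of haplogroups (here: two per
chromosome, one "reference-like" — the lineage closest to the reference
assembly — and one "alternate"). Inputs are biallelic SNP genotypes from
low-coverage sequencing plus imputation, with a per-variant INFO quality
score; calls are REF / HET / ALT / MISSING.

## Haplogroup calling

**Hemizygous masking.** A single-copy chromosome cannot be heterozygous;
every HET call is converted to MISSING before any analysis. The operation
is idempotent and reported (count of masked calls).

**Filter cascade.** Four stages in a fixed order, each computed on the
output of the previous stage:

1. INFO score < `info_min` (default 0.9, explicit in replication configs);
2. minor allele frequency = 0 (monomorphic among non-missing calls; a
   surviving HET on a non-hemizygous chromosome contributes one REF and
   one ALT allele);
3. per-SNP missing rate > 0.25 (strict: exactly 25% is retained);
4. per-sample missing rate > 0.50 (strict).

The order is load-bearing — per-SNP and per-sample missing rates change
as earlier stages remove items — and the test suite contains a fixture
where swapping stages 3 and 4 changes the result. Any subset of stages
can be enabled per analysis (e.g. MAF is skipped when building consensus
haplotypes so newly fixed variants stay visible), but the relative order
is immutable. A variant with all calls missing has undefined MAF; it is
removed at the MAF stage when that stage runs, otherwise at the per-SNP
missingness stage, so it is always removed deterministically.

**Assignment.** Per sample, count REF and ALT calls over the filtered
variants; strict majority assigns the group, an exact tie leaves the
sample UNASSIGNED (never randomly labelled — downstream association
must not receive arbitrary group labels). Unassigned samples are excluded
from consensus building and from every association test.

**Consensus, founder match, intragroup variation.** The consensus is the
per-variant modal non-missing call among group members (MISSING on a
REF/ALT tie or when no member is called). Consensus–founder matching uses
Hamming distance ignoring sites missing in either haplotype; equal-best
founders are reported together with a tie flag. Intragroup variation
counts per-sample mismatches against the sample's own group consensus,
restricted to sites called in both, so masking a call can never increase
a mismatch count.

## Phylogeny

Pairwise distances between haplotypes are normalised Hamming distances on
the sites called in both (a pair with zero comparable sites is an error,
not a zero). Trees are built with classical neighbor joining: Q-criterion
join selection, the standard branch-length and distance-update formulas,
and a deterministic tie-break (the lexicographically smallest pair of
clade labels, a clade being labelled by its smallest leaf) so that
permuting the input order yields an isomorphic tree. Negative branch
lengths — possible on non-additive inputs — are kept as computed but
flagged; an option clamps them to zero and transfers the deficit to the
sister branch. Output is Newick, written rooted at an internal
(trifurcating) node as is conventional for unrooted trees. On any
additive matrix the tree reproduces the input distances to numerical
tolerance; the tests verify exact recovery against a brute-force
least-squares fit over all unrooted topologies for 4 and 5 taxa.

## Mixed-model PheWAS

Haplogroup is correlated with autosomal relatedness: full sibs share a
father (hence Y) and a mother (hence MT) as well as half their autosomes,
so any polygenic trait shows a spurious marginal haplogroup association.
The remedy is the standard mixed linear model association:

- **GRM.** From autosomal dosages after QC (missing rate > 0.1, exact
  Hardy–Weinberg p < 1e-10, MAF < 0.005 removed; the HWE test can be
  restricted to a sample subset, e.g. females only for X-chromosome QC
  where male hemizygosity distorts genotype frequencies):
  A(j,k) = mean over SNPs of (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)),
  averaging over SNPs non-missing in both samples. The HWE test is the
  exact conditional enumeration of heterozygote counts rather than
  chi-square, because the filter threshold sits at 1e-10 where the
  asymptotic approximation is unreliable.
- **Phenotypes.** OLS residuals on covariates (intercept included), then
  a rank-based inverse-normal transform with the Blom offset
  (r − 3/8)/(n + 1/4), average ranks for ties; the offset is
  configurable. Missing values propagate.
- **Encoding.** Reference-like group → 0, alternate group → 2, unassigned
  → missing (excluded per test). With this 0/2 coding the reported beta
  is a per-allele effect equal to half the group-mean difference.
- **REML.** y = Xβ + g + e with cov(g) = σg²·GRM, cov(e) = σe²·I. One
  spectral decomposition of the GRM per sample set; in the eigenbasis the
  restricted likelihood is a 1-D function of δ = σe²/σg², optimised over
  log δ ∈ [−10, 10] by a 21-point grid followed by bounded Brent search
  (the grid guards against local minima; an optimum at the upper bound is
  reported as σg² = 0). Estimates are nonnegative by construction. A GRM
  that is (a multiple of) the identity makes the components jointly
  unidentifiable and raises.
- **Test.** Components are estimated once per trait on the null model and
  held fixed for the haplotype test (one encoded variant per trait makes
  joint re-estimation pointless); the test is generalised least squares
  with a 1-df Wald chi-square. A genotype constant among the tested
  samples yields a flagged result with no p-value.
- **FDR.** Benjamini–Hochberg step-up q-values across traits, separately
  per chromosome type. Binary traits unsuited to the mixed model are
  tested by a one-sided Fisher's exact test (zero-margin tables return
  p = 1, flagged).

Under the confounded simulation (haplogroup nested in sibships, purely
polygenic traits) the package's own acceptance checks measure MLMA type-I
error 0.05 ± 0.01 and genomic-control λ ≈ 1.0 where naive OLS shows
λ > 3.

## Expression

Counts are gene-level integers per tissue. Genes detectably expressed
(count > 0; threshold configurable) in fewer than 10% of samples are
dropped. TMM normalisation follows the published algorithm exactly:
reference sample = the one whose 75th-percentile count fraction is
closest to the mean of those fractions; per-sample factor = inverse-
variance-weighted mean of log2 expression ratios against the reference
after trimming 30% of M-values and 5% of A-values; factors rescaled to
geometric mean 1; normalised value = count / (library size × factor) ×
1e6. The implementation agrees with edgeR's `calcNormFactors` to 1e-8
(tested via Rscript).

Differential expression between haplogroups uses the two-sided
Mann–Whitney test — exact null distribution when both groups have ≤ 25
observations and no ties, otherwise the normal approximation with tie and
continuity corrections (real cohorts always use the approximation; the
exact path exists for the small-sample tests). Rank tests are invariant
under monotone transforms, so results are identical on CPM and log-CPM.
BH q-values are pooled across all genes and tissues within a chromosome
type (per-tissue pooling available as an option). Samples without a
haplogroup assignment drop out first — which automatically excludes
females from Y analyses. The X-SNP scan is a plain per-sex linear
regression of one gene's expression on dosage (0/1/2), with the Y
haplogroup indicator as a covariate in males, reported only for SNPs with
at least 5 minor-allele carriers in the stratum; strata under 3 samples
are skipped.

## Synthetic data

The generator produces, from per-artifact seeds fanned out of one master
seed (`derive_seeds`, values < 2^31):

- **Founder panel:** two haplogroups with `d_between` sites fixed-different
  between groups and `d_within` private sites per founder, on a fixed site
  budget (validated). Differences between founders are exact by
  construction, which the tests exploit.
- **Population:** each sample inherits one founder haplotype (drawn i.i.d.
  from founder frequencies, or constant within sibships for the
  confounded design); each call is observed as the latent allele with
  probability 1 − m_i − ε, as HET with probability ε, as MISSING with
  probability m_i, where m_i is the sample's missing rate drawn from a
  clipped normal. INFO scores are Beta-distributed per variant
  (default Beta(9,1), skewed toward 1 like real imputation scores —
  a synthetic choice; no quantitative distribution was available to
  copy).
- **Autosomes:** full-sib families drawn from four parental haplotypes
  with independent assortment per SNP; within-sibship GRM entries are
  ~0.5 as for real full sibs. No linkage disequilibrium and no
  multi-generation pedigree — enough structure for GRM/REML behaviour,
  not a breeding-program simulator.
- **Phenotypes:** covariate effects + polygenic term built from the
  standardised dosages (variance = heritability) + haplotype effect on a
  0/1 group indicator + Gaussian residual (variance = 1 − heritability);
  `hap_effect` is in non-haplotype SD units and 0 gives exact nulls.
- **Expression:** negative-binomial counts (var = μ + φμ²), per-gene
  baseline log-means and dispersions, fold changes applied to the
  alternate group for DE genes, optional male-specific genes emitting
  zero counts in females, and a uniform library-size range.

Default observation noise in the pipeline config is modest
(missing rate ~0.15 ± 0.08) because imputed data have low missingness —
that is what makes the published cascade thresholds meaningful — while
the recovery stress test uses 50–80% missingness with 1% het errors.
What the generator does **not** emulate: linkage disequilibrium,
coverage-dependent error profiles, library-preparation batch structure,
pseudo-autosomal leakage, structural variants, or multi-tissue
correlation in expression. Passing tests therefore demonstrate the
statistical machinery under the stated generative model, not robustness
to every artifact of real sequencing data.

## Numerical conventions and problem sizes

- Coordinates are 1-based (VCF convention) throughout.
- INFO scores round-trip through float32 in VCF INFO fields; the INFO
  threshold comparison uses a 1e-6 tolerance so a score written exactly
  at the threshold is retained deterministically.
- Haploid and diploid GT encodings are both accepted on read (0 → REF,
  1 → ALT for haploid calls); multiallelic records are dropped and
  counted.
- NJ join ties: smallest (sorted) pair of clade labels. Consensus ties:
  MISSING. Assignment ties: UNASSIGNED.
- BH q-values: step-up with cumulative minimum, capped at 1, returned in
  input order.
- The property checks run at deliberately compact sizes chosen to make
  their statistical bounds sharp: 2,000 samples × 5,000 sites for
  haplogroup recovery; n = 1,000 with 2,000 SNPs, sibships of 10 and
  2,000 null traits for MLMA calibration; 50 replicates for REML
  recovery; 100 replicates each for the null-PheWAS and DE-power checks;
  all exact-kernel enumerations cover every table up to their stated n.
  `scripts/acceptance.py --seed <s> --out <path>` reruns all of them and
  completes in well under a minute.

## Known limitations

- Exactly two haplogroups per chromosome are modelled (the motivating
  population has two); more groups would need a different assignment
  rule.
- Probabilistic/likelihood-based assignment, genotype likelihoods (GL/PL),
  bootstrap support, eQTL permutation schemes and leave-one-chromosome-out
  GRMs are out of scope.
- The REML fit is single-component (one GRM); multi-component models are
  not supported.
- λ estimates from small trait panels (e.g. the 20-trait worked example)
  are noisy; calibration statements rest on the 2,000-trait check.
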