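# nrhap — nonrecombinant-chromosome haplotype analysis

`nrhap` is a tested, reusable pipeline for analysing the **Y and
mitochondrial (MT) chromosomes** in outbred rodent populations descended
from a small panel of inbred founder strains (heterogeneous stock and
similar designs). Because Y and MT do not recombine, every animal carries
one founder's haplotype essentially intact; with low-coverage imputed
genotypes this lets you

1. **call haplogroups** from biallelic SNPs by a simple allele-majority
   rule after masking biologically impossible heterozygous calls
   (hemizygous chromosomes carry one copy, so an observed het is an
   error),
2. **reconstruct per-group consensus haplotypes** and match them to
   founders by Hamming distance ignoring missingness,
3. build **unrooted neighbor-joining trees** of founder haplotypes,
4. run a **mixed-model PheWAS**: haplogroup encoded as a biallelic dosage
   (0 = reference-like group, 2 = alternate group) tested against many
   phenotypes with a polygenic random effect whose covariance is the
   autosomal genetic relationship matrix (GRM) — necessary because
   haplogroup is nested in families and naive regression is confounded,
5. run **rank-based differential expression** (TMM-normalised CPM +
   Mann–Whitney, BH FDR) treating the two haplogroups as conditions, and
   a **sex-stratified X-SNP linear scan** for individual genes.

A first-class synthetic-data generator reproduces the statistical
structure of such a study (founder panels, low-coverage observation noise,
full-sib family confounding, polygenic traits, negative-binomial counts)
together with truth tables, so every step is verifiable end to end.

## The model

Haplogroup calling: for sample *i* with *r_i* reference and *a_i*
alternate calls across filtered SNPs, the label is REF-like if
*r_i > a_i*, ALT-like if *a_i > r_i*, unassigned on a tie. Genotype QC is
an ordered cascade — INFO score, MAF = 0, per-SNP missingness > 25%,
per-sample missingness > 50% — each stage computed on the output of the
previous one.

Association: for trait *y* (covariate-residualised, then rank
inverse-normal transformed),

```
y = x β + Z u + ε,   u ~ N(0, σg² · GRM),   ε ~ N(0, σe² I)
```

with *x* ∈ {0, 2} the haplogroup dosage. (σg², σe²) are estimated by REML
on the null model via one spectral decomposition of the GRM and a 1-D
optimisation over the variance ratio; the haplotype effect is then tested
by generalised least squares with a 1-df Wald χ². q-values are
Benjamini–Hochberg across traits.

## Worked example

The numbered drivers under `analysis/` run a full synthetic study
(2,000 samples, 5,000 Y-like SNPs, 8 founders in a 3:5 haplogroup split,
full-sib families confounded with haplogroup, 20 polygenic null traits,
200 genes with two planted 2-fold DE genes):

```
python analysis/01_simulate_cohort.py
python analysis/02_call_haplogroups.py
python analysis/03_founder_phylogeny.py
python analysis/04_phewas.py
python analysis/05_expression_de.py
```

`02_call_haplogroups.py` prints the filter audit and the calls:

```
         stage  examined  removed  threshold
          INFO      5000     1917       0.90
           MAF      3083      576       0.00
   SNP_MISSING      2507        0       0.25
SAMPLE_MISSING      2000        0       0.50

masked 100141 spurious heterozygous calls; 2507 SNPs x 2000 samples survive
haplogroups: 744 reference-like, 1256 alternate
assignment accuracy vs truth: 100.0000%
consensus divergence between groups: 2463 SNPs
```

i.e. ~20% of variants fall to the INFO filter, monomorphic sites to MAF,
and every sample is then assigned to the correct haplogroup; the two
consensus haplotypes differ at essentially all surviving between-group
sites. `04_phewas.py` shows why the mixed model matters:

```
significant at FDR < 0.05: 0 trait(s)
MLMA genomic inflation lambda: 0.784
naive OLS lambda on the same traits: 2.725 (inflated by design)
one-sided Fisher's exact test on the binary trait: P=0.66
```

All 20 traits are true nulls: MLMA keeps the hit list empty while plain
regression on the same data would be wildly anticonservative (λ ≈ 2.7).
`05_expression_de.py` recovers both planted DE genes as the
positive control:

```
tested 200 genes; significant at FDR < 0.05: 3
planted DE genes recovered: 2/2
false positives at FDR < 0.05: 1
```

The same stages are available as a CLI over a single YAML config:
`nrhap simulate|haplotype|tree|phewas|expression|all -c config.yaml`.

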