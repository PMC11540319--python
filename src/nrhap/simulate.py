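"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates an outbred population descended from a small founder
panel in which the nonrecombinant chromosome (Y or MT) is inherited whole
from a single founder:

* a founder panel of haploid haplotypes split into two haplogroups, with a
  block of sites fixed-different between the groups and private variants
  within each founder;
* a modern population in which every sample carries one founder haplotype,
  observed through a low-coverage screen: per-sample missingness, a small
  rate of spurious heterozygous calls (impossible on a hemizygous
  chromosome, hence pure error), and per-variant imputation INFO scores;
* autosomal dosages with optional full-sib family structure, the raw
  material for the GRM -- and, when sibships are coupled to haplogroup, for
  the confounding that motivates mixed-model association;
* polygenic phenotypes with optional haplotype effects and covariates;
* negative-binomial expression counts with haplotype-linked differential
  expression and optional male-specific genes.

Every artifact carries its own seed so parts can be regenerated
independently; :func:`derive_seeds` fans a master seed out into per-artifact
seeds.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import ALT, HET, MISSING, REF, GenotypeMatrix
from .haplotyping import ALT_GROUP, REF_GROUP
from .phewas import DosageMatrix


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into ``n`` independent per-artifact seeds (< 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Founder panel


@dataclasses.dataclass
class FounderSimConfig:
    """Two-haplogroup founder panel layout.

    ``group_split`` partitions the founders: the first element is the size
    of the reference-like group (haplotypes mostly REF), the second the size
    of the alternate group.  ``d_between`` sites are fixed-different between
    the groups; each founder additionally carries ``d_within`` private sites.
    """

    n_founders: int = 8
    n_sites: int = 5000
    group_split: tuple[int, int] = (3, 5)
    d_between: int = 4000
    d_within: int = 0
    seed: int = 0
    chromosome: str = "Y"

    def __post_init__(self) -> None:
        if sum(self.group_split) != self.n_founders:
            raise SimConfigError("group_split must partition the founders")
        if min(self.group_split) < 1:
            raise SimConfigError("each haplogroup needs at least one founder")
        budget = self.d_between + self.n_founders * self.d_within
        if budget > self.n_sites:
            raise SimConfigError(
                f"site budget exceeded: d_between + private sites = {budget} "
                f"> n_sites = {self.n_sites}"
            )


def simulate_founder_haplotypes(config: FounderSimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate the founder panel and its group table.

    Every cross-group founder pair differs at exactly ``d_between`` sites
    beyond their private sites; a within-group pair differs at exactly the
    union of their private sites.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_founders, config.n_sites
    names = [f"F{i + 1:02d}" for i in range(n)]
    groups = [REF_GROUP] * config.group_split[0] + [ALT_GROUP] * config.group_split[1]

    # choose disjoint site sets: between-group block, then private blocks
    budget = config.d_between + n * config.d_within
    chosen = rng.choice(m, size=budget, replace=False)
    between_sites = chosen[: config.d_between]
    private = {
        names[i]: chosen[config.d_between + i * config.d_within:
                         config.d_between + (i + 1) * config.d_within]
        for i in range(n)
    }

    calls = np.full((n, m), REF, dtype=np.int8)
    for i in range(n):
        if groups[i] == ALT_GROUP:
            calls[i, between_sites] = ALT
        # a private site flips the founder's own group background
        sites = private[names[i]]
        calls[i, sites] = np.where(calls[i, sites] == REF, ALT, REF)

    variants = pd.DataFrame(
        {
            "chrom": config.chromosome,
            "pos": np.arange(1, m + 1),
            "id": [f"{config.chromosome}_{p}" for p in range(1, m + 1)],
            "ref": "A",
            "alt": "G",
            "info_score": np.nan,
        }
    )
    panel = GenotypeMatrix(sample_ids=names, variants=variants, calls=calls)
    table = pd.DataFrame({"founder": names, "group": groups})
    return panel, table


# ---------------------------------------------------------------------------
# Modern population under the low-coverage observation model


@dataclasses.dataclass
class PopulationSimConfig:
    """Observation model for a low-coverage modern population.

    ``group_frequencies`` gives the probability that each founder contributed
    the nonrecombinant chromosome (must sum to 1).  Per-sample missing rates
    are drawn from a normal clipped to [0, 1]; ``het_error_rate`` is the
    probability that a non-missing call is emitted as a (spurious) HET.
    INFO scores are Beta-distributed per variant, a shape choice matching
    the skewed-toward-1 scores low-coverage imputation produces.
    """

    n_samples: int = 2000
    group_frequencies: Sequence[float] = ()
    missing_rate_mean: float = 0.65
    missing_rate_sd: float = 0.1
    het_error_rate: float = 0.01
    info_beta: tuple[float, float] = (9.0, 1.0)
    female_fraction: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name, v in (
            ("missing_rate_mean", self.missing_rate_mean),
            ("missing_rate_sd", self.missing_rate_sd),
            ("het_error_rate", self.het_error_rate),
            ("female_fraction", self.female_fraction),
        ):
            if v < 0 or (name != "missing_rate_sd" and v > 1):
                raise SimConfigError(f"{name}={v} out of range")
        if self.group_frequencies:
            if abs(sum(self.group_frequencies) - 1.0) > 1e-9:
                raise SimConfigError("group_frequencies must sum to 1")
            if min(self.group_frequencies) < 0:
                raise SimConfigError("negative founder frequency")


@dataclasses.dataclass
class TruthTable:
    """Ground truth for a simulated cohort.

    ``samples`` has one row per sample (sample_id, founder, group, sex, and
    sibship once autosomes are simulated); ``traits`` and ``genes`` record
    the true haplotype effect per trait and true DE status per gene once the
    corresponding artifacts exist.
    """

    samples: pd.DataFrame
    traits: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None


def simulate_population(
    panel: GenotypeMatrix,
    founder_groups: pd.DataFrame,
    config: PopulationSimConfig,
    founder_idx: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw a modern population inheriting whole founder haplotypes.

    Each observed call is the latent founder allele with probability
    (1 - missing_i - het_error), HET with probability het_error, and MISSING
    otherwise, where missing_i is the sample's own missing rate.
    ``founder_idx`` fixes each sample's founder of origin (e.g. constant
    within sibships, the confounded design); by default founders are drawn
    independently per sample from ``group_frequencies``.
    """
    if panel.n_samples == 0:
        raise ValueError("empty founder panel")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, panel.n_variants
    freqs = (
        np.asarray(config.group_frequencies, dtype=float)
        if len(config.group_frequencies)
        else np.full(panel.n_samples, 1.0 / panel.n_samples)
    )
    if freqs.size != panel.n_samples:
        raise SimConfigError("group_frequencies length must match panel size")

    if founder_idx is None:
        founder_idx = rng.choice(panel.n_samples, size=n, p=freqs)
    else:
        founder_idx = np.asarray(founder_idx)
        if founder_idx.shape != (n,):
            raise SimConfigError("founder_idx length must equal n_samples")
    latent = panel.calls[founder_idx, :]

    miss = np.clip(
        rng.normal(config.missing_rate_mean, config.missing_rate_sd, size=n), 0, 1
    )
    e = config.het_error_rate
    miss = np.minimum(miss, 1.0 - e)
    u = rng.random((n, m))
    calls = latent.copy()
    calls[u < e] = HET
    calls[(u >= e) & (u < e + miss[:, None])] = MISSING

    info = rng.beta(*config.info_beta, size=m)
    variants = panel.variants.copy()
    variants["info_score"] = info

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    matrix = GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)

    group_of = dict(zip(founder_groups["founder"], founder_groups["group"]))
    sex = np.where(
        rng.random(n) < config.female_fraction, "female", "male"
    )
    truth = TruthTable(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "founder": [panel.sample_ids[i] for i in founder_idx],
                "group": [group_of[panel.sample_ids[i]] for i in founder_idx],
                "sex": sex,
                "missing_rate": miss,
            }
        )
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Autosomal dosages with sibship structure


def simulate_autosomal_dosages(
    n_samples: int,
    n_snps: int,
    sibship_size: int = 1,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[DosageMatrix, np.ndarray]:
    """Biallelic autosomal dosages, optionally in full-sib families.

    Siblings are drawn from four shared parental haplotypes (one transmitted
    per parent, chosen independently per SNP), giving the expected full-sib
    kinship: within-sibship GRM entries ~0.5, between ~0.  Returns the
    dosage matrix and the per-sample sibship index.
    """
    if sibship_size < 1:
        raise ValueError("sibship_size must be >= 1")
    if n_samples % sibship_size != 0:
        raise ValueError("n_samples must be divisible by sibship_size")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, size=n_snps)
    n_fam = n_samples // sibship_size

    # 4 parental haplotypes per family
    parental = (rng.random((n_fam, 4, n_snps)) < p[None, None, :]).astype(np.int8)
    dosages = np.empty((n_samples, n_snps), dtype=float)
    sibships = np.repeat(np.arange(n_fam), sibship_size)
    for fam in range(n_fam):
        for k in range(sibship_size):
            from_mom = np.where(
                rng.random(n_snps) < 0.5, parental[fam, 0], parental[fam, 1]
            )
            from_dad = np.where(
                rng.random(n_snps) < 0.5, parental[fam, 2], parental[fam, 3]
            )
            dosages[fam * sibship_size + k] = from_mom + from_dad

    ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    snp_ids = [f"chr{1 + i % 20}_snp{i + 1}" for i in range(n_snps)]
    return DosageMatrix(sample_ids=ids, snp_ids=snp_ids, dosages=dosages), sibships


def draw_founders_by_sibship(
    sibships: np.ndarray,
    n_founders: int,
    frequencies: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Founder-of-origin indices constant within each sibship.

    Models the fact that full sibs inherit the same nonrecombinant
    chromosome, so haplogroup is nested in family -- the source of
    confounding between haplotype and autosomal relatedness.
    """
    rng = np.random.default_rng(seed)
    p = (
        np.asarray(frequencies, dtype=float)
        if frequencies is not None
        else np.full(n_founders, 1.0 / n_founders)
    )
    fams = np.unique(sibships)
    fam_founder = rng.choice(n_founders, size=fams.size, p=p)
    lookup = dict(zip(fams.tolist(), fam_founder.tolist()))
    return np.array([lookup[f] for f in sibships])


def assign_groups_by_sibship(
    sibships: np.ndarray, p_alt: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Haplogroup labels constant within each sibship (confounded design).

    Full sibs share a father, hence a Y haplogroup, and a mother, hence an
    MT haplotype -- so haplogroup is perfectly nested in family.  Any trait
    with a polygenic component then shows a spurious marginal haplogroup
    association that only a relatedness-aware test removes.
    """
    rng = np.random.default_rng(seed)
    fams = np.unique(sibships)
    fam_group = np.where(rng.random(fams.size) < p_alt, ALT_GROUP, REF_GROUP)
    lookup = dict(zip(fams.tolist(), fam_group.tolist()))
    return np.array([lookup[f] for f in sibships])


# ---------------------------------------------------------------------------
# Phenotypes


@dataclasses.dataclass
class PhenotypeSimConfig:
    """Polygenic phenotype generator settings.

    Each trait is
        covariate effects + polygenic term + hap_effect * 1[alternate group]
        + residual,
    with the polygenic term built from the standardised autosomal dosages and
    scaled to variance ``heritability``; the residual has variance
    1 - heritability, so ``hap_effect`` is in (non-haplotype) SD units.
    """

    n_traits: int = 1
    heritability: float = 0.0
    hap_effect: float | Sequence[float] = 0.0
    covariate_effects: Sequence[float] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise SimConfigError(f"heritability={self.heritability} outside [0, 1]")

    def hap_effects(self) -> np.ndarray:
        eff = np.asarray(self.hap_effect, dtype=float)
        if eff.ndim == 0:
            eff = np.full(self.n_traits, float(eff))
        if eff.size != self.n_traits:
            raise SimConfigError("hap_effect length must equal n_traits")
        return eff


def simulate_phenotypes(
    dosages: DosageMatrix,
    groups: np.ndarray,
    config: PhenotypeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate traits on a cohort; returns (phenotypes, covariates, truth).

    ``groups`` holds each sample's haplogroup label.  Traits with
    hap_effect 0 are exact nulls for the haplotype test (though confounded
    with relatedness whenever groups follow sibships and heritability > 0).
    """
    rng = np.random.default_rng(config.seed)
    n = dosages.n_samples
    groups = np.asarray(groups)
    if groups.size != n:
        raise ValueError("groups length must match sample count")
    indicator = (groups == ALT_GROUP).astype(float)

    d = dosages.dosages
    p = dosages.allele_frequencies()
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z)
    m = z.shape[1]

    effects = config.hap_effects()
    n_cov = len(config.covariate_effects)
    covariates = rng.standard_normal((n, n_cov)) if n_cov else np.zeros((n, 0))
    cov_beta = np.asarray(config.covariate_effects, dtype=float)

    h2 = config.heritability
    traits = {}
    for t in range(config.n_traits):
        poly = z @ rng.normal(0.0, np.sqrt(h2 / m), size=m) if h2 > 0 else 0.0
        resid = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
        traits[f"trait_{t + 1:04d}"] = (
            covariates @ cov_beta + poly + effects[t] * indicator + resid
        )

    phenotypes = pd.DataFrame(traits, index=pd.Index(dosages.sample_ids, name="sample_id"))
    cov_table = pd.DataFrame(
        covariates,
        index=phenotypes.index,
        columns=[f"cov_{k + 1}" for k in range(n_cov)],
    )
    truth = pd.DataFrame(
        {"trait": list(traits), "hap_effect": effects, "heritability": h2}
    )
    return phenotypes, cov_table, truth


# ---------------------------------------------------------------------------
# Expression counts


@dataclasses.dataclass
class ExpressionSimConfig:
    """Negative-binomial expression generator settings.

    ``de_genes`` maps gene index -> fold change applied to the alternate
    haplogroup's mean; ``male_specific_genes`` emit zero counts in females
    (the behaviour of Y-linked genes).  ``dispersion`` is the NB
    overdispersion phi (var = mu + phi mu^2); must be positive.
    """

    n_genes: int = 200
    baseline_log_mean: float | Sequence[float] = 4.0
    dispersion: float | Sequence[float] = 0.1
    de_genes: Mapping[int, float] = dataclasses.field(default_factory=dict)
    male_specific_genes: Sequence[int] = ()
    library_size_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp <= 0).any():
            raise SimConfigError("dispersion must be positive")
        bad = [g for g in self.de_genes if not 0 <= g < self.n_genes]
        bad += [g for g in self.male_specific_genes if not 0 <= g < self.n_genes]
        if bad:
            raise SimConfigError(f"gene indices out of range: {bad}")


def simulate_expression(
    truth: TruthTable,
    config: ExpressionSimConfig,
    tissue: str = "tissue1",
) -> tuple["pd.DataFrame", pd.DataFrame]:
    """Simulate a genes x samples count table for one tissue.

    Returns (counts DataFrame, per-gene truth with DE status/fold change).
    """
    from .expression import CountMatrix  # local import to avoid cycle at import time

    rng = np.random.default_rng(config.seed)
    samples = truth.samples
    n = len(samples)
    g = config.n_genes
    base = np.asarray(config.baseline_log_mean, dtype=float)
    if base.ndim == 0:
        base = np.full(g, float(base))
    disp = np.asarray(config.dispersion, dtype=float)
    if disp.ndim == 0:
        disp = np.full(g, float(disp))

    lib = rng.uniform(*config.library_size_range, size=n)
    lib = lib / lib.mean()
    is_alt = (samples["group"].to_numpy() == ALT_GROUP).astype(float)
    is_female = samples["sex"].to_numpy() == "female"

    fc = np.ones(g)
    for gene_idx, fold in config.de_genes.items():
        fc[gene_idx] = fold

    mu = np.exp(base)[:, None] * (fc[:, None] ** is_alt[None, :]) * lib[None, :]
    size = 1.0 / disp
    counts = rng.negative_binomial(
        n=size[:, None], p=size[:, None] / (size[:, None] + mu)
    )
    for gene_idx in config.male_specific_genes:
        counts[gene_idx, is_female] = 0

    gene_ids = [f"gene_{i + 1:04d}" for i in range(g)]
    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=samples["sample_id"].tolist(),
        counts=counts,
        tissue=tissue,
    )
    gene_truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_de": [i in config.de_genes and config.de_genes[i] != 1.0
                      for i in range(g)],
            "fold_change": fc,
            "male_specific": [i in set(config.male_specific_genes) for i in range(g)],
        }
    )
    return cm, gene_truth
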