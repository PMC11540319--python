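"""Differential expression by haplogroup and the sex-stratified X-SNP scan.

Expression analysis treats the two haplogroups of a nonrecombinant
chromosome as conditions in a standard DE design rather than mapping eQTLs:
counts are TMM-normalised to counts-per-million, each gene is tested with a
two-sided Mann-Whitney (Wilcoxon rank-sum) test between haplogroups, and
Benjamini-Hochberg q-values are pooled across all genes and tissues for a
chromosome type.  Rank tests are invariant under monotone transforms of the
normalised values, so the choice of log scale is immaterial.

TMM (trimmed mean of M-values) follows the published algorithm exactly:
log2 expression ratios (M) and average log intensities (A) of each sample
against a reference sample are doubly trimmed (30% on M, 5% on A) and the
surviving M-values averaged with inverse delta-method-variance weights; the
resulting factors are rescaled to geometric mean one.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .haplotyping import ALT_GROUP, REF_GROUP
from .phewas import bh_fdr, linear_association

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CountMatrix:
    """Gene-level counts for one tissue: genes x samples, nonnegative ints."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx].copy(),
            tissue=self.tissue,
        )


def filter_genes(counts: CountMatrix, min_fraction: float = 0.10) -> CountMatrix:
    """Drop genes detectably expressed (count > 0) in fewer than
    ``min_fraction`` of samples; exactly at the boundary is retained."""
    frac = (counts.counts > 0).mean(axis=1)
    keep = frac >= min_fraction
    return CountMatrix(
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        sample_ids=list(counts.sample_ids),
        counts=counts.counts[keep],
        tissue=counts.tissue,
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m, method="average")
    ra = stats.rankdata(a, method="average")
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2**f) if np.isfinite(f) else 1.0


def tmm_normalize(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> tuple[pd.Series, np.ndarray]:
    """TMM normalisation factors and normalised counts-per-million.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  Factors are rescaled to
    geometric mean 1; the normalised value is
    count / (library size * factor) * 1e6.
    """
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
        raise ValueError(f"zero library size for sample(s) {bad}")
    x = counts.counts.astype(float)
    f75 = np.quantile(x, 0.75, axis=0) / lib
    if f75.min() < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                             logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = x / (lib * factors)[None, :] * 1e6
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor"), cpm


def mann_whitney(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have <= 25 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U of the first group, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 25 and b.size <= 25 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def de_scan(
    tissue_counts: dict[str, CountMatrix],
    assignments: pd.DataFrame,
    chromosome_type: str,
    min_fraction: float = 0.10,
    pool_tissues: bool = True,
) -> pd.DataFrame:
    """Haplogroup differential expression across tissues.

    Per tissue: keep only samples with a haplogroup assignment, drop genes
    below the detectable-expression fraction, TMM-normalise, and Mann-Whitney
    test each gene between haplogroups.  BH q-values are computed across all
    genes and tissues for the chromosome type (``pool_tissues=False`` pools
    per tissue instead).  Tissues with fewer than two haplogroups present
    are skipped with a warning.
    """
    label_of = dict(zip(assignments["sample_id"], assignments["label"]))
    rows = []
    for tissue, cm in tissue_counts.items():
        labels = np.array([label_of.get(s, "NONE") for s in cm.sample_ids])
        keep = np.isin(labels, [REF_GROUP, ALT_GROUP])
        if keep.sum() == 0 or np.unique(labels[keep]).size < 2:
            logger.warning(
                "tissue %s skipped: fewer than two haplogroups present", tissue
            )
            continue
        sub = cm.subset_samples(keep)
        labels = labels[keep]
        sub = filter_genes(sub, min_fraction=min_fraction)
        if not sub.gene_ids:
            continue
        _, cpm = tmm_normalize(sub)
        in_ref = labels == REF_GROUP
        for gi, gene in enumerate(sub.gene_ids):
            va, vb = cpm[gi, in_ref], cpm[gi, ~in_ref]
            u, p = mann_whitney(va, vb)
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "chrom_type": chromosome_type,
                    "median_ref_group": float(np.median(va)),
                    "median_alt_group": float(np.median(vb)),
                    "U": u,
                    "p": p,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=["gene", "tissue", "chrom_type", "median_ref_group",
                 "median_alt_group", "U", "p"],
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        return result
    if pool_tissues:
        result["q"] = bh_fdr(result["p"].to_numpy())
    else:
        result["q"] = np.nan
        for tissue in result["tissue"].unique():
            sel = result["tissue"] == tissue
            result.loc[sel, "q"] = bh_fdr(result.loc[sel, "p"].to_numpy())
    return result


def xsnp_linear_scan(
    expression: pd.Series,
    x_genotypes,
    sex: pd.Series,
    y_assignments: pd.DataFrame | None = None,
    min_carriers: int = 5,
    min_stratum: int = 3,
) -> pd.DataFrame:
    """Sex-stratified linear scan of one gene's expression on X-chromosome SNPs.

    For each sex separately and each SNP with at least ``min_carriers``
    minor-allele carriers in the stratum, regress expression on the dosage
    (0/1/2 copies of the alternate allele); male models additionally include
    the Y haplogroup indicator as a covariate.  Strata smaller than
    ``min_stratum`` are skipped.  Genotype QC (missingness, female-only HWE,
    MAF) is assumed done upstream via :func:`nrhap.phewas.grm_snp_filters`.
    """
    expr = expression
    hap = None
    if y_assignments is not None:
        hap = dict(zip(y_assignments["sample_id"], y_assignments["label"]))
    rows = []
    for stratum in ("male", "female"):
        in_stratum = [
            i for i, s in enumerate(x_genotypes.sample_ids)
            if sex.get(s) == stratum and s in expr.index
            and np.isfinite(expr[s])
        ]
        if len(in_stratum) < min_stratum:
            continue
        ids = [x_genotypes.sample_ids[i] for i in in_stratum]
        y = expr.loc[ids].to_numpy(dtype=float)
        covar = None
        if stratum == "male" and hap is not None:
            covar = np.array(
                [1.0 if hap.get(s) == ALT_GROUP else 0.0 for s in ids]
            )
            if np.ptp(covar) == 0:
                covar = None
        for j, snp in enumerate(x_genotypes.snp_ids):
            g = x_genotypes.dosages[in_stratum, j]
            ok = np.isfinite(g)
            if ok.sum() < min_stratum:
                continue
            gv = g[ok]
            freq = gv.mean() / 2
            minor_dose = gv if freq <= 0.5 else 2 - gv
            n_carriers = int((minor_dose > 0).sum())
            if n_carriers < min_carriers:
                continue
            yv = y[ok]
            cv = covar[ok] if covar is not None else None
            if np.ptp(gv) == 0:
                continue
            slope, _, p = linear_association(yv, gv, cv)
            rows.append(
                {
                    "snp_id": snp,
                    "sex": stratum,
                    "slope": slope,
                    "p": p,
                    "n_carriers": n_carriers,
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "sex", "slope", "p", "n_carriers", "n"]
    )
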