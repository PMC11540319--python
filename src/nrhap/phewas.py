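"""Mixed-model association of haplotype-as-SNP against many phenotypes.

In an outbred population bred from a few founders, Y/MT haplogroup is
correlated with autosomal relatedness through family structure, so a naive
regression of trait on haplogroup is confounded.  The remedy used here is
the standard mixed linear model association (MLMA): the haplogroup, encoded
as a biallelic "SNP" dosage (0 for the reference-like group, 2 for the
alternate group), is tested as a fixed effect while a polygenic random
effect with covariance proportional to the autosomal genetic relationship
matrix (GRM) absorbs relatedness:

    y = X b + g + e,   g ~ N(0, sg2 * GRM),   e ~ N(0, se2 * I)

Variance components are estimated once per trait by REML on the null model
(covariates only) via a single spectral decomposition of the GRM and a 1-D
optimisation over the variance ratio, then reused for the haplotype test
(generalised least squares with fixed V; Wald chi-square with 1 df).

Phenotypes are preprocessed GWAS-style: OLS residuals on covariates, then a
rank-based inverse-normal transform.  Multiple testing across traits is
handled by Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .haplotyping import ALT_GROUP, REF_GROUP, UNASSIGNED

# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, the heterozygote count follows a known
    distribution under HWE; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one
    (Wigginton-style enumeration).  Exactness matters at the extreme
    thresholds (e.g. 1e-10) used for genotype QC, where the chi-square
    approximation is unreliable.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(homr + 1)
        - special.gammaln(homc + 1)
        + hets * np.log(2.0)
        + special.gammaln(n_A + 1)
        + special.gammaln(n_a + 1)
        - special.gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed = prob[hets == n_Aa][0]
    return float(min(prob[prob <= observed * (1 + 1e-12)].sum(), 1.0))


# ---------------------------------------------------------------------------
# Dosage matrix, GRM-path SNP filters and GRM construction


@dataclasses.dataclass
class DosageMatrix:
    """Autosomal dosages in {0,1,2} with NaN for missing calls."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float (n_samples, n_snps), NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape mismatch")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP ALT allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def grm_snp_filters(
    dosages: DosageMatrix,
    max_missing: float = 0.1,
    hwe_p_min: float = 1e-10,
    maf_min: float = 0.005,
    hwe_sample_subset: np.ndarray | None = None,
) -> DosageMatrix:
    """SNP QC for the GRM path: missingness, HWE and MAF.

    A SNP is removed if its missing rate exceeds ``max_missing`` (strictly),
    its exact HWE p-value falls below ``hwe_p_min``, or its MAF falls below
    ``maf_min``.  ``hwe_sample_subset`` (boolean mask over samples) restricts
    the HWE test to a subset -- e.g. females only when QCing X-chromosome
    SNPs, where male hemizygosity distorts genotype frequencies.
    """
    d = dosages.dosages
    miss = np.isnan(d).mean(axis=0)
    keep = miss <= max_missing

    hwe_d = d if hwe_sample_subset is None else d[np.asarray(hwe_sample_subset)]
    for j in np.flatnonzero(keep):
        col = hwe_d[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            keep[j] = False
            continue
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if hwe_exact_test(n_AA, n_het, n_aa) < hwe_p_min:
            keep[j] = False

    freq = dosages.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    keep &= ~np.isnan(maf)
    keep &= maf >= maf_min

    if not keep.any():
        raise ValueError("all SNPs removed by GRM filters")
    idx = np.flatnonzero(keep)
    return DosageMatrix(
        sample_ids=list(dosages.sample_ids),
        snp_ids=[dosages.snp_ids[j] for j in idx],
        dosages=d[:, idx].copy(),
    )


def compute_grm(dosages: DosageMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Genetic relationship matrix from standardised dosages.

    A(j,k) = mean over SNPs i of (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with p_i the sample ALT frequency and the mean taken over SNPs
    non-missing in both j and k.  Returns (A, per-pair SNP counts).
    """
    d = dosages.dosages
    p = dosages.allele_frequencies()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP reached GRM construction; filter first")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    obs = np.isfinite(z)
    z0 = np.where(obs, z, 0.0)
    counts = obs.astype(float) @ obs.astype(float).T
    if (counts == 0).any():
        raise ValueError("a sample pair shares no genotyped SNP")
    grm = (z0 @ z0.T) / counts
    return (grm + grm.T) / 2, counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Phenotype preprocessing


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    z_i = Phi^-1((r_i - c) / (n + 1 - 2c)) with c = 3/8 by default; ties get
    average ranks.  NaNs are preserved.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(values[ok], method="average")
    out[ok] = special.ndtri((ranks - offset) / (n + 1 - 2 * offset))
    return out


def preprocess_phenotype(
    raw: np.ndarray,
    covariates: np.ndarray | None = None,
    int_offset: float = 3.0 / 8.0,
) -> np.ndarray:
    """GWAS phenotype preprocessing: OLS residuals on covariates (intercept
    included), then rank-based inverse-normal transform of the residuals.

    Missing raw values stay missing; samples missing any covariate are also
    treated as missing.  Requires >= 3 non-missing values and a non-constant
    trait.
    """
    raw = np.asarray(raw, dtype=float)
    ok = np.isfinite(raw)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != raw.shape[0]:
            covariates = covariates.T
        ok &= np.isfinite(covariates).all(axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing phenotype values")
    y = raw[ok]
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    if covariates is None:
        resid = y - y.mean()
    else:
        X = np.column_stack([np.ones(ok.sum()), covariates[ok]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    out = np.full_like(raw, np.nan)
    out[ok] = inverse_normal_transform(resid, offset=int_offset)
    return out


def encode_haplotype(
    assignments: pd.DataFrame, reference_like_group: str
) -> pd.Series:
    """Encode haplogroup labels as a biallelic SNP dosage.

    The reference-like group (the one matching the reference-genome founder
    lineage) becomes homozygous reference (0); the other group homozygous
    alternate (2); UNASSIGNED becomes NaN and is excluded from tests.
    """
    if reference_like_group not in (REF_GROUP, ALT_GROUP):
        raise ValueError(f"unknown group {reference_like_group!r}")
    other = ALT_GROUP if reference_like_group == REF_GROUP else REF_GROUP
    mapping = {reference_like_group: 0.0, other: 2.0, UNASSIGNED: np.nan}
    return pd.Series(
        [mapping[label] for label in assignments["label"]],
        index=pd.Index(assignments["sample_id"], name="sample_id"),
        name="hap_dosage",
    )


# ---------------------------------------------------------------------------
# REML variance components and MLMA


@dataclasses.dataclass
class GRMEigen:
    """Cached spectral decomposition of a GRM (one per sample set)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @classmethod
    def from_grm(cls, grm: np.ndarray) -> "GRMEigen":
        vals, vecs = np.linalg.eigh(grm)
        if np.ptp(vals) < 1e-8:
            raise ValueError(
                "GRM is (a multiple of) the identity: sg2 and se2 are not "
                "separately identifiable"
            )
        return cls(eigenvalues=vals, eigenvectors=vecs)


def _reml_neg_ll(log_delta: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """-2 * restricted log-likelihood of V = sg2 (K + delta I), profiled over sg2."""
    delta = np.exp(log_delta)
    w = s + delta
    Xi = Xr / w[:, None]
    xtx = Xr.T @ Xi
    beta = np.linalg.solve(xtx, Xi.T @ yr)
    r = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(r @ (r / w))
    sg2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll2 = (
        (n - p) * np.log(sg2)
        + np.log(w).sum()
        + logdet_xtx
        + (n - p)
    )
    return ll2, sg2, beta


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    eig: GRMEigen,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
) -> tuple[float, float]:
    """REML estimates of (sg2, se2) for y = Xb + g + e with cov(g) = sg2*GRM.

    Works in the GRM eigenbasis: a single rotation turns V into a diagonal
    matrix parameterised by the ratio delta = se2/sg2, leaving a 1-D
    restricted-likelihood optimisation over log(delta).  The two boundary
    regimes (sg2 -> 0, se2 -> 0) are checked explicitly.  Estimates are
    nonnegative by construction.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    U, s = eig.eigenvectors, eig.eigenvalues
    yr = U.T @ y
    Xr = U.T @ X
    # clip tiny negative GRM eigenvalues from finite-SNP sampling noise
    s = np.maximum(s, 0.0)

    obj = lambda ld: _reml_neg_ll(ld, s, yr, Xr)[0]
    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, 21)
    vals = [obj(g) for g in grid]
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(a, b), method="bounded")
    best_ld = res.x if res.fun <= vals[k] else grid[k]
    _, sg2, _ = _reml_neg_ll(best_ld, s, yr, Xr)
    se2 = sg2 * np.exp(best_ld)
    # delta at the upper bound means essentially no genetic variance
    if best_ld >= hi - 1e-6:
        return 0.0, float(sg2 * np.exp(best_ld))
    return float(sg2), float(se2)


@dataclasses.dataclass
class MLMAResult:
    trait: str
    n: int
    beta: float
    se: float
    wald: float
    p: float
    sigma_g2: float
    sigma_e2: float
    flagged: str | None = None


def mlma_test(
    y: np.ndarray,
    x: np.ndarray,
    eig: GRMEigen,
    covariates: np.ndarray | None = None,
    variance_components: tuple[float, float] | None = None,
    trait: str = "",
) -> MLMAResult:
    """Test a single encoded variant against a trait by GLS with fixed V.

    ``y``, ``x`` and the GRM eigensystem must already be aligned to the same
    non-missing sample set.  Variance components default to REML estimates
    on the null model (covariates only) and are held fixed for the test, the
    usual MLMA convention.  The statistic is a 1-df Wald chi-square.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.shape[0]
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1)]
    )
    if np.ptp(x) == 0:
        return MLMAResult(trait, n, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, flagged="constant genotype")
    if variance_components is None:
        variance_components = reml_variance_components(y, X0, eig)
    sg2, se2 = variance_components

    U, s = eig.eigenvectors, eig.eigenvalues
    w = sg2 * np.maximum(s, 0.0) + se2
    w = np.maximum(w, 1e-12)
    D = np.column_stack([X0, x])
    Dr = U.T @ D
    yr = U.T @ y
    Di = Dr / w[:, None]
    xtx = Dr.T @ Di
    xty = Di.T @ yr
    beta = np.linalg.solve(xtx, xty)
    cov = np.linalg.inv(xtx)
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    wald = (b / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return MLMAResult(trait, n, b, se, wald, max(p, np.nextafter(0, 1)),
                      sg2, se2)


# ---------------------------------------------------------------------------
# Multiple testing and the binary-trait exact test


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min_{j >= i} m * p(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_one_sided(
    table: np.ndarray, direction: str = "greater"
) -> tuple[float, bool]:
    """One-sided Fisher's exact test on a 2x2 count table.

    Returns (p, degenerate) where ``degenerate`` marks a zero margin, for
    which p = 1 by convention.  ``direction`` refers to the association of
    the top-left cell ('greater': enrichment; 'less': depletion).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, True
    p = float(stats.fisher_exact(t, alternative=direction)[1])
    return p, False


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def linear_association(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Plain OLS slope, SE and two-sided p for y ~ x (+ covariates).

    The naive comparator to MLMA: no polygenic term, so confounding through
    relatedness inflates its test statistics.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        cols.append(np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1))
    X = np.column_stack(cols + [x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    p = float(2 * stats.t.sf(abs(b / se), dof))
    return b, se, p


# ---------------------------------------------------------------------------
# Tabular I/O for the GRM path


def write_dosage_tsv(dosages: DosageMatrix, path) -> None:
    """Samples x SNPs dosage table with a sample_id column; NaN = missing."""
    df = pd.DataFrame(dosages.dosages, columns=dosages.snp_ids)
    df.insert(0, "sample_id", dosages.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")


def read_dosage_tsv(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: dosage table needs a sample_id column")
    ids = df.pop("sample_id").astype(str).tolist()
    return DosageMatrix(
        sample_ids=ids,
        snp_ids=list(df.columns),
        dosages=df.to_numpy(dtype=float),
    )


def write_grm_tsv(grm: np.ndarray, sample_ids: list[str], path) -> None:
    """GRM as TSV with a sample-id sidecar (<path>.ids)."""
    np.savetxt(path, grm, delimiter="\t", fmt="%.8g")
    Path(str(path) + ".ids").write_text("\n".join(sample_ids) + "\n")
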