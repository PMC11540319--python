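"""Biallelic SNP genotype containers and VCF / metadata I/O.

Genotype calls are stored as a dense ``int8`` grid of samples x variants with
the encoding ``REF=0, HET=1, ALT=2, MISSING=-1``.  This is the natural shape
for hemizygous-chromosome work, where every downstream operation (allele
counting, consensus, Hamming distance) is a vectorised reduction over that
grid.

Hemizygous chromosomes (Y, MT) carry a single copy, so a heterozygous call is
biologically impossible and can only be a genotyping/imputation artifact;
:func:`mask_hemizygous_hets` converts every such call to MISSING.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Call codes (values of the VariantCall enumeration).
REF: int = 0
HET: int = 1
ALT: int = 2
MISSING: int = -1

CALL_NAMES = {REF: "REF", HET: "HET", ALT: "ALT", MISSING: "MISSING"}

#: Default INFO field carrying the imputation quality score.  Imputation
#: tools name this differently (STITCH emits ``INFO_SCORE``); configurable
#: everywhere it is consumed.
DEFAULT_INFO_KEY = "INFO_SCORE"

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info_score"]


class GenotypeIOError(RuntimeError):
    """Raised for unreadable/ill-formed genotype inputs."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x biallelic variants with calls in {REF, HET, ALT, MISSING}.

    Attributes
    ----------
    sample_ids:
        Ordered, unique sample identifiers (rows of ``calls``).
    variants:
        One row per variant: ``chrom``, 1-based ``pos``, ``id``, ``ref``,
        ``alt`` alleles and ``info_score`` (NaN when absent).  Sorted by
        position within chromosome.
    calls:
        ``int8`` array of shape ``(n_samples, n_variants)``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(
        self,
        samples: Sequence[int] | np.ndarray | None = None,
        variants: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given positional indices/masks."""
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        v_idx = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        if v_idx.dtype == bool:
            v_idx = np.flatnonzero(v_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s_idx],
            variants=self.variants.iloc[v_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(s_idx, v_idx)].copy(),
        )

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def _decode_gt(gt: list) -> int:
    """Map a cyvcf2 genotype entry (alleles + trailing phased flag) to a call."""
    alleles = gt[:-1]  # last element is the phased bool
    if len(alleles) == 1:  # haploid GT
        a = alleles[0]
        if a < 0:
            return MISSING
        return REF if a == 0 else ALT
    a, b = alleles[0], alleles[1]
    if a < 0 or b < 0:
        return MISSING
    if a == 0 and b == 0:
        return REF
    if a == 1 and b == 1:
        return ALT
    return HET


def read_vcf(
    path: str | Path,
    chromosome: str | None = None,
    info_key: str = DEFAULT_INFO_KEY,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes for one chromosome from a VCF.

    Diploid GTs map 0/0->REF, 0/1 or 1/0->HET, 1/1->ALT, ./.->MISSING; haploid
    GTs map 0->REF, 1->ALT.  Sites with more than one ALT allele are dropped
    (and counted in the log): the analysis is defined on biallelic SNPs only.

    Parameters
    ----------
    chromosome:
        Restrict to this chromosome label; ``None`` keeps all records (they
        must then be sorted by position within each chromosome).
    info_key:
        INFO field parsed into the per-variant imputation quality score.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such VCF: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions for bad files
        raise GenotypeIOError(f"unreadable VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    n_seen = 0
    for rec in vcf:
        if chromosome is not None and rec.CHROM != chromosome:
            continue
        n_seen += 1
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        score = rec.INFO.get(info_key)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.ID or ".",
                rec.REF,
                rec.ALT[0],
                float(score) if score is not None else np.nan,
            )
        )
        columns.append(
            np.array([_decode_gt(g) for g in rec.genotypes], dtype=np.int8)
        )
    vcf.close()

    if chromosome is not None and n_seen == 0:
        raise GenotypeIOError(f"chromosome {chromosome!r} absent from {path}")
    if not rows:
        raise GenotypeIOError(
            f"no biallelic sites in {path}"
            + (f" on chromosome {chromosome!r}" if chromosome else "")
        )
    if n_multiallelic:
        logger.info("dropped %d multiallelic site(s) from %s", n_multiallelic, path)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = np.stack(columns, axis=1)
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


_GT_STRINGS = {REF: "0/0", HET: "0/1", ALT: "1/1", MISSING: "./."}
_GT_STRINGS_HAPLOID = {REF: "0", ALT: "1", MISSING: "."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    info_key: str = DEFAULT_INFO_KEY,
    haploid: bool = False,
) -> None:
    """Write a :class:`GenotypeMatrix` as VCF v4.2 (1-based positions).

    With ``haploid=True`` calls are written as single-allele GTs; HET calls
    cannot be represented and raise.
    """
    path = Path(path)
    gt_map = _GT_STRINGS_HAPLOID if haploid else _GT_STRINGS
    if haploid and (matrix.calls == HET).any():
        raise ValueError("cannot write HET calls with haploid=True")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(matrix.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            f'##INFO=<ID={info_key},Number=1,Type=Float,'
            'Description="Imputation INFO score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, var in enumerate(matrix.variants.itertuples(index=False)):
            info = (
                f"{info_key}={var.info_score:.6g}"
                if np.isfinite(var.info_score)
                else "."
            )
            gts = "\t".join(gt_map[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}\t.\t.\t"
                f"{info}\tGT\t{gts}\n"
            )


def mask_hemizygous_hets(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Convert every HET call to MISSING on a hemizygous chromosome.

    The caller asserts hemizygosity; a single-copy chromosome cannot be
    heterozygous, so observed HETs are treated as missing data.  Returns the
    masked matrix and the number of converted calls.  Idempotent.
    """
    het = matrix.calls == HET
    masked = matrix.calls.copy()
    masked[het] = MISSING
    out = GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variants=matrix.variants.copy(),
        calls=masked,
    )
    return out, int(het.sum())


SEXES = ("male", "female", "unknown")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, sex, birth_date, library_prep).

    ``sex`` values outside {male, female} become ``unknown``.  Missing
    optional columns are added as NA.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise GenotypeIOError(f"{path}: sample metadata needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeIOError(f"{path}: duplicate sample ids {dupes}")
    for col in ("sex", "birth_date", "library_prep"):
        if col not in meta.columns:
            meta[col] = pd.NA
    meta["sex"] = meta["sex"].where(meta["sex"].isin(["male", "female"]), "unknown")
    return meta[["sample_id", "sex", "birth_date", "library_prep"]]


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
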