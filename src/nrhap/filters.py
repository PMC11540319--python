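"""Ordered genotype filter cascade for low-coverage imputed data.

Four stages are applied in a fixed order -- INFO score, zero minor allele
frequency, per-SNP missing rate, per-sample missing rate -- with any subset
of stages enabled.  The order matters: per-SNP and per-sample missing rates
are computed on the *current* matrix, i.e. after whatever earlier stages
removed, so enabling or reordering stages changes the result (see the tests
for an explicit order-dependence fixture).

Rate thresholds are strict: a SNP missing in exactly 25% of samples survives
a ``max_snp_missing=0.25`` stage, because the rule removes rates *greater
than* the threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .genotype_io import ALT, HET, MISSING, REF, GenotypeMatrix

STAGE_ORDER = ("INFO", "MAF", "SNP_MISSING", "SAMPLE_MISSING")

#: comparisons against a threshold that round-trips through float32 (cyvcf2
#: stores INFO values as float32) must not drop values written exactly at it
_INFO_EPS = 1e-6


class EmptyResultError(RuntimeError):
    """All variants or all samples removed; names the offending stage."""

    def __init__(self, stage: str, axis: str):
        self.stage = stage
        super().__init__(f"filter stage {stage} removed every {axis}")


@dataclasses.dataclass
class FilterConfig:
    """Thresholds and stage toggles for :func:`apply_filter_cascade`.

    ``info_min`` must be given explicitly when replicating published filter
    counts; the default mirrors common low-coverage imputation practice.
    """

    info_min: float = 0.9
    drop_maf_zero: bool = True
    max_snp_missing: float = 0.25
    max_sample_missing: float = 0.50
    stages_enabled: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        for name, val in (
            ("info_min", self.info_min),
            ("max_snp_missing", self.max_snp_missing),
            ("max_sample_missing", self.max_sample_missing),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        unknown = set(self.stages_enabled) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        # stage order is immutable: normalise whatever subset was given
        self.stages_enabled = tuple(
            s for s in STAGE_ORDER if s in self.stages_enabled
        )


@dataclasses.dataclass
class StageReport:
    stage: str
    examined: int
    removed: int
    threshold: float | None


@dataclasses.dataclass
class FilterReport:
    """Per-stage audit of a cascade run."""

    stages: list[StageReport]
    input_shape: tuple[int, int]  # (samples, variants)
    output_shape: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "examined": s.examined,
                    "removed": s.removed,
                    "threshold": s.threshold,
                }
                for s in self.stages
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def snp_missing_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a MISSING call, per variant."""
    return (matrix.calls == MISSING).mean(axis=0)


def sample_missing_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of variants with a MISSING call, per sample."""
    return (matrix.calls == MISSING).mean(axis=1)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant MAF from non-missing calls.

    Hemizygous-style accounting: REF and ALT calls contribute one allele
    each; a HET (possible on non-hemizygous chromosomes) contributes one REF
    and one ALT allele.  Variants with every call MISSING get NaN.
    """
    calls = matrix.calls
    n_ref = (calls == REF).sum(axis=0) * 2 + (calls == HET).sum(axis=0)
    n_alt = (calls == ALT).sum(axis=0) * 2 + (calls == HET).sum(axis=0)
    total = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, n_alt / np.maximum(total, 1), np.nan)
    return np.minimum(freq, 1.0 - freq)


def apply_filter_cascade(
    matrix: GenotypeMatrix, config: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the enabled stages in the fixed order INFO -> MAF -> SNP_MISSING ->
    SAMPLE_MISSING, each on the output of the previous one.

    Returns the filtered matrix and a :class:`FilterReport` whose removals
    are conserved: input dims minus removals equal output dims stage by
    stage.  Raises :class:`EmptyResultError` if a stage empties the matrix.
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("empty input matrix")

    current = matrix
    stages: list[StageReport] = []

    for stage in config.stages_enabled:
        if stage == "INFO":
            scores = current.variants["info_score"].to_numpy(dtype=float)
            # variants with no score are kept (the filter targets scored,
            # low-quality imputations)
            keep = ~(scores < config.info_min - _INFO_EPS)
            stages.append(
                StageReport("INFO", current.n_variants,
                            int((~keep).sum()), config.info_min)
            )
            current = _drop_variants(current, keep, stage)
        elif stage == "MAF":
            maf = minor_allele_frequency(current)
            # all-MISSING variants have undefined MAF; removed here
            # deterministically when this stage runs
            keep = maf > 0
            keep &= ~np.isnan(maf)
            stages.append(
                StageReport("MAF", current.n_variants, int((~keep).sum()), 0.0)
            )
            current = _drop_variants(current, keep, stage)
        elif stage == "SNP_MISSING":
            rate = snp_missing_rate(current)
            keep = rate <= config.max_snp_missing
            stages.append(
                StageReport("SNP_MISSING", current.n_variants,
                            int((~keep).sum()), config.max_snp_missing)
            )
            current = _drop_variants(current, keep, stage)
        elif stage == "SAMPLE_MISSING":
            rate = sample_missing_rate(current)
            keep = rate <= config.max_sample_missing
            stages.append(
                StageReport("SAMPLE_MISSING", current.n_samples,
                            int((~keep).sum()), config.max_sample_missing)
            )
            if not keep.any():
                raise EmptyResultError(stage, "sample")
            current = current.subset(samples=keep)

    report = FilterReport(
        stages=stages,
        input_shape=(matrix.n_samples, matrix.n_variants),
        output_shape=(current.n_samples, current.n_variants),
    )
    return current, report


def _drop_variants(matrix: GenotypeMatrix, keep: np.ndarray, stage: str) -> GenotypeMatrix:
    if not keep.any():
        raise EmptyResultError(stage, "variant")
    if keep.all():
        return matrix
    return matrix.subset(variants=keep)
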