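"""Haplogroup assignment for nonrecombinant chromosomes.

A nonrecombinant chromosome (Y or MT) is inherited whole from one parent, so
in a population descended from a small founder panel every sample carries an
(almost) exact copy of one founder haplotype.  When the observed haplotypes
fall into two clusters -- one carrying mostly reference alleles relative to
the reference genome, one mostly alternate -- each sample can be assigned by
simply counting its reference vs alternate calls: the strict majority decides
the group, and an exact tie leaves the sample unassigned rather than
arbitrarily labelled.

From the assignments a per-group consensus haplotype (modal non-missing call
per site) is built, matched against the founder panel by Hamming distance
(ignoring missingness), and each sample's residual variation relative to its
own group consensus is tabulated.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd

from .genotype_io import ALT, MISSING, REF, GenotypeMatrix

REF_GROUP = "REF_GROUP"
ALT_GROUP = "ALT_GROUP"
UNASSIGNED = "UNASSIGNED"


def count_alleles(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample (n_ref, n_alt, n_missing) counts over all variants.

    The matrix must already be hemizygous-masked (no HET calls); counts then
    partition the variant set for every sample.
    """
    if (matrix.calls == 1).any():
        raise ValueError("matrix contains HET calls; mask hemizygous hets first")
    n_ref = (matrix.calls == REF).sum(axis=1)
    n_alt = (matrix.calls == ALT).sum(axis=1)
    n_missing = (matrix.calls == MISSING).sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "n_ref": n_ref,
            "n_alt": n_alt,
            "n_missing": n_missing,
        }
    )


def assign_haplogroups(counts: pd.DataFrame) -> pd.DataFrame:
    """Label each sample by strict majority of its allele counts.

    REF_GROUP iff n_ref > n_alt, ALT_GROUP iff n_alt > n_ref, else
    UNASSIGNED (ties, including all-missing samples).  Unassigned samples
    take no part in consensus building or association testing.
    """
    label = np.where(
        counts["n_ref"] > counts["n_alt"],
        REF_GROUP,
        np.where(counts["n_alt"] > counts["n_ref"], ALT_GROUP, UNASSIGNED),
    )
    out = counts.copy()
    out.insert(1, "label", label)
    return out


def consensus_genotypes(
    matrix: GenotypeMatrix, assignments: pd.DataFrame, group: str
) -> np.ndarray:
    """Modal non-MISSING call per variant among the group's members.

    Returns an int8 vector over {REF, ALT, MISSING}; a site is MISSING when
    no member has a call or REF and ALT are exactly tied.
    """
    members = assignments.loc[assignments["label"] == group, "sample_id"]
    if members.empty:
        raise ValueError(f"no samples assigned to group {group!r}")
    idx = [matrix.sample_index(s) for s in members]
    sub = matrix.calls[idx, :]
    n_ref = (sub == REF).sum(axis=0)
    n_alt = (sub == ALT).sum(axis=0)
    consensus = np.full(matrix.n_variants, MISSING, dtype=np.int8)
    consensus[n_ref > n_alt] = REF
    consensus[n_alt > n_ref] = ALT
    return consensus


def consensus_divergence(consensus_a: np.ndarray, consensus_b: np.ndarray) -> int:
    """Number of sites where two consensuses differ, counting only sites
    non-MISSING in both."""
    both = (consensus_a != MISSING) & (consensus_b != MISSING)
    return int((consensus_a[both] != consensus_b[both]).sum())


@dataclasses.dataclass
class FounderMatch:
    """Best-founder report for one consensus haplotype.

    ``distances`` maps founder id -> (mismatches, comparable sites); founders
    with zero comparable sites are listed in ``incomparable``.  Ties are
    flagged, never silently broken.
    """

    group: str
    best: list[str]
    distances: dict[str, tuple[int, int]]
    incomparable: list[str]
    tie: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": self.group,
                "founder": f,
                "mismatches": d[0],
                "comparable_sites": d[1],
                "distance": d[0] / d[1] if d[1] else np.nan,
                "best": f in self.best,
            }
            for f, d in self.distances.items()
        ]
        return pd.DataFrame(rows)


def match_founders(
    consensus: np.ndarray,
    founder_panel: GenotypeMatrix,
    group: str = "",
) -> FounderMatch:
    """Match a consensus haplotype to founders by Hamming distance.

    Distance ignores sites MISSING in either the consensus or the founder.
    The panel must share the consensus's variant set (the caller intersects
    beforehand if needed).
    """
    if founder_panel.n_variants != len(consensus):
        raise ValueError(
            "founder panel and consensus cover different variant sets; "
            "intersect them first"
        )
    distances: dict[str, tuple[int, int]] = {}
    incomparable: list[str] = []
    for i, founder in enumerate(founder_panel.sample_ids):
        hap = founder_panel.calls[i]
        both = (hap != MISSING) & (consensus != MISSING)
        n_comp = int(both.sum())
        if n_comp == 0:
            incomparable.append(founder)
            continue
        mism = int((hap[both] != consensus[both]).sum())
        distances[founder] = (mism, n_comp)
    if not distances:
        raise ValueError("no founder shares a called site with the consensus")
    best_d = min(m / c for m, c in distances.values())
    best = sorted(f for f, (m, c) in distances.items() if m / c == best_d)
    return FounderMatch(
        group=group,
        best=best,
        distances=distances,
        incomparable=incomparable,
        tie=len(best) > 1,
    )


def intragroup_variation(
    matrix: GenotypeMatrix, assignments: pd.DataFrame, consensus: np.ndarray, group: str
) -> tuple[pd.DataFrame, Counter]:
    """Per-sample mismatch count against the sample's own group consensus.

    Mismatches are counted only at sites called (non-MISSING) in both the
    sample and the consensus, so masking a site can never increase a count.
    Returns the per-sample table and a histogram Counter {count: n_samples}.
    """
    members = assignments.loc[assignments["label"] == group, "sample_id"].tolist()
    idx = [matrix.sample_index(s) for s in members]
    sub = matrix.calls[idx, :]
    comparable = (sub != MISSING) & (consensus != MISSING)[None, :]
    mismatch = comparable & (sub != consensus[None, :])
    counts = mismatch.sum(axis=1)
    table = pd.DataFrame(
        {
            "sample_id": members,
            "mismatches": counts,
            "comparable_sites": comparable.sum(axis=1),
        }
    )
    return table, Counter(counts.tolist())
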