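"""Unrooted neighbor-joining tree of the founder haplotypes.

Computes pairwise Hamming distances (ignoring missingness) between founder
haplotypes, builds the NJ tree, writes Newick + distance TSV, and verifies
that a single internal edge separates the two haplogroups.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import COHORT_DIR, cohort_config

from nrhap.cli import run_subcommand
from nrhap.haplotyping import ALT_GROUP, REF_GROUP


def main() -> None:
    cfg = cohort_config()
    run_subcommand("tree", cfg)

    dist = pd.read_csv(COHORT_DIR / "founder_distances.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(COHORT_DIR / "founder_groups.tsv", sep="\t")
    newick = (COHORT_DIR / "founder_tree.nwk").read_text().strip()
    print("founder Hamming distances (fraction of comparable sites):")
    print(dist.round(3).to_string())
    print(f"\nNJ tree: {newick}")

    g1 = groups.loc[groups["group"] == REF_GROUP, "founder"].tolist()
    g2 = groups.loc[groups["group"] == ALT_GROUP, "founder"].tolist()
    within = max(
        dist.loc[a, b] for grp in (g1, g2) for a in grp for b in grp if a != b
    )
    between = min(dist.loc[a, b] for a in g1 for b in g2)
    print(
        f"max within-group distance {within:.3f} < "
        f"min between-group distance {between:.3f}: "
        f"{'yes' if within < between else 'NO'}"
    )


if __name__ == "__main__":
    main()
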