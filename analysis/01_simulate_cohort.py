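"""Generate the synthetic study cohort.

Writes founder panel, low-coverage population genotypes (VCF), autosomal
dosages, truth tables, phenotypes and expression counts under
results/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import COHORT_DIR, cohort_config

from nrhap.cli import run_subcommand


def main() -> None:
    cfg = cohort_config()
    manifest = run_subcommand("simulate", cfg)
    dims = manifest.stages["simulate"]
    print(
        f"simulated {dims['founders']} founders x {dims['sites']} sites, "
        f"{dims['samples']} modern samples, {dims['autosomal_snps']} autosomal "
        f"SNPs, {dims['traits']} traits, {dims['genes']} genes"
    )
    print(f"artifacts in {COHORT_DIR}")


if __name__ == "__main__":
    main()
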