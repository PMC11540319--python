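"""Shared configuration for the analysis drivers.

One synthetic cohort emulating the study design: 8 founders in two
haplogroups, a 2,000-rat modern population carrying whole founder
haplotypes observed through low-coverage imputation noise, full-sib family
structure on the autosomes with haplogroup nested in family (confounding),
20 polygenic null phenotypes and a 200-gene expression panel with two
planted haplotype-linked DE genes and one male-specific gene.
"""

from pathlib import Path

from nrhap.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"

SEED = 20240901


def cohort_config() -> PipelineConfig:
    return PipelineConfig.load(
        None,
        seed=SEED,
        output_dir=str(COHORT_DIR),
        simulate={
            "founders": {"n_sites": 5000, "d_between": 4000, "d_within": 10},
            "population": {"n_samples": 2000},
            "autosomes": {"n_snps": 2000, "sibship_size": 4, "confound": True},
            "phenotypes": {"n_traits": 20, "heritability": 0.5, "hap_effect": 0.0},
            "expression": {
                "n_genes": 200,
                "de_genes": {10: 2.0, 25: 0.5},
                "male_specific_genes": [40],
            },
        },
    )
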