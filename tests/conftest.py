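import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nrhap.genotype_io import GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(calls, sample_ids=None, info_scores=None, chrom="Y") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1),
            "id": [f"v{j + 1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "info_score": info_scores if info_scores is not None else np.nan,
        }
    )
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, calls=calls)


@pytest.fixture
def small_vcf(tmp_path):
    """Plain-text VCF: 2 samples x 4 sites incl. haploid, missing and a
    multiallelic record."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=Y>
##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation INFO score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
Y\t100\t.\tA\tG\t.\t.\tINFO_SCORE=0.95\tGT\t0/0\t0/1
Y\t200\t.\tC\tT\t.\t.\tINFO_SCORE=0.5\tGT\t1\t0
Y\t300\t.\tG\tA\t.\t.\t.\tGT\t./.\t1/1
Y\t400\t.\tG\tA,T\t.\t.\tINFO_SCORE=0.8\tGT\t1/1\t2/2
"""
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path
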