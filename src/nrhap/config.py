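"""Structured pipeline configuration (YAML) and run manifests.

One config file drives every stage so a run is auditable from a single
document; the manifest records the config hash, package version and the
dimensions flowing through each stage.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from . import __version__

DEFAULTS: dict[str, Any] = {
    "seed": 42,
    "output_dir": "nrhap_out",
    "simulate": {
        "founders": {
            "n_founders": 8,
            "n_sites": 5000,
            "group_split": [3, 5],
            "d_between": 4000,
            "d_within": 10,
            "chromosome": "Y",
        },
        "population": {
            "n_samples": 2000,
            # post-imputation missingness: modest, so the published cascade
            # thresholds (25% per SNP, 50% per sample) bite but do not empty
            # the matrix; the high-missingness stress band is exercised by
            # the recovery checks instead
            "missing_rate_mean": 0.15,
            "missing_rate_sd": 0.08,
            "het_error_rate": 0.01,
            "info_beta": [9.0, 1.0],
            "female_fraction": 0.0,
        },
        "autosomes": {"n_snps": 2000, "sibship_size": 4, "confound": True},
        "phenotypes": {
            "n_traits": 20,
            "heritability": 0.5,
            "hap_effect": 0.0,
            "covariate_effects": [],
        },
        "expression": {
            "n_genes": 200,
            "baseline_log_mean": 4.0,
            "dispersion": 0.1,
            "de_genes": {},
            "male_specific_genes": [],
            "library_size_range": [0.8, 1.2],
        },
    },
    "filters": {
        "haplotype": {
            "info_min": 0.9,
            "max_snp_missing": 0.25,
            "max_sample_missing": 0.50,
            "stages_enabled": ["INFO", "MAF", "SNP_MISSING", "SAMPLE_MISSING"],
        },
        "consensus": {
            # MAF skipped so newly fixed variants stay visible
            "info_min": 0.9,
            "stages_enabled": ["INFO", "SNP_MISSING", "SAMPLE_MISSING"],
        },
    },
    "association": {
        "reference_like_group": "REF_GROUP",
        "fdr_level": 0.05,
        "info_key": "INFO_SCORE",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclasses.dataclass
class PipelineConfig:
    raw: dict[str, Any]

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        merged = _merge(_merge(DEFAULTS, data), overrides)
        fdr = merged["association"]["fdr_level"]
        if not 0 < fdr < 1:
            raise ValueError(f"association.fdr_level={fdr} must lie in (0, 1)")
        return cls(raw=merged)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance for one pipeline run; one JSON file per invocation."""

    config_hash: str
    stages: dict[str, Any] = dataclasses.field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, **dims) -> None:
        self.stages[stage] = dims

    def write(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config_hash": self.config_hash,
            "timestamp": datetime.datetime.now(datetime.UTC).isoformat(),
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
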