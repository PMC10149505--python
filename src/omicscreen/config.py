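"""Pipeline configuration: every analysis threshold in one place.

Defaults are the values used throughout the analysis; a YAML file can
override any subset.  Each pipeline run logs the fully resolved mapping so
that results are traceable to the thresholds that produced them.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("omicscreen")

DEFAULT_CONFIG: dict[str, Any] = {
    "de": {
        "alpha": 0.05,
        # tumor/BPH fold-change gates per layer (up, down)
        "proteome_fc": [1.2, 1 / 1.2],
        "surfaceome_fc": [1.2, 1 / 1.2],
        "transcriptome_fc": [1.5, 1 / 1.5],
        "test": "wilcoxon",  # or "ttest"
        "bh_correction": False,
    },
    "qc": {
        "dip_alpha": 0.05,
        "dip_n_boot": 1000,
        "reference_corr_threshold": 0.97,
    },
    "impute": {
        "k": 10,
        "max_missing_frac": 0.2,
    },
    "screen": {
        "n_doses": 7,
        "dilution_factor": 10.0,
        # 7-AA orientation: "resistance" reads 7-AA as n_doses - AA
        # (larger = more resistant); "activity" reads it as AA itself.
        "aa_orientation": "resistance",
        "selectivity_alpha": 0.05,
    },
    "assoc": {
        "alpha": 0.05,
        "max_missing_frac": 0.5,
        "min_pairs": 5,
        "bh_correction": False,
    },
    "gsea": {
        "weight": 1.0,
        "n_perm": 1000,
        "fdr_threshold": 0.05,
        "metric": "signed_logp",  # sign(log2FC) * -log10(p)
    },
    "synergy": {
        "ci_synergy": 0.9,
        "ci_antagonism": 1.1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the resolved configuration, optionally overridden from YAML."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with Path(path).open() as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"{path}: config must be a mapping")
        config = _merge(config, override)
    return config


def log_config(config: dict[str, Any]) -> None:
    logger.info("resolved config: %s", json.dumps(config, sort_keys=True))


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
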