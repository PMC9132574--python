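"""Default configuration and YAML loading."""

from __future__ import annotations

import copy
from typing import Any, Dict, Optional

import yaml

#: terms whose presence in a free-text annotation marks it as "unknown
#: function" (case-insensitive substring match); configurable via YAML
DEFAULT_UNKNOWN_TERMS = (
    "hypothetical",
    "uncharacterized",
    "unknown function",
    "DUF",
    "putative",
    "predicted protein",
    "conserved protein of unknown",
)

DEFAULTS: Dict[str, Any] = {
    "unknown_terms": list(DEFAULT_UNKNOWN_TERMS),
    "duf_accessions": [],
    "min_cluster_size": 10,
    "shadow": {"opposite_strand_bp": 60, "same_strand_frac": 0.5},
    "shadow_discard_fraction": 0.30,
    "msa_outlier_floor": 0.8,
    "broken_stick": {"method": "closed_form", "n_iter": 100, "seed": 0},
    "homolog_log_fraction": 0.6,
    "vote_weight_by_bitscore": False,
    "consensus_incomplete_weight": 0.5,
    "hq_min_complete_fraction": 1.0 / 3.0,
    "da_cosine_max_distance": 0.9,
    "da_collapse_complete_fraction": 0.75,
    "refinement": {"min_probability": 0.90, "min_target_cov": 0.60},
    "communities": {
        "min_probability": 0.5,
        "min_coverage": 0.6,
        "rescue_min_probability": 0.5,
        "rescue_min_coverage": 0.4,
        "inflation_grid": [round(1.2 + 0.1 * i, 1) for i in range(19)],
        "mcl_prune": 1e-5,
        "mcl_tol": 1e-8,
        "mcl_max_iter": 200,
    },
    "ecology": {
        "min_mean_abundance": 1e-5,
        "n_random_datasets": 10,
        "n_null": 100,
        "count_scale": 1_000_000,
        "min_group_size": 3,
    },
    "phylo": {
        "f1_threshold": 0.95,
        "max_prevalence": 0.5,
        "min_genomes": 2,
        "consentrait_threshold": 0.9,
    },
}


def _deep_update(base: Dict[str, Any], extra: Dict[str, Any]) -> Dict[str, Any]:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: Optional[str] = None) -> Dict[str, Any]:
    """Return the default config, optionally overlaid with a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        _deep_update(cfg, user)
    return cfg
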