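"""Run configuration: one YAML file mirroring every tunable threshold.

Defaults are the values used throughout the analysis; a YAML file may
override any subset.  ``load_config`` returns the fully resolved mapping so
runs can log exactly what they used.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    # identification-quality filter
    "min_fragment_run": 4,          # >=4 consecutive b- or y-ions
    "strict_fragment_evidence": False,  # drop peptides lacking evidence
    # presence / missingness gates
    "min_samples_per_group": 3,     # >=3 samples per group
    "max_missing_fraction": 0.20,   # strict <20% per group for ROC/UMAP export
    # differential calling
    "p_threshold": 0.05,
    "fc_threshold": 2.0,            # up: ratio > 2; down: ratio < 0.5
    "test_method": "t",             # t | wilcoxon | anova
    "welch": True,                  # unequal-variance t-test
    "use_bh": False,                # BH column computed, not used for calling
    "fc_cap": 1024.0,               # cap for ratios against a zero mean
    # grouped aa-score
    "bond_assignment": "internal",  # internal {s..e-1} | inclusive {s-1..e}
    "stable_min_members": 2,
    "require_nonzero_step": True,   # transition points need a non-zero step
    "severity_epsilon": 0.0,        # tolerance for strict monotone trends
    # biomarker selection
    "auc_threshold": 0.90,
    "min_cluster_members": 2,
    # PRM
    "q_value_cutoff": 0.01,
    "reference_mean": "arithmetic",  # arithmetic | geometric
    "min_reference_detections": 1,
    # normalization
    "zero_is_missing": False,
    "row_scaling": "mean100",       # mean100 | max100
}


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Resolve the run configuration from defaults, YAML file and overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
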