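"""Pipeline configuration: defaults, validation and YAML loading.

Default thresholds match the analysis they reproduce (coverage filters
3 / 99.95th percentile, 100-bp bins, q < 0.05 with |diff| > 10%, +/-5 kb TSS
proximity, 1000 bootstrap iterations, 70/30 split with 10-fold CV over 200
lambdas on [e^-7, e^-2], probability cutoff 0.8).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # stage toggles
    simulate: bool = True
    run_binning: bool = True
    run_dmr: bool = True
    run_annotate: bool = True
    run_compare: bool = True
    run_validate: bool = True
    run_signature: bool = True
    # analysis thresholds
    min_cov: int = 3
    high_pct: float = 99.95
    bin_size: int = 100
    q_threshold: float = 0.05
    diff_threshold: float = 0.10
    proximal_bp: int = 5000
    n_boot: int = 1000
    train_frac: float = 0.7
    folds: int = 10
    n_lambda: int = 200
    lambda_min: float = math.exp(-7)
    lambda_max: float = math.exp(-2)
    cutoff: float = 0.8
    destrand: bool = True
    use_donor_covariate: bool = True
    # simulation parameters
    sim: dict = field(default_factory=dict)
    sim_array: dict = field(default_factory=dict)
    # paths (used when simulate is off)
    calls_dir: str | None = None
    sample_sheet: str | None = None
    annotation_dir: str | None = None
    beta_matrix: str | None = None
    manifest: str | None = None
    array_sample_sheet: str | None = None
    # seeds per stage
    seed: int = 0

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_RANGE_CHECKS = [
    ("min_cov", lambda v: v >= 0, "must be >= 0"),
    ("high_pct", lambda v: 0 < v <= 100, "must be in (0, 100]"),
    ("bin_size", lambda v: v > 0, "must be positive"),
    ("q_threshold", lambda v: 0 < v, "must be positive"),
    ("diff_threshold", lambda v: v >= 0, "must be non-negative"),
    ("proximal_bp", lambda v: v >= 0, "must be non-negative"),
    ("n_boot", lambda v: v > 0, "must be positive"),
    ("train_frac", lambda v: 0 < v < 1, "must be in (0, 1)"),
    ("folds", lambda v: v >= 2, "must be >= 2"),
    ("n_lambda", lambda v: v >= 2, "must be >= 2"),
    ("lambda_min", lambda v: v > 0, "must be positive"),
    ("cutoff", lambda v: 0 < v < 1, "must be in (0, 1)"),
]


def validate_config(raw: dict | PipelineConfig | None) -> tuple[PipelineConfig | None, list[str]]:
    """Fill defaults and validate; returns (config, errors).

    ``config`` is None when errors are present.  Unknown keys and
    out-of-range values are reported with field names.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, PipelineConfig):
        cfg = raw
        errors: list[str] = []
    else:
        known = set(PipelineConfig.__dataclass_fields__)
        errors = [f"unknown config key: {k}" for k in raw if k not in known]
        try:
            cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
        except TypeError as exc:
            return None, errors + [str(exc)]
    for name, check, msg in _RANGE_CHECKS:
        v = getattr(cfg, name)
        try:
            ok = check(v)
        except TypeError:
            ok = False
        if not ok:
            errors.append(f"{name}={v!r}: {msg}")
    if cfg.lambda_max <= cfg.lambda_min:
        errors.append("lambda_max must exceed lambda_min")
    if errors:
        return None, errors
    return cfg, []


def load_config(path: str | Path | None) -> tuple[PipelineConfig | None, list[str]]:
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        return None, ["config file must contain a mapping"]
    return validate_config(raw)
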