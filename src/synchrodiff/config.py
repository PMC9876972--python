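"""Pipeline configuration: defaults, YAML loading and full validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters with their canonical defaults."""

    seed: int = 0
    out_dir: str = "synchrodiff_run"

    # core / signal extraction
    merge_gap: int = 40
    chip_extend: int = 316
    atac_extend: int = 140
    mapq_min_chip: int = 10
    mapq_min_atac: int = 5

    # differential accessibility
    n_bins: int = 31
    n_basis: int = 10
    var_fraction: float = 0.95
    fc_threshold: float = 2.0
    p_adj_threshold: float = 1e-4
    log_base: float = 2.718281828459045

    # footprints
    flank: int = 25
    flr_min: float = 10.0
    ps_min: float = 0.0
    min_footprints_per_pwm: int = 50
    expression_min: float = 1.0
    min_matches: int = 100

    # regression
    regress_fc_min: float = 1.5
    regress_fc_max: float = 10.0
    regress_min_footprints: int = 15
    regress_min_regions_hit: int = 10

    # chromatin state
    gtest_window: int = 1000
    gtest_step: int = 100
    gtest_fc_min: float = 2.0
    gtest_alpha: float = 0.01
    se_threshold: int = 3000

    # expression clustering
    k_min: int = 2
    k_max: int = 8
    n_init: int = 10

    # simulation scale (desk defaults)
    sim_chrom_length: int = 200_000
    sim_n_regions: int = 60
    sim_n_genes: int = 300

    def to_dict(self) -> dict:
        return asdict(self)


_POSITIVE = {
    "merge_gap", "chip_extend", "atac_extend", "n_bins", "n_basis",
    "fc_threshold", "p_adj_threshold", "flank", "flr_min",
    "min_footprints_per_pwm", "expression_min", "min_matches",
    "regress_fc_min", "regress_fc_max", "gtest_window", "gtest_step",
    "gtest_fc_min", "gtest_alpha", "se_threshold", "k_min", "k_max",
    "n_init", "sim_chrom_length", "sim_n_regions", "sim_n_genes",
    "var_fraction", "log_base",
}


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config, reporting every error at once.

    An empty/missing file yields the all-defaults config; unknown keys,
    type mismatches and non-positive values for positive-only keys are all
    collected into a single error message.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a key-value mapping")
            data = loaded
    if overrides:
        data.update(overrides)

    known = {f.name: f.type for f in fields(PipelineConfig)}
    errors = []
    clean = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"unknown key: {key}")
            continue
        default = getattr(PipelineConfig(), key)
        try:
            coerced = type(default)(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected {type(default).__name__}, got {value!r}")
            continue
        if key in _POSITIVE and coerced <= 0:
            errors.append(f"{key}: must be positive, got {coerced}")
            continue
        clean[key] = coerced
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(**clean)


def write_resolved(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
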