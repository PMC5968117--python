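"""Run configuration: one YAML file drives the end-to-end workflow.

Validation reports every problem at once rather than stopping at the first,
so a config can be repaired in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

STAGES = ("screen", "tree", "clades", "motifs", "de", "regulons")


@dataclass
class Comparison:
    """One wild-type vs TF-mutant contrast on a single carbon source."""

    tf: str
    wt_strain: str
    mutant_strain: str
    carbon_source: str


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # input paths (only those needed by enabled stages are required)
    proteome: str | None = None
    reference_labels: str | None = None
    reference_alignment: str | None = None
    alignment: str | None = None
    outgroup: str | None = None
    tree: str | None = None
    motif_table: str | None = None
    expression: str | None = None
    samples: str | None = None
    st_list: str | None = None
    hmmer_table: str | None = None
    comparisons: list[Comparison] = field(default_factory=list)
    # thresholds; defaults are the study's printed parameters
    cutoff: float | None = None  # None -> calibrate from references
    max_gap_fraction: float = 0.20
    bootstrap: int = 500
    min_support: int = 60
    min_branch_length: float = 0.02
    fc: float = 1.5
    adj_p: float = 0.01
    floor: float = 50.0
    conservation_threshold: float = 0.9

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def _range_checks(cfg: RunConfig) -> list[str]:
    errors = []
    if not isinstance(cfg.seed, int):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    if not 0 <= cfg.max_gap_fraction < 1:
        errors.append(f"max_gap_fraction must be in [0, 1), got {cfg.max_gap_fraction}")
    if cfg.bootstrap < 1:
        errors.append(f"bootstrap must be >= 1, got {cfg.bootstrap}")
    if not 0 <= cfg.min_support <= 100:
        errors.append(f"min_support must be in [0, 100], got {cfg.min_support}")
    if cfg.min_branch_length < 0:
        errors.append(f"min_branch_length must be >= 0, got {cfg.min_branch_length}")
    if cfg.fc <= 0:
        errors.append(f"fc must be positive, got {cfg.fc}")
    if not 0 < cfg.adj_p <= 1:
        errors.append(f"adj_p must be in (0, 1], got {cfg.adj_p}")
    if cfg.floor < 0:
        errors.append(f"floor must be >= 0, got {cfg.floor}")
    if not 0 <= cfg.conservation_threshold <= 1:
        errors.append(
            f"conservation_threshold must be in [0, 1], got {cfg.conservation_threshold}"
        )
    if cfg.cutoff is not None and not isinstance(cfg.cutoff, (int, float)):
        errors.append(f"cutoff must be numeric or null, got {cfg.cutoff!r}")
    return errors


# inputs each stage cannot run without
_STAGE_INPUTS = {
    "screen": ("proteome", "reference_alignment", "reference_labels"),
    "tree": ("alignment", "outgroup"),
    "clades": ("reference_labels",),
    "motifs": ("proteome",),
    "de": ("expression", "samples"),
    "regulons": (),
}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All problems are collected and raised together as a
    :class:`ConfigError`; syntactic YAML errors carry the parser's
    location.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"YAML syntax error: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}

    comparisons = []
    for i, item in enumerate(kwargs.pop("comparisons", []) or []):
        if not isinstance(item, dict):
            errors.append(f"comparisons[{i}] must be a mapping")
            continue
        missing = {"tf", "wt_strain", "mutant_strain", "carbon_source"} - set(item)
        if missing:
            errors.append(f"comparisons[{i}] missing keys {sorted(missing)}")
            continue
        comparisons.append(Comparison(**{k: str(item[k]) for k in ("tf", "wt_strain", "mutant_strain", "carbon_source")}))

    stages = {s: True for s in STAGES}
    for k, v in (kwargs.pop("stages", {}) or {}).items():
        if k not in STAGES:
            errors.append(f"unknown stage {k!r} (choose from {list(STAGES)})")
        elif not isinstance(v, bool):
            errors.append(f"stage {k!r} must be true/false")
        else:
            stages[k] = v

    try:
        cfg = RunConfig(stages=stages, comparisons=comparisons, **kwargs)
    except TypeError as exc:
        raise ConfigError(errors + [str(exc)]) from exc

    errors.extend(_range_checks(cfg))

    # existence of the inputs each enabled stage needs
    base = path.parent
    for stage, inputs in _STAGE_INPUTS.items():
        if not cfg.stages.get(stage):
            continue
        for name in inputs:
            value = getattr(cfg, name)
            if value is None:
                errors.append(f"stage {stage!r} enabled but {name!r} is not set")
            elif not (base / value).exists() and not Path(value).exists():
                errors.append(f"stage {stage!r}: {name} path not found: {value}")
    if cfg.stages.get("de") and not cfg.comparisons:
        errors.append("stage 'de' enabled but no comparisons given")
    if cfg.stages.get("tree") and cfg.tree is None:
        pass  # tree is built from the alignment
    if errors:
        raise ConfigError(errors)
    # resolve paths relative to the config file
    for name in (
        "proteome", "reference_labels", "reference_alignment", "alignment",
        "outgroup", "tree", "motif_table", "expression", "samples",
        "st_list", "hmmer_table",
    ):
        value = getattr(cfg, name)
        if value is not None and not Path(value).is_absolute():
            resolved = base / value
            if resolved.exists():
                setattr(cfg, name, str(resolved))
    return cfg
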