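"""Pipeline configuration: one YAML file driving all stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pipeline import PipelineParams
from .synthetic import GeneratorConfig


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    seed: int = 1
    outdir: str = "wwscreen_out"
    generator: GeneratorConfig | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def __post_init__(self) -> None:
        p = self.params
        for name in ("ppm_tol", "rt_tol_within", "rt_tol_across",
                     "frag_tol_da", "blank_fold"):
            if getattr(p, name) <= 0:
                raise ValueError(f"tolerance {name} must be positive")
        if not (0.0 < p.rt_level < 1.0):
            raise ValueError("rt_level must be in (0, 1)")
        if p.score_weights is not None:
            total = sum(p.score_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("score_weights must sum to 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {"seed", "outdir", "generator", "params"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    seed = int(raw.get("seed", 1))
    gen_kwargs = dict(raw.get("generator") or {})
    gen_kwargs.setdefault("seed", seed)
    for key, value in gen_kwargs.items():
        if isinstance(value, list):
            gen_kwargs[key] = tuple(value)
    params_kwargs = dict(raw.get("params") or {})
    for key, value in params_kwargs.items():
        if isinstance(value, list):
            params_kwargs[key] = tuple(value)
    try:
        generator = GeneratorConfig(**gen_kwargs)
        params = PipelineParams(**params_kwargs)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid configuration: {exc}") from exc
    return PipelineConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "wwscreen_out")),
        generator=generator,
        params=params,
    )


def provenance(config: PipelineConfig) -> dict:
    """Config hash + seed embedded in every stage report."""
    payload = json.dumps(
        {
            "seed": config.seed,
            "generator": dataclasses.asdict(config.generator)
            if config.generator
            else None,
            "params": dataclasses.asdict(config.params),
        },
        sort_keys=True,
        default=str,
    )
    return {
        "seed": config.seed,
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:12],
    }
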