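"""Run configuration: a sectioned YAML file validated before anything runs.

Sections mirror the pipeline stages (``simulate``, ``preprocess``,
``window``, ``stft``, ``train``) plus a global ``seed`` and the condition
list; unknown keys anywhere are rejected up front.  The shipped defaults
equal the study's stated parameters: 2000 sps, 49/51 Hz notch edges,
250/100/50 ms segmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .encode import StftSpec, WindowSpec
from .evaluate import DEFAULT_CONDITIONS
from .exceptions import ConfigError
from .models import TrainConfig
from .preprocess import FilterSpec
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_SECTIONS = {
    "simulate": SimConfig,
    "window": WindowSpec,
    "stft": StftSpec,
    "train": TrainConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for every stage of one pipeline run."""

    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: tuple[FilterSpec, ...] = (
        FilterSpec(kind="dc_block"),
        FilterSpec(kind="notch"),
    )
    window: WindowSpec = field(default_factory=WindowSpec)
    stft: StftSpec = field(default_factory=StftSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    conditions: tuple[tuple[str, int], ...] = DEFAULT_CONDITIONS
    seed: int = 0

    def reseeded(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every stage."""
        return dataclasses.replace(
            self,
            seed=seed,
            simulate=dataclasses.replace(self.simulate, seed=seed),
            train=dataclasses.replace(self.train, seed=seed),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": dataclasses.asdict(self.simulate),
            "preprocess": [dataclasses.asdict(s) for s in self.preprocess],
            "window": dataclasses.asdict(self.window),
            "stft": dataclasses.asdict(self.stft),
            "train": dataclasses.asdict(self.train),
            "conditions": [list(c) for c in self.conditions],
        }


def default_config_dict() -> dict:
    return RunConfig().to_dict()


def _build_section(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    fixed = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        fixed[key] = value
    try:
        return cls(**fixed)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section {section!r}: {err}") from err


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path, YAML text, or a dict."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    known = set(_SECTIONS) | {"preprocess", "conditions", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    if "preprocess" in raw:
        specs = raw["preprocess"] or []
        if not isinstance(specs, list):
            raise ConfigError("'preprocess' must be a list of filter specs")
        kwargs["preprocess"] = tuple(
            _build_section(FilterSpec, s or {}, "preprocess") for s in specs
        )
    if "conditions" in raw:
        conds = []
        for item in raw["conditions"]:
            enc, n_ch = item
            if enc not in ("time_domain", "spectrogram", "enhanced_spectrogram"):
                raise ConfigError(f"unknown encoder in conditions: {enc!r}")
            if int(n_ch) not in (8, 16):
                raise ConfigError(f"condition channel count must be 8 or 16, got {n_ch}")
            conds.append((enc, int(n_ch)))
        kwargs["conditions"] = tuple(conds)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])

    cfg = RunConfig(**kwargs)
    if "seed" in raw:
        cfg = cfg.reseeded(int(raw["seed"]))
    return cfg
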