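"""Run configuration: one record holding every pipeline setting, with a
YAML round-trip.  Every field has a documented default, and the effective
configuration is echoed into output metadata by the writers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .embedding import SpiralConfig
from .hybrid import EvaluationScheme, LearnerConfig
from .visibility import BuildConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for an end-to-end run (embedding, build, null model,
    learner, evaluation scheme, seed)."""

    spiral: SpiralConfig = field(default_factory=SpiralConfig)
    build: BuildConfig = field(default_factory=BuildConfig)
    null: str = "dyad"
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    scheme: EvaluationScheme = field(default_factory=EvaluationScheme)
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "spiral" in raw:
            kwargs["spiral"] = SpiralConfig(**raw["spiral"])
        if "build" in raw:
            kwargs["build"] = BuildConfig(**raw["build"])
        if "learner" in raw:
            hidden = raw["learner"].pop("hidden", None)
            kwargs["learner"] = LearnerConfig(
                **raw["learner"], **({"hidden": tuple(hidden)} if hidden else {})
            )
        if "scheme" in raw:
            kwargs["scheme"] = EvaluationScheme(**raw["scheme"])
        for key in ("null", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)
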