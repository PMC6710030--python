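"""Study configuration: YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import CohortSpec, VertebraParams

__all__ = ["StudyConfig", "load_study_config"]

_EPSILON_GRID = (0.1, 0.5, 1.0, 2.0)


@dataclass
class StudyConfig:
    """Everything a study run needs.

    Exactly one input mode: a synthetic :class:`CohortSpec`, or a
    directory of cloud files with a manifest CSV (columns ``specimen,
    level, path``).
    """

    cohort: CohortSpec | None = None
    input_dir: Path | None = None
    epsilon: float = 0.5
    iterations: int = 100
    cov_repeats: int = 20
    seed: int = 0
    alpha: float = 0.05
    out_dir: Path = Path("study_out")

    def __post_init__(self):
        if (self.cohort is None) == (self.input_dir is None):
            raise ConfigError(
                "exactly one input mode required: synthetic cohort or input directory"
            )
        if not self.epsilon > 0:
            raise ConfigError("epsilon must be positive")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.cov_repeats < 2:
            raise ConfigError("cov_repeats must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


def load_study_config(path) -> StudyConfig:
    """Parse a YAML study configuration.

    Schema::

        seed: 1
        epsilon: 0.5
        iterations: 100
        cov_repeats: 20
        alpha: 0.05
        out_dir: study_out
        cohort:                 # synthetic mode
          n_specimens: 4
          levels: [C1, C2, ...]   # optional, defaults to C1..S1
          jitter_sd: 0.05
          relief_scale: 1.0
          vertebra: {noise_sd: 0.15, ...}   # VertebraParams overrides
        # OR
        input_dir: clouds/      # directory mode (with manifest.csv inside)
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(f"no such config file: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    cohort = None
    if "cohort" in raw:
        c = dict(raw["cohort"] or {})
        vparams = VertebraParams(**c.pop("vertebra", {}))
        if "levels" in c:
            c["levels"] = tuple(c["levels"])
        try:
            cohort = CohortSpec(base_params=vparams, seed=raw.get("seed", 0), **c)
        except TypeError as exc:
            raise ConfigError(f"bad cohort spec: {exc}") from exc
    input_dir = Path(raw["input_dir"]) if "input_dir" in raw else None

    try:
        return StudyConfig(
            cohort=cohort,
            input_dir=input_dir,
            epsilon=float(raw.get("epsilon", 0.5)),
            iterations=int(raw.get("iterations", 100)),
            cov_repeats=int(raw.get("cov_repeats", 20)),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            out_dir=Path(raw.get("out_dir", "study_out")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad study config: {exc}") from exc
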