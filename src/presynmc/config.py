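"""Run configuration: a single round-trippable YAML schema.

Every run writes its resolved configuration beside its outputs so any result
directory carries enough metadata (scheme, engine, seed, versions) to be
reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError

__all__ = ["RunConfig", "load_run_config", "save_run_config", "setup_logging"]

logger = logging.getLogger("presynmc")


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    scheme: str = "vdcc5"          # preset name or path to a scheme YAML
    engine: str = "multinomial"
    n: int = 65
    duration_s: float = 0.01
    dt_s: float = 1e-6
    n_runs: int = 1
    seed: int = 0
    stimulus: dict = field(default_factory=lambda: {"kind": "action_potential"})
    free_calcium_M: float = 1e-7
    coupled: bool = False
    output_dir: str = "presynmc_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> "RunConfig":
        from .engines import ENGINES
        if self.engine not in ENGINES:
            raise ConfigurationError(f"field 'engine': unknown engine {self.engine!r}")
        for name in ("n", "n_runs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"field {name!r}: must be >= 1")
        for name in ("duration_s", "dt_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"field {name!r}: must be > 0")
        if self.free_calcium_M < 0:
            raise ConfigurationError("field 'free_calcium_M': must be >= 0")
        kind = self.stimulus.get("kind")
        if kind not in ("action_potential", "constant", "file"):
            raise ConfigurationError(f"field 'stimulus.kind': unknown kind {kind!r}")
        return self


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("presynmc_version", None)  # provenance stamp, not a config field
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw).validate()


def save_run_config(config: RunConfig, path) -> None:
    payload = config.to_dict()
    payload["presynmc_version"] = __version__
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def write_audit_json(audit, path) -> None:
    with open(path, "w") as fh:
        json.dump(audit.to_dict(), fh, indent=2)
        fh.write("\n")
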