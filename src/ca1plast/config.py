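"""Run configuration: YAML key-value files with validated defaults.

An empty document resolves to the published defaults. Unknown keys are
rejected by name; model-parameter overrides are re-validated (e.g. a dt
exceeding tau_0 fails). The fully resolved configuration round-trips
through :func:`dump_config` / :func:`load_config` unchanged and is
persisted alongside every output for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ConnectivityConfig
from .params import ModelParams
from .plasticity import PlasticityConfig
from .protocols import (DEFAULT_LAP_SCHEDULE, ExplorationProtocol, IOProtocol)

__all__ = ["RunConfig", "load_config", "dump_config"]

_CONN_FIELDS = ("pv_alpha", "pv_beta", "pv_gamma",
                "sst_alpha", "sst_beta", "sst_gamma")


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    protocol: str = "exploration"          # "exploration" | "io"
    trials: int = 10
    seed: int = 1
    out: str = "results"
    record_every_ms: float = 10.0
    params: ModelParams = field(default_factory=ModelParams)
    # exploration settings
    iplas: str = "on"                      # on / off / pv-only / sst-only
    exc_plasticity: bool = True
    lap_schedule: tuple = DEFAULT_LAP_SCHEDULE
    # io settings
    pathway: str = "both"
    active_rule: str = "both"
    connectivity: dict = field(
        default_factory=lambda: {k: 0 for k in _CONN_FIELDS})
    baseline_ms: float = 10_000.0
    induction_ms: float = 60_000.0
    post_ms: float = 10_000.0
    # analysis settings
    n_bins: int = 50
    late_laps: tuple = (-2, -1)
    early_laps: tuple = (0, 1)

    def __post_init__(self) -> None:
        if self.protocol not in ("exploration", "io"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        unknown = set(self.connectivity) - set(_CONN_FIELDS)
        if unknown:
            raise ValueError(f"unknown connectivity keys: {sorted(unknown)}")
        PlasticityConfig.from_name(self.iplas)  # validates

    def exploration_protocol(self) -> ExplorationProtocol:
        plast = PlasticityConfig.from_name(self.iplas)
        plast = dataclasses.replace(plast, exc_on=self.exc_plasticity)
        schedule = tuple((str(e), int(k)) for e, k in self.lap_schedule)
        return ExplorationProtocol(lap_schedule=schedule, plasticity=plast,
                                   record_every_ms=self.record_every_ms,
                                   params=self.params)

    def io_protocol(self) -> IOProtocol:
        conn = ConnectivityConfig(mode="connectivity_driven",
                                  **{k: int(v) for k, v
                                     in self.connectivity.items()})
        return IOProtocol(connectivity=conn, pathway=self.pathway,
                          active_rule=self.active_rule,
                          baseline_ms=self.baseline_ms,
                          induction_ms=self.induction_ms,
                          post_ms=self.post_ms,
                          record_every_ms=self.record_every_ms,
                          params=self.params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["lap_schedule"] = [[e, k] for e, k in self.lap_schedule]
        d["late_laps"] = list(self.late_laps)
        d["early_laps"] = list(self.early_laps)
        return d


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file and/or apply inline overrides.

    Later sources win: defaults < file < ``overrides``. Unknown keys raise
    ``ValueError`` naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got "
                             f"{type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    if "params" in data:
        pdata = data["params"] or {}
        if isinstance(pdata, ModelParams):
            data["params"] = pdata
        else:
            bad = set(pdata) - set(ModelParams.field_names())
            if bad:
                raise ValueError(f"unknown model parameter(s): {sorted(bad)}")
            data["params"] = ModelParams(**pdata)
    if "lap_schedule" in data:
        data["lap_schedule"] = tuple(
            (str(e), int(k)) for e, k in data["lap_schedule"])
    for key in ("late_laps", "early_laps"):
        if key in data:
            data[key] = tuple(int(v) for v in data[key])
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    """Persist the fully resolved configuration as YAML."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
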