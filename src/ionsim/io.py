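"""Configuration files, trace writers, and reproducibility metadata.

Configs are flat JSON with sections mirroring the library's dataclasses;
unknown keys are rejected with their full path.  Traces are written as
CSV (full double precision) or a binary columnar ``.npz`` container,
always with a JSON metadata sidecar sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ClassificationRules
from .engine import Protocol, Trace
from .geometry import geometry_from_radius
from .parameters import ModelParameters, VariantFlags


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    params: ModelParameters = field(default_factory=ModelParameters)
    flags: VariantFlags = field(default_factory=VariantFlags)
    r_in: float = 4.82
    r_tot: float = 5.0
    protocol: Protocol = field(default_factory=lambda: Protocol(duration=100.0))
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    seed: int = 0
    out: str | None = None

    def geometry(self):
        return geometry_from_radius(self.r_in, self.r_tot)

    def to_dict(self) -> dict:
        d = dict(
            parameters=dataclasses.asdict(self.params),
            geometry=dict(r_in=self.r_in, r_tot=self.r_tot),
            flags=dataclasses.asdict(self.flags),
            protocol=dict(duration=self.protocol.duration,
                          schedule=[list(s) for s in self.protocol.schedule],
                          dt=self.protocol.dt,
                          record_stride=self.protocol.record_stride,
                          transient_discard=self.protocol.transient_discard),
            rules=dataclasses.asdict(self.rules),
            seed=self.seed,
        )
        if self.out is not None:
            d["out"] = self.out
        return d


def _build(section: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}")


def config_from_dict(raw: dict) -> ExperimentConfig:
    known = {"parameters", "geometry", "flags", "protocol", "rules",
             "seed", "out"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; "
                          f"valid sections: {sorted(known)}")
    params = _build("parameters", ModelParameters, raw.get("parameters", {}))
    flags = _build("flags", VariantFlags, raw.get("flags", {}))
    geo = dict(raw.get("geometry", {}))
    bad = set(geo) - {"r_in", "r_tot"}
    if bad:
        raise ConfigError(f"unknown key(s) {sorted(bad)} in section 'geometry'")
    r_in = float(geo.get("r_in", 4.82))
    r_tot = float(geo.get("r_tot", 5.0))
    proto_raw = dict(raw.get("protocol", {}))
    if "schedule" in proto_raw:
        proto_raw["schedule"] = tuple(
            (float(a), float(b), str(nm), float(v))
            for a, b, nm, v in proto_raw["schedule"])
    proto = _build("protocol", Protocol,
                   {"duration": 100.0, **proto_raw})
    rules = _build("rules", ClassificationRules, raw.get("rules", {}))
    cfg = ExperimentConfig(params, flags, r_in, r_tot, proto, rules,
                           int(raw.get("seed", 0)), raw.get("out"))
    cfg.geometry()   # validates 0 < r_in < r_tot
    return cfg


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}")
    return config_from_dict(raw)


def write_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
                          + "\n")


# ---------------------------------------------------------------------------
# traces

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: Trace, path, fmt: str = "csv") -> None:
    """Write a trace as CSV ('.' decimal, comma separator, LF endings,
    17-significant-digit floats; read back with round-trip parsing) or
    binary columnar npz, plus a JSON metadata sidecar."""
    path = Path(path)
    try:
        if fmt == "csv":
            trace.data.to_csv(path, index=False, lineterminator="\n",
                              float_format="%.17g")
        elif fmt == "npz":
            np.savez_compressed(
                path, **{c: trace.data[c].to_numpy()
                         for c in trace.data.columns})
        else:
            raise ValueError(f"unknown trace format {fmt!r}")
        _sidecar(path).write_text(
            json.dumps(trace.meta, indent=2, sort_keys=True, default=str))
    except OSError as exc:
        raise OSError(f"failed writing trace to {path}: {exc}") from exc


def read_trace(path) -> Trace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            df = pd.DataFrame({c: z[c] for c in z.files})
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Trace(df, meta)
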