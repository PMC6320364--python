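"""Trajectory and configuration I/O.

Trajectories are tab-separated tables with columns ``t_s``, ``x_um`` and
optionally ``fext_fN``; ``#``-prefixed header lines carry JSON metadata.
Run configurations are JSON objects validated against a small hand-checked
schema with precise error paths.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, PathtimesError
from .model import (
    ConstantD,
    DiffusionProfile,
    Linear,
    PotentialSpec,
    Quartic,
    Tabulated,
    TabulatedD,
    TelegraphSpec,
    TrapMixture,
    Units,
)
from .simulate import SimConfig, Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "potential_from_dict",
    "potential_to_dict",
    "diffusion_from_dict",
    "diffusion_to_dict",
    "RunConfig",
    "load_config",
]


class ParseError(PathtimesError, ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def write_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    path = Path(path)
    cols = ["t_s", "x_um"] + (["fext_fN"] if traj.fext is not None else [])
    with path.open("w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata) + "\n")
        fh.write("\t".join(cols) + "\n")
        data = [traj.t, traj.x] + ([traj.fext] if traj.fext is not None else [])
        for row in zip(*data):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    header = None
    t, x, f = [], [], []
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["t_s", "x_um"] or (
                    len(header) == 3 and header[2] != "fext_fN"
                ) or len(header) > 3:
                    raise ParseError(f"unexpected header {header!r}", ln)
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(parts)}", ln
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"non-numeric value in {parts!r}", ln) from None
            if t and vals[0] <= t[-1]:
                raise ParseError("timestamps must be strictly increasing", ln)
            t.append(vals[0])
            x.append(vals[1])
            if len(header) == 3:
                f.append(vals[2])
    if header is None:
        raise ParseError("file has no header line", 0)
    fext = np.asarray(f) if f else None
    return Trajectory(t=np.asarray(t), x=np.asarray(x), fext=fext)


# ---------------------------------------------------------------------------
# JSON config schema
# ---------------------------------------------------------------------------

_POTENTIAL_VARIANTS = {"quartic", "linear", "trap_mixture", "tabulated"}


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"{where}: missing required key '{key}'")
    return d[key]


def potential_from_dict(d: dict, where: str = "potential") -> PotentialSpec:
    variant = _require(d, "variant", where)
    try:
        if variant == "quartic":
            return Quartic(a=float(_require(d, "a", where)),
                           b=float(_require(d, "b", where)),
                           c=float(_require(d, "c", where)))
        if variant == "linear":
            return Linear(f=float(_require(d, "f", where)))
        if variant == "trap_mixture":
            traps = _require(d, "traps", where)
            return TrapMixture(traps=tuple(tuple(t) for t in traps))
        if variant == "tabulated":
            return Tabulated(x=tuple(_require(d, "x", where)),
                             U=tuple(_require(d, "U", where)))
    except PathtimesError:
        raise
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e
    raise ConfigError(
        f"{where}: unknown variant '{variant}' (expected one of {sorted(_POTENTIAL_VARIANTS)})"
    )


def potential_to_dict(spec: PotentialSpec) -> dict:
    if isinstance(spec, Quartic):
        return {"variant": "quartic", "a": spec.a, "b": spec.b, "c": spec.c}
    if isinstance(spec, Linear):
        return {"variant": "linear", "f": spec.f}
    if isinstance(spec, TrapMixture):
        return {"variant": "trap_mixture", "traps": [list(t) for t in spec.traps]}
    if isinstance(spec, Tabulated):
        return {"variant": "tabulated", "x": list(spec.x), "U": list(spec.U)}
    raise ConfigError(f"unknown potential type {type(spec).__name__}")


def diffusion_from_dict(d: dict | float, where: str = "diffusion") -> DiffusionProfile:
    if isinstance(d, (int, float)):
        return ConstantD(float(d))
    if "constant" in d:
        return ConstantD(float(d["constant"]))
    if "x" in d and "D" in d:
        return TabulatedD(x=tuple(d["x"]), D=tuple(d["D"]))
    raise ConfigError(f"{where}: expected a number, {{'constant': D}} or {{'x': [...], 'D': [...]}}")


def diffusion_to_dict(D: DiffusionProfile) -> dict:
    if isinstance(D, ConstantD):
        return {"constant": D.D}
    return {"x": list(D.x), "D": list(D.D)}


@dataclass
class RunConfig:
    units: Units
    potential: PotentialSpec
    diffusion: DiffusionProfile
    telegraph: TelegraphSpec | None
    sim: SimConfig
    interval: tuple[float, float] | None
    protocol: str
    seed: int


_PROTOCOLS = {"exit", "transitions", "sweep", "hairpin", "simulate"}


def load_config(path_or_dict) -> RunConfig:
    """Parse and validate a JSON run configuration."""
    if isinstance(path_or_dict, (str, Path)):
        try:
            cfg = json.loads(Path(path_or_dict).read_text())
        except json.JSONDecodeError as e:
            raise ConfigError(f"invalid JSON: {e}") from e
    else:
        cfg = dict(path_or_dict)
    units = Units(kBT=float(cfg.get("units", {}).get("kBT", 4.11)))
    potential = potential_from_dict(_require(cfg, "potential", "config"))
    diffusion = diffusion_from_dict(_require(cfg, "diffusion", "config"))
    tg = None
    if cfg.get("telegraph") is not None:
        td = cfg["telegraph"]
        tg = TelegraphSpec(
            f0=float(_require(td, "f0", "telegraph")),
            alpha=float(_require(td, "alpha", "telegraph")),
            initial_level=td.get("initial_level", "random"),
            seed=int(td.get("seed", cfg.get("seed", 0))),
        )
    sd = cfg.get("sim", {})
    seed = int(cfg.get("seed", 0))
    bounds = sd.get("reflecting_bounds")
    sim = SimConfig(
        dt=float(sd.get("dt", 1e-3)),
        t_max=float(sd.get("t_max", 10.0)),
        x0=float(sd.get("x0", 0.0)),
        record_stride=int(sd.get("record_stride", 1)),
        reflecting_bounds=tuple(bounds) if bounds is not None else None,
        seed=seed,
    )
    interval = cfg.get("interval")
    if interval is not None:
        interval = (float(interval[0]), float(interval[1]))
        if not interval[0] < interval[1]:
            raise ConfigError("config: interval must be ordered (left, right)")
        if sim.reflecting_bounds is not None:
            lo, hi = sim.reflecting_bounds
            if interval[0] < lo or interval[1] > hi:
                raise ConfigError("config: interval must lie inside reflecting_bounds")
    protocol = cfg.get("protocol", "simulate")
    if protocol not in _PROTOCOLS:
        raise ConfigError(
            f"config: unknown protocol '{protocol}' (expected one of {sorted(_PROTOCOLS)})"
        )
    return RunConfig(
        units=units, potential=potential, diffusion=diffusion, telegraph=tg,
        sim=sim, interval=interval, protocol=protocol, seed=seed,
    )
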