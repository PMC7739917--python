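"""Run configuration: TOML parsing and schema validation.

A run is described by one TOML document.  Validation is strict — unknown
keys are rejected by name — and every source of randomness flows from the
single ``[coupling] seed``, so two runs of the same config produce
byte-identical CSV outputs.

Example::

    schema_version = 1

    [geometry]
    fixture = "one_to_n"      # or "tube" / "bifurcating_tree" / file = "g.h5"
    n = 3

    [units]
    dx = 1e-4                  # m
    dt = 1.5e-4                # s
    rho_ref = 1050.0           # kg/m^3
    nu = 3.3e-6                # m^2/s
    v_max = 0.01               # m/s, for the Mach check

    [run]
    n_steps = 3000
    output_dir = "out"
    snapshot_every = 0         # 0 = final state only

    [coupling]
    seed = 1
    exchange_period = 10
    dp_range = [0.3, 0.7]
    gain = 10.0
    P0 = 1.0                   # Pa, reference for pressure bookkeeping

    [[boundary]]
    instance = "arterial"      # "main" for single-instance runs
    patch = 0
    kind = "velocity"          # velocity | pressure
    value = 0.01               # m/s, or relative lattice pressure for kind=pressure
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .units import BLOOD_NU, BLOOD_RHO, UnitSystem

__all__ = ["RunConfig", "load_config"]

_SCHEMA = {
    "schema_version": None,
    "geometry": {
        "fixture": None,
        "file": None,
        "n": None,
        "radius": None,
        "length": None,
        "axis": None,
        "side": None,
        "channel_len": None,
    },
    "units": {"dx": None, "dt": None, "rho_ref": None, "nu": None, "v_max": None},
    "run": {"n_steps": None, "output_dir": None, "snapshot_every": None},
    "coupling": {
        "seed": None,
        "exchange_period": None,
        "dp_range": None,
        "gain": None,
        "P0": None,
    },
    "boundary": {
        "instance": None,
        "patch": None,
        "kind": None,
        "value": None,
        "profile": None,
        "gain": None,
    },
}


@dataclass
class RunConfig:
    """Validated run configuration."""

    geometry: dict
    units: UnitSystem
    n_steps: int
    output_dir: Path
    snapshot_every: int
    seed: int
    exchange_period: int
    dp_range: tuple
    gain: float
    P0: float
    boundaries: list = field(default_factory=list)


def _check_keys(section: str, data: dict, allowed: dict) -> None:
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' in [{section}]")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Raises :class:`ConfigError` naming the offending key on any schema
    violation.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    _check_keys("<root>", doc, _SCHEMA)
    if doc.get("schema_version") != 1:
        raise ConfigError("schema_version must be present and equal to 1")

    geo = doc.get("geometry", {})
    _check_keys("geometry", geo, _SCHEMA["geometry"])
    if ("fixture" in geo) == ("file" in geo):
        raise ConfigError("[geometry] needs exactly one of 'fixture' or 'file'")

    uni = doc.get("units", {})
    _check_keys("units", uni, _SCHEMA["units"])
    for req in ("dx", "dt"):
        if req not in uni:
            raise ConfigError(f"missing required key '{req}' in [units]")
    units = UnitSystem(
        dx=float(uni["dx"]),
        dt=float(uni["dt"]),
        rho_ref=float(uni.get("rho_ref", BLOOD_RHO)),
        nu_phys=float(uni.get("nu", BLOOD_NU)),
        v_max=float(uni.get("v_max", 0.0)),
    )

    run = doc.get("run", {})
    _check_keys("run", run, _SCHEMA["run"])
    if "n_steps" not in run:
        raise ConfigError("missing required key 'n_steps' in [run]")

    cpl = doc.get("coupling", {})
    _check_keys("coupling", cpl, _SCHEMA["coupling"])
    dp = tuple(cpl.get("dp_range", (0.3, 0.7)))
    if not (len(dp) == 2 and 0 < dp[0] <= dp[1] < 1):
        raise ConfigError("coupling.dp_range must be [lo, hi] with 0 < lo <= hi < 1")

    bcs = doc.get("boundary", [])
    if isinstance(bcs, dict):
        bcs = [bcs]
    for bc in bcs:
        _check_keys("boundary", bc, _SCHEMA["boundary"])
        for req in ("patch", "kind", "value"):
            if req not in bc:
                raise ConfigError(f"missing required key '{req}' in [[boundary]]")
        if bc["kind"] not in ("velocity", "pressure"):
            raise ConfigError(
                f"boundary.kind '{bc['kind']}' must be 'velocity' or 'pressure'"
            )

    return RunConfig(
        geometry=geo,
        units=units,
        n_steps=int(run["n_steps"]),
        output_dir=Path(run.get("output_dir", "out")),
        snapshot_every=int(run.get("snapshot_every", 0)),
        seed=int(cpl.get("seed", 0)),
        exchange_period=int(cpl.get("exchange_period", 10)),
        dp_range=dp,
        gain=float(cpl.get("gain", 10.0)),
        P0=float(cpl.get("P0", 1.0)),
        boundaries=list(bcs),
    )
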