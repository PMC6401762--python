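"""YAML run configuration, validation and dispatch.

A config names an engine and a parameter block; physical quantities carry
explicit units which are normalized to the internal system (nm, kBT, e,
seconds) at load time.  Unknown keys are rejected.  A run writes scalar
results as JSON and profiles/sweeps as CSV next to the requested output
stem, plus a provenance record with the fully resolved configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import ATM_TO_PA, NM_PER_ANGSTROM
from .electrostatics import Electrolyte, PoreSystem
from .fixtures import get_fixture
from .iftp import IFTPParams, iftp_solve, scaling_exponent, waiting_time

__all__ = ["RunConfig", "load_config", "run"]

_LENGTH_UNITS = {"nm": 1.0, "angstrom": NM_PER_ANGSTROM, "A": NM_PER_ANGSTROM}
_VOLT_UNITS = {"V": 1.0, "mV": 1e-3}
_PRESSURE_UNITS = {"Pa": 1.0, "atm": ATM_TO_PA, "bar": 1e5}
_DENSITY_UNITS = {"M": 1.0, "mM": 1e-3}

_EHD_KEYS = {"a", "d", "Lm", "Lp", "sigma_p", "sigma_m", "delta_V",
             "delta_P", "salt", "barrier"}
_IFTP_KEYS = {"N0", "f", "eta_p", "nu", "gamma_prime", "A_nu", "mode",
              "chain", "entropic", "noise", "kT", "dt"}


def _quantity(name, value, units_table, default_unit):
    """Resolve a `{value, units}` mapping or bare number to internal units."""
    if isinstance(value, dict):
        extra = set(value) - {"value", "units"}
        if extra:
            raise ValueError(f"unknown sub-keys {sorted(extra)} under {name!r}")
        unit = value.get("units", default_unit)
        if unit not in units_table:
            raise ValueError(
                f"unknown units {unit!r} for {name!r}; allowed: "
                f"{sorted(units_table)}")
        return float(value["value"]) * units_table[unit]
    return float(value) * units_table[default_unit]


@dataclass
class RunConfig:
    """Validated, unit-normalized run description."""

    engine: str
    params: dict
    barrier: str = "mf"
    scan: dict | None = None
    seed: int | None = None
    output: str | None = None
    log_level: str = "info"
    fixture: str | None = None

    def to_dict(self) -> dict:
        d = {"engine": self.engine, "params": dict(self.params),
             "barrier": self.barrier, "log_level": self.log_level}
        if self.scan:
            d["scan"] = dict(self.scan)
        if self.seed is not None:
            d["seed"] = self.seed
        if self.output:
            d["output"] = self.output
        if self.fixture:
            d["fixture"] = self.fixture
        return d

    def build(self):
        """Instantiate the engine parameter object."""
        if self.engine == "ehd":
            p = dict(self.params)
            molar = p.pop("salt")
            el = Electrolyte.monovalent(molar)
            return PoreSystem(electrolyte=el, **p)
        p = dict(self.params)
        if p.get("noise") and self.seed is None:
            raise ValueError("stochastic IFTP runs require a seed")
        return IFTPParams(seed=self.seed if p.get("noise") else None, **p)


def _normalize_ehd(params: dict) -> dict:
    unknown = set(params) - _EHD_KEYS
    if unknown:
        raise ValueError(f"unknown ehd parameter(s): {sorted(unknown)}")
    out = {}
    for key in ("a", "d", "Lm", "Lp"):
        if key in params:
            out[key] = _quantity(key, params[key], _LENGTH_UNITS, "nm")
    for key in ("sigma_p", "sigma_m"):
        if key in params:
            out[key] = _quantity(key, params[key], {"e/nm2": 1.0}, "e/nm2")
    if "delta_V" in params:
        out["delta_V"] = _quantity("delta_V", params["delta_V"], _VOLT_UNITS, "V")
    if "delta_P" in params:
        out["delta_P"] = _quantity("delta_P", params["delta_P"], _PRESSURE_UNITS, "Pa")
    out["salt"] = _quantity("salt", params.get("salt", 0.1), _DENSITY_UNITS, "M")
    return out


def _normalize_iftp(params: dict) -> dict:
    unknown = set(params) - _IFTP_KEYS
    if unknown:
        raise ValueError(f"unknown iftp parameter(s): {sorted(unknown)}")
    out = dict(params)
    if "N0" in out:
        out["N0"] = int(out["N0"])
    return out


def make_config(raw: dict) -> RunConfig:
    """Build and validate a RunConfig from a raw mapping."""
    allowed = {"engine", "params", "barrier", "scan", "seed", "output",
               "log_level", "fixture"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    fixture = raw.get("fixture")
    if fixture:
        fx = get_fixture(fixture)
        engine = fx.engine
        if engine == "ehd":
            p = dict(fx.params)
            barrier = p.pop("barrier", "mf")
            p["salt"] = p.pop("rho_molar")
            params = p
        else:
            params = dict(fx.params)
            barrier = raw.get("barrier", "mf")
    else:
        engine = raw.get("engine")
        if engine not in ("ehd", "iftp"):
            raise ValueError("config must set engine to 'ehd' or 'iftp' "
                             "or name a fixture")
        params = raw.get("params", {})
        if engine == "ehd":
            barrier = params.pop("barrier", raw.get("barrier", "mf"))
            params = _normalize_ehd(params)
        else:
            params = _normalize_iftp(params)
            barrier = raw.get("barrier", "mf")
    cfg = RunConfig(engine=engine, params=params, barrier=barrier,
                    scan=raw.get("scan"), seed=raw.get("seed"),
                    output=raw.get("output"),
                    log_level=raw.get("log_level", "info"), fixture=fixture)
    cfg.build()  # surface invariant violations (e.g. a >= d) at load time
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return make_config(raw)


def run(config: RunConfig, out_dir=".") -> dict:
    """Dispatch a config to its engine and write the result files.

    Returns the scalar results; identical config + seed gives identical
    outputs.
    """
    from . import transport

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = config.output or f"{config.fixture or config.engine}"

    if config.engine == "ehd":
        if config.scan:
            import pandas as pd

            rows = []
            for val in config.scan["grid"]:
                p = dict(config.params)
                p[config.scan["parameter"]] = val
                cfg_i = RunConfig(engine="ehd", params=p, barrier=config.barrier)
                system = cfg_i.build()
                res = transport.solve(system, barrier=config.barrier)
                rows.append({config.scan["parameter"]: val, **res.scalars()})
            df = pd.DataFrame(rows)
            df.to_csv(out_dir / f"{stem}_scan.csv", index=False)
            scalars = {"rows": len(rows)}
        else:
            system = config.build()
            res = transport.solve(system, barrier=config.barrier)
            res.to_frame().to_csv(out_dir / f"{stem}_profile.csv", index=False)
            scalars = res.scalars()
    else:
        params = config.build()
        result = iftp_solve(params)
        result.to_frame().to_csv(out_dir / f"{stem}_trajectory.csv", index=False)
        w = waiting_time(result)
        import pandas as pd

        pd.DataFrame({"s_bin": np.arange(1, params.N0 + 1), "w": w}).to_csv(
            out_dir / f"{stem}_waiting_time.csv", index=False)
        scalars = {"tau": result.tau, "tau_TP": result.tau_TP,
                   "tau_PP": result.tau_PP}

    provenance = {"config": config.to_dict(), "version": __version__}
    with open(out_dir / f"{stem}_result.json", "w") as fh:
        json.dump({"scalars": scalars, "provenance": provenance}, fh,
                  indent=2, default=float)
    return scalars
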