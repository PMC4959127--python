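"""Configuration, presets, unit handling and result serialization.

A model run is described by four blocks -- ``geometry``, ``material``,
``kernel`` and ``load`` -- plus a ``numerics`` block with quadrature and
time-grid settings.  Lengths may be given in mm or m and moduli in kPa,
MPa or Pa via per-block ``units`` tags; everything is converted to SI on
load.

The built-in preset ``"reference"`` is the human-incisor-like parameter
set the model was originally calibrated with: root height 13.0 mm, crest
minor semi-axis 3.9 mm, eccentricity 0.6, PDL thickness 0.229 mm, relaxed
modulus 680 kPa, Poisson ratio 0.49, and fractional kernel
``gamma = 0.35``, ``tau_sigma = 550 s``, ``nu_sigma = 1.3e3``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import RootGeometry
from .motion import LoadCase
from .stiffness import PDLMaterial
from .viscokernel import FractionalKernel, convert_creep_relax

__all__ = ["ModelConfig", "RunResult", "PRESETS", "load_config", "config_from_dict", "write_results"]

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6}
_PRESSURE_UNITS = {"Pa": 1.0, "kPa": 1e3, "MPa": 1e6}

PRESETS: dict[str, dict] = {
    "reference": {
        "geometry": {"h": 13.0, "b": 3.9, "e": 0.6, "delta": 0.229, "units": "mm"},
        "material": {"e_inf": 680.0, "nu": 0.49, "units": "kPa"},
        "kernel": {"gamma": 0.35, "tau_sigma": 550.0, "nu_sigma": 1.3e3},
        "load": {"force": [0.0, -2.0, 0.0], "point": [0.0, 0.0, 0.0]},
        "numerics": {},
    }
}

_DEFAULT_NUMERICS = {
    "n_r": 256,
    "n_phi": 256,
    "element": "projected",
    "t_min": 1e-6,
    "t_max": 300.0,
    "n_t": 600,
    "creep_form": "rabotnov",
}


@dataclass(frozen=True)
class ModelConfig:
    """Validated, SI-resolved model configuration."""

    geometry: RootGeometry
    material: PDLMaterial
    kernel: FractionalKernel
    load: LoadCase
    numerics: dict = field(default_factory=lambda: dict(_DEFAULT_NUMERICS))

    def to_dict(self) -> dict:
        k = self.kernel
        return {
            "geometry": {
                "h": self.geometry.h,
                "b": self.geometry.b,
                "e": self.geometry.e,
                "delta": self.geometry.delta,
                "units": "m",
            },
            "material": {"e_inf": self.material.e_inf, "nu": self.material.nu, "units": "Pa"},
            "kernel": {
                "gamma": k.gamma,
                "tau_sigma": k.tau_sigma,
                "nu_sigma": k.nu_sigma,
                "tau_eps": k.tau_eps,
                "nu_eps": k.nu_eps,
                "tol": k.tol,
                "n_max": k.n_max,
            },
            "load": {
                "force": list(self.load.f),
                "point": list(self.load.r_f),
                "moment": list(self.load.m_ext),
            },
            "numerics": dict(self.numerics),
        }


class ConfigError(ValueError):
    """Raised with the list of offending fields on schema violations."""


def _require(block: dict, names: list[str], where: str) -> list[str]:
    return [f"{where}.{n}" for n in names if n not in block]


def config_from_dict(raw: dict) -> ModelConfig:
    """Validate a raw (YAML/JSON-level) mapping and resolve units to SI."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping of blocks")
    missing = [b for b in ("geometry", "material", "kernel") if b not in raw]
    if missing:
        raise ConfigError(f"missing blocks: {', '.join(missing)}")

    geo = dict(raw["geometry"])
    errs = _require(geo, ["h", "b", "e", "delta"], "geometry")
    mat = dict(raw["material"])
    errs += _require(mat, ["e_inf", "nu"], "material")
    ker = dict(raw["kernel"])
    errs += _require(ker, ["gamma"], "kernel")
    if errs:
        raise ConfigError(f"missing fields: {', '.join(errs)}")

    lu = geo.pop("units", "m")
    if lu not in _LENGTH_UNITS:
        raise ConfigError(f"geometry.units: unknown length unit {lu!r}")
    scale = _LENGTH_UNITS[lu]
    geometry = RootGeometry(
        h=geo["h"] * scale, b=geo["b"] * scale, e=geo["e"], delta=geo["delta"] * scale
    )

    pu = mat.pop("units", "Pa")
    if pu not in _PRESSURE_UNITS:
        raise ConfigError(f"material.units: unknown pressure unit {pu!r}")
    material = PDLMaterial(e_inf=mat["e_inf"] * _PRESSURE_UNITS[pu], nu=mat["nu"])

    kernel = convert_creep_relax(
        FractionalKernel(
            gamma=ker["gamma"],
            tau_sigma=ker.get("tau_sigma"),
            nu_sigma=ker.get("nu_sigma"),
            tau_eps=ker.get("tau_eps"),
            nu_eps=ker.get("nu_eps"),
            tol=ker.get("tol", 1e-10),
            n_max=ker.get("n_max", 200),
        )
    )

    ld = dict(raw.get("load", {"force": [0.0, 0.0, 0.0], "point": [0.0, 0.0, 0.0]}))
    load = LoadCase(
        f=np.asarray(ld.get("force", [0.0, 0.0, 0.0]), dtype=float),
        r_f=np.asarray(ld.get("point", [0.0, 0.0, 0.0]), dtype=float) * scale,
        m_ext=np.asarray(ld.get("moment", [0.0, 0.0, 0.0]), dtype=float),
    )

    numerics = dict(_DEFAULT_NUMERICS)
    numerics.update(raw.get("numerics", {}))
    if numerics["element"] not in ("projected", "true"):
        raise ConfigError(f"numerics.element must be 'projected' or 'true'")
    return ModelConfig(geometry=geometry, material=material, kernel=kernel, load=load, numerics=numerics)


def load_config(path_or_preset: str | Path) -> ModelConfig:
    """Load a YAML/JSON configuration file, or a named built-in preset."""
    key = str(path_or_preset)
    if key in PRESETS:
        return config_from_dict(PRESETS[key])
    path = Path(path_or_preset)
    if not path.exists():
        raise ConfigError(f"no such config file or preset: {key!r} (presets: {sorted(PRESETS)})")
    text = path.read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if raw is None:
        raise ConfigError(f"empty configuration file: {path}")
    return config_from_dict(raw)


@dataclass
class RunResult:
    """Inputs echo (SI), outputs and provenance of one computation."""

    inputs: dict
    outputs: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"inputs": self.inputs, "outputs": self.outputs, "provenance": self.provenance}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(result: RunResult, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a result deterministically (sorted keys, full float precision).

    ``fmt="csv"`` expects ``result.outputs["table"]`` to be a mapping of
    equal-length columns; metadata goes into a commented header.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_jsonify(result.to_dict()), indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        import pandas as pd

        table = result.outputs.get("table")
        if table is None:
            raise ValueError("csv output requires result.outputs['table']")
        header = "".join(
            f"# {k}: {json.dumps(_jsonify(v), sort_keys=True)}\n"
            for k, v in sorted(result.provenance.items())
        )
        df = pd.DataFrame(table)
        path.write_text(header + df.to_csv(index=False, float_format="%.17g"))
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path
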