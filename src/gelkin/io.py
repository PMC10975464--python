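"""File I/O: the curve CSV dialect, FitResult JSON, and config loading.

Curve files are plain CSV with leading ``# key: value`` comment lines for
metadata, a mandatory ``t_s,eta_mPas`` header, and one sample per row.
Numbers are serialized with Python's shortest-roundtrip repr so that
``read(write(curve)) == curve`` exactly.  One curve per file; multi-curve
scenarios get numbered files plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path

import numpy as np

from .errors import CurveParseError, CurveValidationError, DomainError
from .fitting import FitResult, ViscosityCurve
from .kinetics import EinsteinMap, FluidProperties, LogisticParams

__all__ = [
    "read_curve",
    "write_curve",
    "write_curves",
    "fit_result_to_dict",
    "write_fit_result",
    "load_scenario_spec",
    "load_sim_config",
]

log = logging.getLogger("gelkin")

_HEADER = "t_s,eta_mPas"
_META_KEYS = ("temperature_C", "concentration_pct", "rpm", "label")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_curve(curve: ViscosityCurve, path) -> None:
    """Serialize one curve in the package CSV dialect."""
    lines = []
    for key in _META_KEYS:
        if key in curve.meta and curve.meta[key] is not None:
            lines.append(f"# {key}: {curve.meta[key]}")
    for key in sorted(curve.meta):
        if key not in _META_KEYS and curve.meta[key] is not None:
            lines.append(f"# {key}: {curve.meta[key]}")
    lines.append(_HEADER)
    for t, eta in zip(curve.t, curve.eta):
        lines.append(f"{_fmt(t)},{_fmt(eta)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce_meta(key: str, raw: str):
    if key in ("temperature_C", "concentration_pct", "rpm", "nu_per_s"):
        try:
            return float(raw)
        except ValueError:
            return raw
    if key == "cycle":
        try:
            return int(raw)
        except ValueError:
            return raw
    return raw


def read_curve(path) -> ViscosityCurve:
    """Parse and validate a curve file.

    Missing metadata keys default to ``None`` with a logged warning; malformed
    rows raise :class:`CurveParseError` with the line number; structural
    problems (non-increasing times, negative viscosities) surface as
    :class:`CurveValidationError`.
    """
    path = Path(path)
    meta: dict = {}
    times: list[float] = []
    etas: list[float] = []
    saw_header = False
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, raw = body.partition(":")
                    meta[key.strip()] = _coerce_meta(key.strip(), raw.strip())
                continue
            if not saw_header:
                if line.replace(" ", "") != _HEADER:
                    raise CurveParseError(
                        f"expected header {_HEADER!r}, got {line!r}", line_no
                    )
                saw_header = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise CurveParseError(f"expected 2 fields, got {len(fields)}", line_no)
            try:
                times.append(float(fields[0]))
                etas.append(float(fields[1]))
            except ValueError as exc:
                raise CurveParseError(f"unparseable number: {exc}", line_no) from exc
    if not saw_header:
        raise CurveParseError("file has no header row", None)
    if not times:
        raise CurveParseError("file has no data rows", None)
    for key in _META_KEYS:
        if key not in meta:
            log.warning("%s: metadata key %r missing; defaulting to None", path, key)
            meta[key] = None
    return ViscosityCurve(t=np.array(times), eta=np.array(etas), meta=meta)


def write_curves(curves, directory, stem: str = "curve") -> list[Path]:
    """Write numbered curve files plus a manifest.json; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, curve in enumerate(curves, start=1):
        p = directory / f"{stem}_{i:02d}.csv"
        write_curve(curve, p)
        paths.append(p)
    manifest = {
        "files": [p.name for p in paths],
        "labels": [c.meta.get("label") for c in curves],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def fit_result_to_dict(result: FitResult) -> dict:
    """JSON-ready FitResult with units in the field names."""
    out = {
        "eta_base_mPas": result.eta_base,
        "eta_plateau_mPas": result.eta_plateau,
        "k1_per_s": result.k1_hat,
        "s0_ratio": result.s0,
        "regime": result.regime,
        "t_onset_s": result.t_onset,
        "rmse_mPas": result.rmse,
    }
    if result.params is not None:
        out["params"] = {
            "k1_per_s": result.params.k1,
            "k_minus_per_s_per_fraction": result.params.k_minus,
            "B0_fraction": result.params.B0,
            "B_inf_fraction": result.params.B_inf,
        }
    return out


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2) + "\n")


def _logistic_params_from(section: dict) -> LogisticParams:
    if "B_inf" in section and "k_minus" not in section:
        return LogisticParams.from_equilibrium(
            k1=section["k1"], B_inf=section["B_inf"], B0=section["B0"]
        )
    return LogisticParams(
        k1=section["k1"],
        k_minus=section["k_minus"],
        B0=section["B0"],
        B_inf=section.get("B_inf"),
    )


def load_scenario_spec(path):
    """Read a ScenarioSpec from a TOML file with [params] and [einstein] sections."""
    from .synth import ScenarioSpec, preset_spec

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        if "preset" in cfg:
            name = cfg.pop("preset")
            kind = cfg.pop("kind", "single_curve")
            return preset_spec(name, kind=kind, **cfg)
        params = _logistic_params_from(cfg.pop("params"))
        einstein = EinsteinMap(**cfg.pop("einstein"))
        if "nu_pair" in cfg:
            cfg["nu_pair"] = tuple(cfg["nu_pair"])
        return ScenarioSpec(params=params, einstein=einstein, **cfg)
    except (KeyError, TypeError) as exc:
        raise DomainError(f"invalid scenario config {path}: {exc}") from exc


def load_sim_config(path):
    """Read a ripening SimConfig from a TOML file with a [fluid] section."""
    from .ripening import SimConfig, standard_fluid

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    try:
        fluid = FluidProperties(**cfg.pop("fluid")) if "fluid" in cfg else standard_fluid()
        if "asym_range" in cfg:
            cfg["asym_range"] = tuple(cfg["asym_range"])
        return SimConfig(fluid=fluid, **cfg)
    except (KeyError, TypeError) as exc:
        raise DomainError(f"invalid sim config {path}: {exc}") from exc
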