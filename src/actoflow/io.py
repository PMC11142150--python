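"""Delimited-text I/O for profiles, stresses, reports and run configs.

Profiles and stress tables are plain CSV/TSV with '#'-prefixed comment lines
carrying provenance (parameters, seed, version); an optional header row is
recognized by a non-numeric first field.  Reports are flat key-value text;
run configurations are YAML with unknown keys rejected (fail-fast).
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitting import FitResult, ObservedProfile
from .solver import FlowSummary, StressDecomposition, VelocityProfile

__all__ = [
    "read_profile",
    "write_profile",
    "write_stresses",
    "write_report",
    "write_outputs",
    "RunConfig",
    "read_config",
    "ProfileParseError",
]


class ProfileParseError(ValueError):
    """A profile file could not be parsed; the message names the line."""


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def read_profile(path: str | Path) -> ObservedProfile:
    """Read a (position, velocity[, sd]) table from delimited text.

    Comma, tab or whitespace delimited; '#' comments ignored; a header row
    is detected by a non-numeric first field.
    """
    path = Path(path)
    rows: list[list[float]] = []
    delim: str | None = None
    header_skipped = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if delim is None:
                delim = _detect_delimiter(line)
            fields = [f for f in line.split(delim) if f.strip()]
            try:
                vals = [float(f) for f in fields]
            except ValueError:
                if not header_skipped and not rows:
                    header_skipped = True
                    continue
                raise ProfileParseError(
                    f"{path}:{lineno}: non-numeric entry in {line!r}"
                ) from None
            if len(vals) < 2:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise ProfileParseError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], dtype=float)
    if not np.all(np.isfinite(data)):
        bad = int(np.argwhere(~np.isfinite(data))[0][0])
        raise ProfileParseError(f"{path}: non-finite entry in data row {bad + 1}")
    pos, vel = data[:, 0], data[:, 1]
    if not np.all(np.diff(pos) > 0):
        bad = int(np.argmax(np.diff(pos) <= 0))
        raise ProfileParseError(
            f"{path}: positions not strictly increasing at data row {bad + 2}"
        )
    sd = data[:, 2] if ncol >= 3 else None
    return ObservedProfile(positions=pos, velocities=vel, sd=sd,
                           provenance={"path": str(path)})


def _provenance_lines(meta: dict | None) -> list[str]:
    lines = [f"# actoflow v{__version__}",
             f"# written: {datetime.datetime.now().isoformat(timespec='seconds')}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_profile(profile: VelocityProfile | ObservedProfile, path: str | Path,
                  meta: dict | None = None) -> Path:
    """Write a profile as CSV with provenance comments."""
    path = Path(path)
    lines = _provenance_lines(meta)
    lines.append("position,velocity")
    for p, v in zip(profile.positions, profile.velocities):
        lines.append(f"{p:.10g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_stresses(dec: StressDecomposition, path: str | Path,
                   meta: dict | None = None) -> Path:
    """Write a stress decomposition table as CSV with provenance comments."""
    path = Path(path)
    lines = _provenance_lines(meta)
    lines.append("position,motor_stress,viscous_stress,traction,residual")
    for p, m, v, t, r in zip(dec.positions, dec.motor, dec.viscous,
                             dec.traction, dec.residual):
        lines.append(f"{p:.10g},{m:.10g},{v:.10g},{t:.10g},{r:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _flatten_report(result: FitResult) -> dict:
    out = {
        "x_cz": result.x_cz,
        "sigma": result.sigma,
        "xi_ratio": result.xi_ratio,
        "force_scale": result.force_scale,
        "mu_ratio": result.mu_ratio,
        "lambda": result.lam,
        "rms_residual": result.rms_residual,
        "n_iterations": result.n_iterations,
        "converged": result.converged,
        "mu_lower_bound": result.mu_lower_bound,
    }
    if result.mu_lower_bound_value is not None:
        out["mu_lower_bound_value"] = result.mu_lower_bound_value
    for k, v in result.diagnostics.items():
        if isinstance(v, (int, float, bool, str)):
            out[f"diag_{k}"] = v
    return out


def write_report(result: FitResult | FlowSummary | dict, path: str | Path,
                 meta: dict | None = None) -> Path:
    """Write a structured key-value report with provenance comments."""
    path = Path(path)
    if isinstance(result, FitResult):
        items = _flatten_report(result)
    elif isinstance(result, FlowSummary):
        items = {k: getattr(result, k) for k in
                 ("v_rear", "v_front", "plateau_left", "plateau_right",
                  "peak_retrograde", "com_velocity", "net_traction")}
    else:
        items = dict(result)
    lines = _provenance_lines(meta)
    for k, v in items.items():
        lines.append(f"{k} = {v:.10g}" if isinstance(v, float) else f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_outputs(outdir: str | Path, profile: VelocityProfile,
                  stresses: StressDecomposition | None = None,
                  summary: FlowSummary | FitResult | dict | None = None,
                  meta: dict | None = None) -> list[Path]:
    """Write the standard output bundle (profile, stresses, summary report).

    Byte-deterministic for fixed inputs apart from the timestamp line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = [write_profile(profile, outdir / "profile.csv", meta)]
    if stresses is not None:
        written.append(write_stresses(stresses, outdir / "stresses.csv", meta))
    if summary is not None:
        written.append(write_report(summary, outdir / "summary.txt", meta))
    return written


# ---------------------------------------------------------------------------
# run configuration

_MODES = ("simulate", "fit", "synth", "preset")
_TOP_KEYS = {"mode", "params", "grid", "noise", "output", "seed",
             "velocity_unit", "profile"}
_PARAM_KEYS = {"preset", "sigma", "x_cz", "L", "xi_ratio", "force_scale",
               "mu_ratio", "amplitude", "xi_left", "xi_right", "mu",
               "smooth_width"}
_GRID_KEYS = {"n_grid"}
_NOISE_KEYS = {"sd", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (one mode per config)."""

    mode: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    output: str | None = None
    seed: int = 0
    velocity_unit: str = "um/min"
    profile: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        if self.mode == "fit":
            if not self.profile:
                raise ValueError("fit mode requires a 'profile' path")
            if not Path(self.profile).exists():
                raise FileNotFoundError(f"profile file not found: {self.profile}")


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {name} keys: {sorted(unknown)}")


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    _check_keys(raw.get("params", {}) or {}, _PARAM_KEYS, "params")
    _check_keys(raw.get("grid", {}) or {}, _GRID_KEYS, "grid")
    _check_keys(raw.get("noise", {}) or {}, _NOISE_KEYS, "noise")
    return RunConfig(
        mode=raw.get("mode", ""),
        params=raw.get("params", {}) or {},
        grid=raw.get("grid", {}) or {},
        noise=raw.get("noise", {}) or {},
        output=raw.get("output"),
        seed=raw.get("seed", 0),
        velocity_unit=raw.get("velocity_unit", "um/min"),
        profile=raw.get("profile"),
    )
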