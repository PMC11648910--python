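"""File formats and configuration.

Profile files are tab-separated text with '#'-prefixed header lines
carrying the acquisition metadata, then columns ``offset_hz``,
``intensity`` and (optionally) ``error`` -- one file per (spin, B1).
Configuration and ground-truth sidecars are TOML (read with the standard
library; written with a small emitter so the package stays text-only).
Populations in files are always fractions, never percent.
"""

from __future__ import annotations

import json
import sys
import tomllib
from pathlib import Path

import numpy as np

from foldcest.bloch import CESTExperiment, CESTProfile

__all__ = [
    "read_profile",
    "read_profiles",
    "write_profile",
    "write_profiles",
    "read_toml",
    "write_toml",
    "write_dataset",
    "RunConfig",
]

_HEADER_KEYS = {
    "spin_id": str,
    "nucleus": str,
    "b1_hz": float,
    "t_ex_s": float,
    "spectrometer_1h_freq_mhz": float,
    "carrier_ppm": float,
    "temperature_c": float,
}
_OPTIONAL_HEADER = {"temperature_c": 25.0}


def write_profile(profile: CESTProfile, path) -> None:
    """Write one profile in the canonical TSV dialect (newline = '\\n')."""
    exp = profile.experiment
    lines = [
        f"# spin_id: {profile.spin_id}",
        f"# nucleus: {exp.nucleus}",
        f"# b1_hz: {exp.b1:.10g}",
        f"# t_ex_s: {exp.t_ex:.10g}",
        f"# spectrometer_1h_freq_mhz: {exp.spectrometer_1h_freq:.10g}",
        f"# carrier_ppm: {exp.carrier:.10g}",
        f"# temperature_c: {exp.temperature:.10g}",
    ]
    has_err = profile.errors is not None
    lines.append("offset_hz\tintensity" + ("\terror" if has_err else ""))
    for i, off in enumerate(exp.offsets):
        row = f"{off:.10g}\t{profile.intensities[i]:.10g}"
        if has_err:
            row += f"\t{profile.errors[i]:.10g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_profile(path) -> CESTProfile:
    """Parse one canonical profile TSV; round-trips with write_profile."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        elif not header_seen and line.startswith("offset_hz"):
            header_seen = True
        else:
            rows.append([float(x) for x in line.split("\t")])

    parsed = {}
    for key, cast in _HEADER_KEYS.items():
        if key not in meta:
            if key in _OPTIONAL_HEADER:
                parsed[key] = _OPTIONAL_HEADER[key]
                continue
            raise ValueError(f"{path}: missing mandatory header key {key!r}")
        parsed[key] = cast(meta[key])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.array(rows)
    exp = CESTExperiment(
        b1=parsed["b1_hz"], t_ex=parsed["t_ex_s"],
        spectrometer_1h_freq=parsed["spectrometer_1h_freq_mhz"],
        carrier=parsed["carrier_ppm"], offsets=data[:, 0],
        nucleus=parsed["nucleus"], temperature=parsed["temperature_c"])
    errors = data[:, 2] if data.shape[1] > 2 else None
    return CESTProfile(exp, parsed["spin_id"], data[:, 1], errors)


def read_profiles(paths) -> list[CESTProfile]:
    return [read_profile(p) for p in sorted(Path(p) for p in paths)]


def write_profiles(profiles: list[CESTProfile], out_dir) -> list[Path]:
    """Write profiles as <spin>_b1_<value>.tsv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for prof in profiles:
        path = out_dir / f"{prof.spin_id}_b1_{prof.experiment.b1:g}.tsv"
        write_profile(prof, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# TOML

def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float, np.integer, np.floating)):
        return repr(float(value)) if isinstance(value, (float, np.floating)) \
            else str(int(value))
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value).__name__} to TOML")


def write_toml(data: dict, path) -> None:
    """Emit a nested dict of scalars/lists as TOML (tables one level deep+)."""
    lines: list[str] = []

    def emit(table: dict, prefix: str):
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix and (scalars or not subtables):
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        if scalars:
            lines.append("")
        for k, v in subtables.items():
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(data, "")
    Path(path).write_text("\n".join(lines).rstrip("\n") + "\n", encoding="utf-8")


def write_dataset(profiles: list[CESTProfile], truth: dict, out_dir) -> None:
    """Write a synthetic dataset: profile TSVs plus a truth.toml sidecar."""
    out_dir = Path(out_dir)
    write_profiles(profiles, out_dir)
    write_toml(truth, out_dir / "truth.toml")


# ---------------------------------------------------------------------------
# Run configuration

class RunConfig:
    """Validated fit configuration loaded from TOML.

    Recognized keys (all under a [fit] table):
      level (required), truth (path to a truth/params TOML for initials),
      perturb (relative perturbation applied to initial kinetics),
      seed, n_starts, vary_relaxation.
    Unknown keys are rejected.
    """

    KNOWN = {"level", "truth", "perturb", "seed", "n_starts",
             "vary_relaxation"}

    def __init__(self, level: str, truth: str | None = None,
                 perturb: float = 0.0, seed: int = 0, n_starts: int = 5,
                 vary_relaxation: bool = False, base_dir: Path | None = None):
        if level not in {"two_state", "three_state", "four_state"}:
            raise ValueError(f"unknown model level {level!r}")
        if perturb < 0 or perturb >= 1:
            raise ValueError("perturb must be in [0, 1)")
        self.level = level
        self.truth = truth
        self.perturb = perturb
        self.seed = seed
        self.n_starts = n_starts
        self.vary_relaxation = vary_relaxation
        self.base_dir = base_dir or Path(".")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = read_toml(path)
        fit = data.get("fit", data)
        unknown = set(fit) - cls.KNOWN
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "level" not in fit:
            raise ValueError(f"{path}: missing required key 'level'")
        return cls(base_dir=Path(path).parent, **fit)

    def truth_path(self) -> Path:
        if self.truth is None:
            raise ValueError("config has no 'truth' entry")
        p = Path(self.truth)
        return p if p.is_absolute() else self.base_dir / p


def write_manifest(path, **entries) -> None:
    """Run manifest: inputs, seeds, versions -- written alongside outputs."""
    import foldcest

    manifest = {
        "foldcest_version": foldcest.__version__,
        "python": sys.version.split()[0],
        **entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
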