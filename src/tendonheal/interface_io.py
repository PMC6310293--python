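"""Configuration, seeded RNG management, CSV/manifest I/O and fixtures.

CSV dialect: comma separated, '.' decimal, metadata in '#'-prefixed header
lines (``# key: value``).  Angles are degrees; times carry a unit suffix in
the column name (``time_s`` at cell scale, ``time_h``/``time_days`` at
tissue scale).
"""

from __future__ import annotations

import datetime
import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics_strain import StrainProfile
from .stressfiber_alignment import SFDistribution
from .wound_abm import ScarMetrics

__all__ = [
    "load_config", "stage_rng", "stage_seed",
    "read_strain_profile", "write_strain_profile",
    "read_sf_distribution", "write_sf_distribution",
    "read_scar_metrics", "write_scar_metrics",
    "write_manifest", "read_manifest",
    "generate_canonical_profiles", "CANONICAL_OPERATING_POINTS",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Packaged default configuration, optionally deep-merged with a user
    YAML/JSON file."""
    text = (importlib.resources.files("tendonheal") / "data"
            / "default_config.yaml").read_text()
    cfg = yaml.safe_load(text)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text())
        if user:
            cfg = _deep_merge(cfg, user)
    return cfg


# --------------------------------------------------------------------------
# seeded RNG management
# --------------------------------------------------------------------------

_STAGE_IDS = {"kinematics": 1, "stressfiber": 2, "synthesis": 3,
              "abm": 4, "protocols": 5, "fixtures": 6}


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the run seed."""
    if stage not in _STAGE_IDS:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(run_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def stage_rng(run_seed: int, stage: str) -> np.random.Generator:
    """A stage-local Generator on an independent substream of the run seed."""
    return np.random.default_rng(stage_seed(run_seed, stage))


# --------------------------------------------------------------------------
# CSV readers/writers
# --------------------------------------------------------------------------

def _write_csv(path: Path, frame: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        else:
            break
    from io import StringIO
    frame = pd.read_csv(StringIO("".join(lines[body_start:])))
    return frame, meta


def _schema_error(path, column, row, message) -> ValueError:
    return ValueError(f"{path}: column {column!r}, row {row}: {message}")


def write_strain_profile(path: str | Path, profile: StrainProfile) -> None:
    frame = pd.DataFrame({"time_s": profile.times, "strain": profile.strain,
                          "level": profile.level})
    _write_csv(Path(path), frame,
               {"kind": "strain_profile", "level": profile.level,
                "period_s": profile.period})


def read_strain_profile(path: str | Path) -> StrainProfile:
    frame, meta = _read_csv(Path(path))
    for col in ("time_s", "strain"):
        if col not in frame.columns:
            raise _schema_error(path, col, "-", "missing column")
        bad = ~np.isfinite(frame[col].to_numpy(dtype=float))
        if bad.any():
            raise _schema_error(path, col, int(np.flatnonzero(bad)[0]),
                                "non-finite value")
    level = meta.get("level", str(frame.get("level", pd.Series(["tendon"])).iloc[0]))
    if level not in ("tendon", "cell"):
        raise _schema_error(path, "level", "-", f"invalid level {level!r}")
    period = meta.get("period_s")
    period = None if period in (None, "None", "") else float(period)
    return StrainProfile(frame["time_s"].to_numpy(dtype=float),
                         frame["strain"].to_numpy(dtype=float),
                         level=level, period=period)


def write_sf_distribution(path: str | Path, dist: SFDistribution,
                          meta: dict | None = None) -> None:
    frame = pd.DataFrame({"theta_deg": dist.bin_centers,
                          "probability": dist.probability})
    md = {"kind": "sf_distribution",
          "order_parameter": f"{dist.order_parameter:.12g}",
          "reference_strain": f"{dist.reference_strain:.12g}"}
    if meta:
        md.update(meta)
    _write_csv(Path(path), frame, md)


def read_sf_distribution(path: str | Path) -> SFDistribution:
    frame, meta = _read_csv(Path(path))
    for col in ("theta_deg", "probability"):
        if col not in frame.columns:
            raise _schema_error(path, col, "-", "missing column")
    prob = frame["probability"].to_numpy(dtype=float)
    if (prob < 0).any():
        raise _schema_error(path, "probability",
                            int(np.flatnonzero(prob < 0)[0]),
                            "negative probability")
    return SFDistribution(frame["theta_deg"].to_numpy(dtype=float), prob,
                          reference_strain=float(meta.get("reference_strain", 0.0)))


def write_scar_metrics(path: str | Path, metrics: list[ScarMetrics],
                       meta: dict | None = None) -> None:
    frame = pd.DataFrame([{
        "time_days": m.time_days,
        "area_fraction": m.collagen_area_fraction,
        "mean_angle_deg": m.mean_angle_deg,
        "order_parameter": m.order_parameter,
        "total_collagen_au": m.total_collagen,
        "n_cells": m.n_cells,
    } for m in metrics])
    _write_csv(Path(path), frame, {"kind": "scar_metrics", **(meta or {})})


def read_scar_metrics(path: str | Path) -> list[ScarMetrics]:
    frame, _ = _read_csv(Path(path))
    required = ("time_days", "area_fraction", "mean_angle_deg",
                "order_parameter", "total_collagen_au", "n_cells")
    for col in required:
        if col not in frame.columns:
            raise _schema_error(path, col, "-", "missing column")
    neg = frame["area_fraction"].to_numpy(dtype=float) < 0
    if neg.any():
        raise _schema_error(path, "area_fraction",
                            int(np.flatnonzero(neg)[0]), "negative density")
    return [ScarMetrics(r.time_days, r.area_fraction, r.mean_angle_deg,
                        r.order_parameter, r.total_collagen_au,
                        int(r.n_cells))
            for r in frame.itertuples(index=False)]


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def write_manifest(path: str | Path, *, seed: int, parameters: dict,
                   inputs: dict | None = None, outputs: dict | None = None) -> dict:
    """Emit the run manifest (parameters + seed + file paths + timestamp).

    Re-running the same stages from the manifest's parameters and seed
    reproduces the outputs bit-identically.
    """
    from . import __version__
    manifest = {
        "tendonheal_version": __version__,
        "seed": int(seed),
        "parameters": parameters,
        "inputs": inputs or {},
        "outputs": outputs or {},
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# canonical cell-strain fixtures
# --------------------------------------------------------------------------

#: Printed operating points of the four conditions at cell level:
#: (min strain, max strain, mean strain over one gait cycle).
CANONICAL_OPERATING_POINTS = {
    "unrep-unloaded": (0.002, 0.002, 0.002),
    "unrep-loaded": (0.009, 0.043, 0.030),
    "rep-unloaded": (0.012, 0.012, 0.012),
    "rep-loaded": (0.011, 0.075, 0.049),
}


def _plateau_waveform(lo: float, hi: float, mean: float, period: float = 1.0,
                      n: int = 2001, ramp_fraction: float = 0.05) -> np.ndarray:
    """Asymmetric stance/swing plateau waveform with cosine transitions whose
    high-plateau duty is solved so the cycle mean is exact."""
    if hi == lo:
        return np.full(n, lo)
    c = ramp_fraction
    a = (mean - lo) / (hi - lo) - c
    b = 1.0 - a - 2 * c
    if a <= 0 or b <= 0:
        raise ValueError("mean incompatible with plateau waveform shape")
    phi = np.linspace(0.0, 1.0, n)
    out = np.empty(n)
    seg1, seg2, seg3 = a, a + c, a + c + b
    for i, f in enumerate(phi):
        if f < seg1:
            out[i] = hi
        elif f < seg2:
            x = (f - seg1) / c
            out[i] = lo + (hi - lo) * 0.5 * (1 + np.cos(np.pi * x))
        elif f < seg3:
            out[i] = lo
        else:
            x = (f - seg3) / c
            out[i] = lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * x))
    return out


def generate_canonical_profiles(period: float = 1.0,
                                n: int = 2001) -> dict[str, StrainProfile]:
    """Cell-level strain fixtures matching the four printed operating points.

    Static conditions are constant traces; loaded conditions are periodic
    plateau waveforms (stance high / swing low with smooth transitions)
    whose min, max and cycle mean match the printed values, so downstream
    stages can be exercised independently of the musculo-tendon stage.
    """
    t = np.linspace(0.0, period, n)
    out = {}
    for name, (lo, hi, mean) in CANONICAL_OPERATING_POINTS.items():
        if lo == hi:
            strain = np.full(n, lo)
        else:
            strain = _plateau_waveform(lo, hi, mean, period, n)
        out[name] = StrainProfile(t, strain, level="cell", period=period)
    return out
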