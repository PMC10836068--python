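"""File formats and run configuration.

Decay cubes travel as HDF5 (dataset ``counts`` plus acquisition metadata
attributes), image maps as single-channel 32-bit float TIFF with a JSON
sidecar recording configuration and seed, tabular outputs as CSV with
9-significant-digit floats, and run configuration as a YAML file with one
block per pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import AcquisitionConfig
from .errors import ConfigurationError
from .pixelfit import FitOptions
from .synth import DecayCube, ParameterMaps

FLOAT_FORMAT = "%.9g"
MAP_FIELDS = ("a1", "a2", "tau1", "tau2", "tau_m", "intensity")


# ---------------------------------------------------------------------------
# HDF5 decay cubes

def save_cube(cube: DecayCube, path: Path | str, seed: Optional[int] = None,
              scene_config: Optional[dict] = None) -> None:
    """Write a decay cube to HDF5 with its acquisition metadata."""
    cube.validate()
    counts = cube.counts
    dtype = np.uint16 if counts.max() < 2**16 else np.uint32
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts.astype(dtype),
                         compression="gzip", compression_opts=4)
        f.create_dataset("time_axis_ns", data=cube.time_axis_ns)
        f.attrs["repetition_rate_hz"] = cube.acquisition.repetition_rate_hz
        f.attrs["bin_width_ns"] = cube.acquisition.bin_width_ns
        if seed is not None:
            f.attrs["seed"] = int(seed)
        config = {"acquisition": cube.acquisition.to_dict()}
        if scene_config is not None:
            config["scene"] = scene_config
        f.attrs["config_json"] = json.dumps(config, sort_keys=True)


def load_cube(path: Path | str) -> DecayCube:
    """Read a decay cube written by :func:`save_cube`."""
    with h5py.File(path, "r") as f:
        counts = f["counts"][()]
        time_axis = f["time_axis_ns"][()]
        config = json.loads(f.attrs["config_json"])
    acq = AcquisitionConfig.from_dict(config["acquisition"])
    cube = DecayCube(counts=counts, time_axis_ns=time_axis, acquisition=acq)
    cube.validate()
    return cube


# ---------------------------------------------------------------------------
# TIFF maps

def save_image(image: np.ndarray, path: Path | str) -> None:
    """Write one single-channel 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_image(path: Path | str) -> np.ndarray:
    return tifffile.imread(str(path))


def save_maps(maps: ParameterMaps, out_dir: Path | str, prefix: str = "",
              sidecar: Optional[dict] = None) -> dict[str, Path]:
    """Write one TIFF per parameter map plus a JSON sidecar.

    Returns the mapping from field name to written path. ``fit_ok`` is
    written as a 0/1 mask TIFF when present.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in MAP_FIELDS:
        path = out_dir / f"{prefix}{name}.tif"
        save_image(getattr(maps, name), path)
        written[name] = path
    if maps.fit_ok is not None:
        path = out_dir / f"{prefix}fit_ok.tif"
        save_image(maps.fit_ok.astype(np.float32), path)
        written["fit_ok"] = path
    if maps.objective_value is not None:
        path = out_dir / f"{prefix}objective.tif"
        save_image(maps.objective_value, path)
        written["objective"] = path
    if sidecar is not None:
        with open(out_dir / f"{prefix}maps.json", "w") as f:
            json.dump(sidecar, f, indent=2, sort_keys=True)
    return written


def load_maps(out_dir: Path | str, prefix: str = "") -> ParameterMaps:
    """Reassemble ParameterMaps from the TIFFs written by :func:`save_maps`."""
    out_dir = Path(out_dir)
    arrays = {name: load_image(out_dir / f"{prefix}{name}.tif").astype(float)
              for name in MAP_FIELDS}
    fit_ok_path = out_dir / f"{prefix}fit_ok.tif"
    fit_ok = (load_image(fit_ok_path).astype(bool)
              if fit_ok_path.exists() else None)
    obj_path = out_dir / f"{prefix}objective.tif"
    objective = load_image(obj_path).astype(float) if obj_path.exists() else None
    return ParameterMaps(**arrays, fit_ok=fit_ok, objective_value=objective)


def maps_to_table(maps: ParameterMaps) -> pd.DataFrame:
    """Per-pixel long-format table (row, col, a1, tau1, tau2, tau_m, fit_ok)."""
    rows, cols = np.indices(maps.shape)
    fit_ok = (maps.fit_ok if maps.fit_ok is not None
              else np.isfinite(maps.a1))
    return pd.DataFrame({
        "row": rows.ravel(), "col": cols.ravel(),
        "a1": maps.a1.ravel(), "tau1": maps.tau1.ravel(),
        "tau2": maps.tau2.ravel(), "tau_m": maps.tau_m.ravel(),
        "fit_ok": fit_ok.ravel().astype(int),
    })


def write_table(table: pd.DataFrame, path: Path | str) -> None:
    """CSV with the package-wide 9-significant-digit float convention."""
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class UnitSpec:
    """One simulated fish/lesion in a pipeline run."""

    unit: str
    group: str
    organ: str = ""
    scene: str = "tumor"  # "tumor" | "uniform" | "bimodal"
    a1_mean: float = 0.7
    a1_sd: float = 0.03
    a1_means: tuple[float, float] = (0.55, 0.75)
    tau1: float = 0.3
    tau2: float = 2.5


@dataclass
class PipelineConfig:
    """Validated configuration for a full simulate-fit-analyze run."""

    seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    threshold_rule: object = "otsu"
    analysis_field: str = "a1"
    units: list[UnitSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.analysis_field not in ("a1", "tau_m"):
            raise ConfigurationError("analysis field must be 'a1' or 'tau_m'")
        labels = [u.unit for u in self.units]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("unit labels must be unique")
        for u in self.units:
            if not 0.0 < u.a1_mean < 1.0:
                raise ConfigurationError(
                    f"unit {u.unit!r}: a1_mean outside (0, 1)")
            if u.scene not in ("tumor", "uniform", "bimodal"):
                raise ConfigurationError(
                    f"unit {u.unit!r}: unknown scene kind {u.scene!r}")


def _parse_threshold(block: dict | str) -> object:
    if block in (None, "otsu") or block == {"rule": "otsu"}:
        return "otsu"
    rule = block["rule"]
    if rule == "otsu":
        return "otsu"
    if rule == "fixed":
        return ("fixed", float(block["value"]))
    if rule == "quantile":
        return ("quantile", float(block["q"]))
    raise ConfigurationError(f"unknown threshold rule {rule!r}")


def load_config(path: Path | str) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration.

    Every block is validated against its stage's type invariants before
    any compute runs; a bad acquisition or fit block fails here.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    try:
        acq = AcquisitionConfig.from_dict(raw.get("acquisition", {}))
        fit = FitOptions(**raw.get("fit", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc
    units = []
    for u in raw.get("units", []):
        u = dict(u)
        if "a1_means" in u:
            u["a1_means"] = tuple(u["a1_means"])
        units.append(UnitSpec(**u))
    analysis = raw.get("analysis", {})
    config = PipelineConfig(
        seed=int(raw.get("seed", 0)), acquisition=acq, fit=fit,
        threshold_rule=_parse_threshold(raw.get("threshold", "otsu")),
        analysis_field=analysis.get("field", "a1"), units=units)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Run manifests

MANIFEST_COLUMNS = ["unit", "group", "organ", "cube_path", "egfp_path",
                    "mcherry_path", "seed"]


def read_manifest(path: Path | str) -> pd.DataFrame:
    """Read and validate a run manifest CSV.

    Unit labels must be unique and every referenced file must exist; path
    resolution happens here, before any compute.
    """
    manifest = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ConfigurationError(
            f"manifest missing columns: {sorted(missing_cols)}")
    if manifest["unit"].duplicated().any():
        raise ConfigurationError("manifest unit labels must be unique")
    base = Path(path).parent
    for col in ("cube_path", "egfp_path", "mcherry_path"):
        for p in manifest[col]:
            resolved = (base / p) if not Path(p).is_absolute() else Path(p)
            if not resolved.exists():
                raise ConfigurationError(f"manifest path not found: {p}")
    return manifest
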