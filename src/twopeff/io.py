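"""Readers and writers for traces, manifests, laser tables and reports.

All tabular data is plain CSV with a header row; nested summaries are JSON.
Pulse-trace files carry their units in the column names (``time_fs`` /
``power_au`` style); internally everything is SI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from ._util import check_uniform_grid
from .efficiency import EfficiencyResult, LaserRecord
from .images import SpotImage
from .pulses import PulseTrace

log = logging.getLogger("twopeff")

__all__ = [
    "StudyConfig",
    "read_pulse_trace",
    "write_pulse_trace",
    "read_laser_table",
    "read_spot_manifest",
    "write_report",
]

_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9, "ps": 1e-12, "fs": 1e-15}
# Arbitrary-unit powers ("au") are accepted: downstream fluorescence
# prediction renormalizes the amplitude anyway.
_POWER_UNITS = {"w": 1.0, "mw": 1e-3, "uw": 1e-6, "nw": 1e-9, "kw": 1e3, "au": 1.0}

_MANIFEST_COLUMNS = (
    "path",
    "laser_label",
    "session_id",
    "power_mw",
    "exposure_ms",
    "pixel_size_um",
)


@dataclass
class StudyConfig:
    """Tunable analysis settings, loadable from YAML."""

    reference_label: str = ""
    power_range: tuple[float, float] = (4e-3, 10e-3)  # watts
    slope_tolerance: float = 0.1
    background_frame_fraction: float = 0.1
    deconvolution_shape: str = "sech2"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.slope_tolerance > 0:
            raise ValueError("slope_tolerance must be positive")
        if not 0 < self.background_frame_fraction <= 0.25:
            raise ValueError("background_frame_fraction must lie in (0, 0.25]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "power_range" in raw:
            raw["power_range"] = tuple(raw["power_range"])
        return cls(**raw)


def _parse_unit(column: str, table: dict[str, float], kind: str) -> float:
    parts = column.strip().lower().rsplit("_", 1)
    if len(parts) != 2 or parts[1] not in table:
        raise ValueError(
            f"cannot parse {kind} unit from column {column!r}: expected a header "
            f"like 'time_fs,power_au' with {kind} unit in {sorted(table)}"
        )
    return table[parts[1]]


def read_pulse_trace(path: str | Path, label: str | None = None) -> PulseTrace:
    """Load a two-column delimited text trace, converting units to SI.

    The header row must name units, e.g. ``time_fs,power_au``.  Non-uniform
    (but monotone) grids are resampled by linear interpolation with a logged
    warning; non-monotone time columns are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns (time, power)")
    tcol, pcol = df.columns[:2]
    tscale = _parse_unit(str(tcol), _TIME_UNITS, "time")
    pscale = _parse_unit(str(pcol), _POWER_UNITS, "power")
    t = df[tcol].to_numpy(dtype=float) * tscale
    p = df[pcol].to_numpy(dtype=float) * pscale
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    try:
        check_uniform_grid(t)
    except ValueError:
        log.warning("%s: non-uniform time grid; resampling by linear interpolation", path)
        tu = np.linspace(t[0], t[-1], t.size)
        p = np.interp(tu, t, p)
        t = tu
    return PulseTrace(times=t, powers=p, label=label or Path(path).stem)


def write_pulse_trace(
    trace: PulseTrace, path: str | Path, time_unit: str = "fs", power_unit: str = "w"
) -> None:
    """Write a trace as CSV with unit-bearing headers."""
    tscale = _TIME_UNITS[time_unit]
    pscale = _POWER_UNITS[power_unit]
    pd.DataFrame(
        {
            f"time_{time_unit}": trace.times / tscale,
            f"power_{power_unit}": trace.powers / pscale,
        }
    ).to_csv(path, index=False)


def read_laser_table(path: str | Path) -> dict[str, LaserRecord]:
    """Load per-laser scalar metadata.

    Expects columns ``label, rep_rate_mhz, pulse_fs`` and optionally
    ``wavelength_nm``; returns records keyed by label (no measurements).
    """
    df = pd.read_csv(path)
    required = {"label", "rep_rate_mhz", "pulse_fs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing laser-table columns {sorted(missing)}")
    records: dict[str, LaserRecord] = {}
    for _, row in df.iterrows():
        wav = float(row["wavelength_nm"]) * 1e-9 if "wavelength_nm" in df.columns else None
        records[str(row["label"])] = LaserRecord(
            label=str(row["label"]),
            rep_rate=float(row["rep_rate_mhz"]) * 1e6,
            pulse_duration=float(row["pulse_fs"]) * 1e-15,
            center_wavelength=wav,
        )
    return records


def _load_frame(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image, got shape {px.shape}")
    if px.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit unsigned pixels, got {px.dtype}")
    return px


def read_spot_manifest(path: str | Path, images_root: str | Path | None = None) -> list[SpotImage]:
    """Load every frame referenced by a study manifest CSV.

    Image paths are resolved relative to the manifest's directory unless
    ``images_root`` is given.  Missing files are reported together with
    their (1-based) manifest row numbers.
    """
    path = Path(path)
    root = Path(images_root) if images_root is not None else path.parent
    df = pd.read_csv(path)
    missing_cols = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing_cols)}")
    if (df["exposure_ms"] <= 0).any():
        bad = df.index[df["exposure_ms"] <= 0][0] + 1
        raise ValueError(f"{path}: non-positive exposure_ms at manifest row {bad}")
    missing = [
        i + 1 for i, rel in enumerate(df["path"]) if not (root / str(rel)).is_file()
    ]
    if missing:
        raise FileNotFoundError(f"{path}: missing image files at manifest row(s) {missing}")
    frames: list[SpotImage] = []
    for _, row in df.iterrows():
        frames.append(
            SpotImage(
                pixels=_load_frame(root / str(row["path"])),
                exposure_ms=float(row["exposure_ms"]),
                incident_power=float(row["power_mw"]) * 1e-3,
                pixel_size=float(row["pixel_size_um"]) * 1e-6,
                laser_label=str(row["laser_label"]),
                session_id=str(row["session_id"]),
            )
        )
    log.info("loaded %d frames from %s", len(frames), path)
    return frames


def write_report(
    results: list[EfficiencyResult],
    config: StudyConfig,
    out_dir: str | Path,
    pairwise: pd.DataFrame | None = None,
    slopes: dict[str, float] | None = None,
) -> Path:
    """Write the study summary: JSON plus per-laser and pairwise CSV tables.

    Output field order is fixed so that reruns on identical inputs are
    byte-identical.  Returns the path of the JSON report.
    """
    if not results:
        raise ValueError("cannot write a report with no results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_laser = pd.DataFrame([asdict(r) for r in results])
    per_laser.to_csv(out / "efficiency.csv", index=False)

    payload = {
        "software": {"name": "twopeff", "version": __version__},
        "config": asdict(config),
        "pairwise_method": "Welch two-sample t-tests with Holm step-down adjustment",
        "results": [asdict(r) for r in results],
    }
    if slopes is not None:
        payload["loglog_slopes"] = {k: slopes[k] for k in sorted(slopes)}
    report = out / "report.json"
    report.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")

    if pairwise is not None:
        pairwise.to_csv(out / "pairwise_pvalues.csv")
    return report
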