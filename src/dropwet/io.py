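"""File formats, configuration and logging helpers.

Frames are exchanged as 8-bit grayscale PNG/TIFF sequences named
``frame_%06d``; per-frame measurements as an RFC-4180 CSV with a fixed,
documented column order ('.' decimal separator, NaN as empty cells); events
as JSON.  Run configuration is a validated YAML file holding the ramp
protocol, per-view calibration, threshold mode, smoothing and depinning
settings, retention inputs and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .frames import Frame, FrameSeries
from .geometry import GeometryMeasurement
from .ramp import (DEPIN_EPSILON, DEPIN_PERSISTENCE, SMOOTH_WINDOW,
                   RampConfig, RetentionInput, WettingEvents, rs_at_time)
from .segmentation import to_grayscale

log = logging.getLogger("dropwet")

#: fixed measurement CSV column order
MEASUREMENT_COLUMNS = ("frame", "time", "rotation_speed",
                       *GeometryMeasurement.FIELDS)

_INDEX_RE = re.compile(r"(\d+)(?=\.[A-Za-z]+$)")


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _frame_index(path: Path) -> int:
    m = _INDEX_RE.search(path.name)
    if m is None:
        raise ValueError(f"cannot parse a frame index from {path.name!r}")
    return int(m.group(1))


def read_frames(source: Union[str, Path], view: str = "side",
                mm_per_px: float = 1.0, fps: float = 10.0,
                ramp: Optional[RampConfig] = None,
                pattern: str = "frame_*.png") -> FrameSeries:
    """Read an image sequence into a FrameSeries.

    ``source`` is a directory (searched with ``pattern``) or a glob pattern.
    Frame indices are parsed from the trailing digits of each file name and
    must be strictly increasing and contiguous; each frame is tagged with
    ``time = (index - index0) / fps`` and, when a ramp protocol is given,
    with its rotation speed.
    """
    src = Path(source)
    if src.is_dir():
        files = sorted(src.glob(pattern))
    else:
        files = sorted(src.parent.glob(src.name))
    if not files:
        raise ValueError(f"no frames found under {source!r}")

    indexed = sorted((( _frame_index(p), p) for p in files), key=lambda t: t[0])
    indices = [i for i, _ in indexed]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate frame indices in sequence")
    for prev, cur in zip(indices, indices[1:]):
        if cur != prev + 1:
            raise ValueError(f"missing frame index {prev + 1} "
                             f"(found {prev} then {cur})")

    frames = []
    for idx, path in indexed:
        try:
            pixels = to_grayscale(iio.imread(path))
        except Exception as exc:
            raise ValueError(f"corrupt or unreadable frame {idx} "
                             f"({path.name}): {exc}") from exc
        t = (idx - indices[0]) / fps
        rs = rs_at_time(t, ramp) if ramp is not None else 0.0
        frames.append(Frame(pixels=pixels, time=t, rotation_speed=rs,
                            view=view, mm_per_px=mm_per_px))
        log.debug("read frame %d (%s): t=%.2f s, RS=%.2f rpm",
                  idx, path.name, t, rs)
    return FrameSeries(frames)


def write_frames(frames: Sequence[Frame], outdir: Union[str, Path],
                 prefix: str = "frame", fmt: str = "png") -> list[Path]:
    """Write frames as 8-bit grayscale images named ``{prefix}_%06d.{fmt}``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = out / f"{prefix}_{i:06d}.{fmt}"
        iio.imwrite(path, frame.pixels)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# measurements and events
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: Sequence[GeometryMeasurement],
                          times: Optional[Sequence[float]] = None,
                          rotation_speeds: Optional[Sequence[float]] = None
                          ) -> pd.DataFrame:
    """Tabulate per-frame measurements in the fixed column order."""
    rows = []
    n = len(measurements)
    for i, m in enumerate(measurements):
        row = {"frame": i,
               "time": times[i] if times is not None else np.nan,
               "rotation_speed": (rotation_speeds[i]
                                  if rotation_speeds is not None else np.nan)}
        row.update(m.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    if n == 0:
        df = pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    return df


def write_measurements(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the measurement table as RFC-4180 CSV; NaN becomes an empty cell."""
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols + extra)


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Read a measurement CSV; empty cells come back as NaN (undefined)."""
    return pd.read_csv(path)


def write_events(events: WettingEvents, path: Union[str, Path],
                 extra: Optional[dict] = None) -> None:
    payload: dict[str, Any] = dataclasses.asdict(events)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_events(path: Union[str, Path]) -> WettingEvents:
    payload = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(WettingEvents)}
    return WettingEvents(**{k: v for k, v in payload.items() if k in fields})


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated analysis configuration (see ``load_config``)."""

    ramp: RampConfig = dataclasses.field(default_factory=RampConfig)
    threshold_mode: str = "auto"
    t_bulky: Optional[float] = None
    t_whole: Optional[float] = None
    side_mm_per_px: float = 0.01
    top_mm_per_px: float = 0.01
    smoothing_window: int = SMOOTH_WINDOW
    depin_epsilon: float = DEPIN_EPSILON
    depin_persistence: int = DEPIN_PERSISTENCE
    retention: RetentionInput = dataclasses.field(default_factory=RetentionInput)
    seed: int = 0


def _build(cls, data: dict, context: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"invalid {context} configuration: {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"invalid {context} configuration: {exc}") from exc


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration, erroring per field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    cfg = RunConfig()
    if "ramp" in raw:
        cfg.ramp = _build(RampConfig, dict(raw["ramp"]), "ramp")
    if "retention" in raw:
        cfg.retention = _build(RetentionInput, dict(raw["retention"]), "retention")
    thr = raw.get("thresholds", {})
    if thr:
        cfg.threshold_mode = thr.get("mode", "auto")
        if cfg.threshold_mode not in ("auto", "manual"):
            raise ValueError("thresholds.mode must be 'auto' or 'manual'")
        if cfg.threshold_mode == "manual":
            try:
                cfg.t_bulky = float(thr["t_bulky"])
                cfg.t_whole = float(thr["t_whole"])
            except KeyError as exc:
                raise ValueError(f"thresholds.{exc.args[0]} is required in "
                                 "manual mode") from exc
    cal = raw.get("calibration", {})
    for key, attr in (("side_mm_per_px", "side_mm_per_px"),
                      ("top_mm_per_px", "top_mm_per_px")):
        if key in cal:
            val = float(cal[key])
            if not val > 0:
                raise ValueError(f"calibration.{key} must be positive")
            setattr(cfg, attr, val)
    if "smoothing_window" in raw:
        w = int(raw["smoothing_window"])
        if w < 1 or w % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")
        cfg.smoothing_window = w
    dep = raw.get("depinning", {})
    if "epsilon" in dep:
        cfg.depin_epsilon = float(dep["epsilon"])
        if not cfg.depin_epsilon > 0:
            raise ValueError("depinning.epsilon must be positive")
    if "persistence" in dep:
        cfg.depin_persistence = int(dep["persistence"])
        if cfg.depin_persistence < 1:
            raise ValueError("depinning.persistence must be >= 1")
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg
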