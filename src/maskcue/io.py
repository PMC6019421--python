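"""File formats: trial tables, landmarks, images, configuration.

All tables are UTF-8 CSV with a mandatory header row; numeric columns are
written with 6 significant digits so cross-platform diffs are stable.
Images are 8-bit grayscale PNG on write (TIFF/JPEG accepted on read).
Configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .types import Category, GroupStats, LandmarkSet, SDTSummary, TestResult, TrialRecord

FLOAT_FORMAT = "%.6g"

TRIAL_COLUMNS = ["participant_id", "stimulus_id", "condition", "truth",
                 "response", "rt_ms"]


class ValidationError(ValueError):
    """A file violated its documented schema."""


def write_trials(trials: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "participant_id": [t.participant_id for t in trials],
        "stimulus_id": [t.stimulus_id for t in trials],
        "condition": [t.condition.value for t in trials],
        "truth": [t.truth for t in trials],
        "response": [t.response for t in trials],
        "rt_ms": [t.rt_ms if t.rt_ms is not None else np.nan for t in trials],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trials(path: Union[str, Path]) -> List[TrialRecord]:
    """Load a trial table, validating each row (errors name the CSV row).

    The rt_ms column may be absent entirely (trials load without reaction
    times); unknown extra columns are ignored on parse but preserved by
    round-tripping through pandas if needed.
    """
    df = pd.read_csv(path)
    required = [c for c in TRIAL_COLUMNS if c != "rt_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    has_rt = "rt_ms" in df.columns
    out: List[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is line 1
        try:
            cond = Category(getattr(row, "condition"))
        except ValueError:
            raise ValidationError(
                f"{path} row {rownum}: invalid condition "
                f"{getattr(row, 'condition')!r}")
        rt = getattr(row, "rt_ms") if has_rt else None
        if rt is not None and (isinstance(rt, float) and np.isnan(rt)):
            rt = None
        try:
            out.append(TrialRecord(
                participant_id=str(getattr(row, "participant_id")),
                stimulus_id=str(getattr(row, "stimulus_id")),
                condition=cond,
                truth=str(getattr(row, "truth")),
                response=str(getattr(row, "response")),
                rt_ms=float(rt) if rt is not None else None,
            ))
        except ValueError as exc:
            raise ValidationError(f"{path} row {rownum}: {exc}")
    return out


def write_landmarks(landmarks: Mapping[str, LandmarkSet],
                    path: Union[str, Path]) -> None:
    """Landmark CSV: stimulus_id,point_index,x,y (one row per point)."""
    rows = []
    for sid, lm in landmarks.items():
        for idx, (x, y) in enumerate(lm.points):
            rows.append((sid, idx, x, y))
    pd.DataFrame(rows, columns=["stimulus_id", "point_index", "x", "y"]
                 ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_landmarks(path: Union[str, Path],
                   schema: Sequence[str]) -> Dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    missing = [c for c in ("stimulus_id", "point_index", "x", "y")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    out: Dict[str, LandmarkSet] = {}
    for sid, grp in df.groupby("stimulus_id", sort=True):
        grp = grp.sort_values("point_index")
        if len(grp) != len(schema):
            raise ValidationError(
                f"{path}: stimulus {sid} has {len(grp)} points, "
                f"schema expects {len(schema)}")
        out[str(sid)] = LandmarkSet(points=grp[["x", "y"]].to_numpy(float),
                                    schema=tuple(schema))
    return out


def write_image(pixels: np.ndarray, path: Union[str, Path]) -> None:
    """Write a grayscale image as 8-bit PNG (floats are rounded/clipped)."""
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(Path(path), format="PNG")


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF/JPEG); returns a uint8 grid."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_grid(values: np.ndarray, path: Union[str, Path]) -> None:
    """Lossless-enough real-valued grid dump (CSV, 6 significant digits)."""
    np.savetxt(path, np.asarray(values, dtype=float),
               fmt=FLOAT_FORMAT, delimiter=",")


def read_grid(path: Union[str, Path]) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def group_stats_frame(stats: Mapping[str, GroupStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(k, s.mean, s.se, s.ci_low, s.ci_high, s.n, s.level)
         for k, s in stats.items()],
        columns=["condition", "mean", "se", "ci_low", "ci_high", "n", "ci_level"])


def test_results_frame(results: Mapping[str, TestResult]) -> pd.DataFrame:
    rows = []
    for k, t in results.items():
        df1 = t.df[0]
        df2 = t.df[1] if len(t.df) > 1 else np.nan
        rows.append((k, t.name, t.value, df1, df2, t.p,
                     t.effect_size if t.effect_size is not None else np.nan,
                     t.effect_size_name or ""))
    return pd.DataFrame(rows, columns=["test", "statistic", "value", "df1",
                                       "df2", "p", "effect_size",
                                       "effect_size_name"])


def sdt_frame(summaries: Mapping[str, SDTSummary]) -> pd.DataFrame:
    rows = []
    for pid, s in summaries.items():
        rows.append((pid, s.hit_rate, s.fa_rate, s.hit_rate_corrected,
                     s.fa_rate_corrected, s.dprime, s.criterion, s.pcorrect,
                     s.n_signal, s.n_noise, s.correction))
    return pd.DataFrame(rows, columns=["participant_id", "H", "F",
                                       "H_corrected", "F_corrected", "dprime",
                                       "C", "pcorrect", "n_signal", "n_noise",
                                       "correction"])


def save_config(config: object, path: Union[str, Path]) -> None:
    """Serialize a dataclass config to YAML (lossless round-trip)."""
    if not dataclasses.is_dataclass(config):
        raise TypeError("config must be a dataclass")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config_dict(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data
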