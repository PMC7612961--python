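"""Table and model persistence: tidy CSV tables, JSON models, YAML configs."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .tac import TimeActivityCurve
from .wscores import WScoreModel

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_tacs",
    "read_tacs",
    "write_wscore_models",
    "read_wscore_models",
    "write_json",
    "read_json",
    "load_yaml",
]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age_y", "scanner"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    return df


def write_tacs(tacs: list[TimeActivityCurve], path) -> None:
    rows = []
    for tac in tacs:
        for s, e, a in zip(tac.frame_start, tac.frame_end, tac.activity):
            rows.append(
                {"frame_start_min": s, "frame_end_min": e, "activity": a,
                 "region_label": tac.region_label}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tacs(path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(path)
    out: dict[str, TimeActivityCurve] = {}
    for label, sub in df.groupby("region_label", sort=False):
        sub = sub.sort_values("frame_start_min")
        out[str(label)] = TimeActivityCurve(
            sub["frame_start_min"].to_numpy(),
            sub["frame_end_min"].to_numpy(),
            sub["activity"].to_numpy(),
            region_label=str(label),
        )
    return out


def write_wscore_models(models: dict[str, WScoreModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({r: m.to_dict() for r, m in models.items()}, fh, indent=2)


def read_wscore_models(path) -> dict[str, WScoreModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {r: WScoreModel.from_dict(d) for r, d in raw.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
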