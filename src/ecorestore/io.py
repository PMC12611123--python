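"""CSV / config / manifest I/O.

Panels travel as long-format CSV with columns::

    site_id, date (YYYY-MM), altitude_m, temp_c, precip_mm, soil_moisture,
    fvc, irrigation_pct, planting_density, survival_pct

Empty cells mean missing.  Floats are written with 17 significant digits so
a write -> read round trip reproduces values exactly.  Every
artifact-producing CLI command writes a JSON run manifest (command, resolved
config, seed, input/output paths with content hashes, software version,
timestamp) so runs are reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ScenarioConfig, SiteSeries, VARIABLES

__all__ = [
    "PANEL_COLUMNS",
    "panel_to_dataframe",
    "panel_from_dataframe",
    "write_panel_csv",
    "read_panel_csv",
    "load_scenario_config",
    "write_manifest",
]

PANEL_COLUMNS = ["site_id", "date", "altitude_m"] + VARIABLES

_FLOAT_FMT = "%.17g"


def _month_str(start_year: int, month_index: int) -> str:
    y, m = divmod(month_index, 12)
    return f"{start_year + y:04d}-{m + 1:02d}"


def panel_to_dataframe(
    panel: list[SiteSeries], start_year: int = 2019
) -> pd.DataFrame:
    """Long-format DataFrame; month_index 0 maps to ``start_year``-01."""
    frames = []
    for s in panel:
        d = s.data.reset_index()
        d.insert(0, "site_id", s.site_id)
        d.insert(1, "date", [_month_str(start_year, int(m)) for m in d["month_index"]])
        d.insert(2, "altitude_m", s.altitude_m)
        frames.append(d.drop(columns=["month_index"]))
    return pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]


def panel_from_dataframe(df: pd.DataFrame) -> list[SiteSeries]:
    """Rebuild :class:`SiteSeries` records from a long-format DataFrame."""
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    df = df.copy()
    periods = pd.PeriodIndex(df["date"], freq="M")
    origin = periods.min()
    df["month_index"] = (periods - origin).map(lambda off: off.n)
    panel = []
    for site_id, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("month_index")
        if grp["month_index"].duplicated().any():
            raise ValueError(f"site {site_id!r} has duplicate months")
        data = grp.set_index("month_index")[VARIABLES].astype(float)
        data.index.name = "month_index"
        alts = grp["altitude_m"].dropna().unique()
        if len(alts) != 1:
            raise ValueError(f"site {site_id!r} has inconsistent altitude_m")
        panel.append(SiteSeries(site_id=str(site_id), altitude_m=float(alts[0]),
                                data=data))
    return panel


def write_panel_csv(panel: list[SiteSeries], path, start_year: int = 2019) -> None:
    panel_to_dataframe(panel, start_year).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_panel_csv(path) -> list[SiteSeries]:
    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    return panel_from_dataframe(df)


def load_scenario_config(path) -> ScenarioConfig:
    """Read a flat YAML/JSON scenario document into a ScenarioConfig."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("scenario config must be a flat mapping")
    known = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    if "altitude_fractions" in doc:
        doc["altitude_fractions"] = tuple(doc["altitude_fractions"])
    cfg = ScenarioConfig(**doc)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    config: dict,
    seed: int,
    inputs: list = (),
    outputs: list = (),
) -> dict:
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in inputs
        ],
        "outputs": [str(p) for p in outputs],
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=_jsonable))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
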