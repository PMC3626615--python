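"""File surfaces: time-series tables, body snapshots, event logs, manifests.

All outputs are plain text: comma-separated tables with a header row and
dot decimals, and JSON-lines event logs.  Readers are crash-tolerant: a
partial trailing line (interrupted write) is detected, dropped, and
reported with a warning.  Floats are written with ``repr`` so values
round-trip at full precision; absent means (empty population) are
written as empty fields and read back as NaN.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np

from .config import RunConfig, config_hash, config_to_dict
from .metrics import StepRecord
from .state import CELL, SimulationState

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_snapshot",
    "read_snapshot_table",
    "write_events",
    "read_events",
    "write_manifest",
]

_INT_FIELDS = {"step", "n_cells", "free_nutrients", "n_detritivores", "n_springs"}
_BOOL_FIELDS = {"top_layer_occupied"}
_LIST_FIELDS = {"n_particles_by_class"}


def _fmt(name: str, value) -> str:
    if name in _LIST_FIELDS:
        return ";".join(str(int(v)) for v in value)
    if name in _BOOL_FIELDS:
        return "1" if value else "0"
    if name in _INT_FIELDS:
        return str(int(value))
    if isinstance(value, float) and math.isnan(value):
        return ""
    return repr(float(value))


def _parse(name: str, text: str):
    if name in _LIST_FIELDS:
        return [int(v) for v in text.split(";")] if text else []
    if name in _BOOL_FIELDS:
        return text == "1"
    if name in _INT_FIELDS:
        return int(text)
    if text == "":
        return math.nan
    return float(text)


def write_timeseries(records: list[StepRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("refusing to write an empty time series")
    names = StepRecord.field_names()
    lines = [",".join(names)]
    for rec in records:
        lines.append(",".join(_fmt(n, getattr(rec, n)) for n in names))
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path: str | Path) -> list[StepRecord]:
    text = Path(path).read_text()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    elif lines:
        warnings.warn(f"{path}: dropping partial trailing line")
        lines.pop()
    header = lines[0].split(",")
    names = StepRecord.field_names()
    if header != names:
        raise ValueError(f"{path}: unexpected time-series header")
    out = []
    for line in lines[1:]:
        parts = line.split(",")
        if len(parts) != len(names):
            warnings.warn(f"{path}: dropping malformed line")
            continue
        out.append(StepRecord(**{n: _parse(n, t) for n, t in zip(names, parts)}))
    return out


_SNAPSHOT_HEADER = [
    "id", "kind", "class", "x", "y", "z", "vx", "vy", "vz",
    "mass", "wall_adhesion", "cell_adhesion", "efficiency",
]


def write_snapshot(state: SimulationState, path: str | Path) -> None:
    """One row per body, cells first then particles, each ordered by id.

    The efficiency vector is semicolon-joined; the table is suitable for
    external 3-D plotting and for seeding a resumed run.
    """
    lines = [",".join(_SNAPSHOT_HEADER)]
    order = np.lexsort((state.ids, state.kind))  # cells (kind 0) before particles
    for i in order.tolist():
        is_cell = state.kind[i] == CELL
        row = [
            str(int(state.ids[i])),
            "cell" if is_cell else "particle",
            str(int(state.pclass[i])),
            *(repr(float(v)) for v in state.pos[i]),
            *(repr(float(v)) for v in state.vel[i]),
            repr(float(state.mass[i])),
            repr(float(state.wall_adh[i])) if is_cell else "",
            repr(float(state.cell_adh[i])) if is_cell else "",
            ";".join(repr(float(v)) for v in state.eff[i]) if is_cell else "",
        ]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot_table(path: str | Path) -> list[dict]:
    """Parse a snapshot back into per-body dicts (crash-tolerant)."""
    lines = Path(path).read_text().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    else:
        warnings.warn(f"{path}: dropping partial trailing line")
        lines.pop()
    if lines[0].split(",") != _SNAPSHOT_HEADER:
        raise ValueError(f"{path}: unexpected snapshot header")
    out = []
    for line in lines[1:]:
        parts = line.split(",")
        if len(parts) != len(_SNAPSHOT_HEADER):
            warnings.warn(f"{path}: dropping malformed line")
            continue
        d = dict(zip(_SNAPSHOT_HEADER, parts))
        d["id"] = int(d["id"])
        d["class"] = int(d["class"])
        for k in ("x", "y", "z", "vx", "vy", "vz", "mass"):
            d[k] = float(d[k])
        for k in ("wall_adhesion", "cell_adhesion"):
            d[k] = float(d[k]) if d[k] else math.nan
        d["efficiency"] = (
            [float(v) for v in d["efficiency"].split(";")] if d["efficiency"] else []
        )
        out.append(d)
    return out


def state_from_snapshot(rows: list[dict], config: RunConfig, seed: int) -> SimulationState:
    """Rebuild a world from a snapshot table (bodies only).

    Adhesion springs, cumulative counters and the RNG position are not
    part of the snapshot: springs start empty and counters at zero, and
    the caller supplies a fresh seed.  For spring-free worlds the rebuilt
    state continues exactly like the original under the same seed.
    """
    state = SimulationState(config, seed)
    if not rows:
        return state
    rows = sorted(rows, key=lambda r: r["id"])
    n = len(rows)
    C = config.ecology.n_classes
    eff = np.zeros((n, C))
    for i, r in enumerate(rows):
        if r["efficiency"]:
            eff[i, : len(r["efficiency"])] = r["efficiency"]
    is_cell = np.array([r["kind"] == "cell" for r in rows])
    state.append(
        kind=np.where(is_cell, CELL, 1).astype(np.int8),
        pos=np.array([[r["x"], r["y"], r["z"]] for r in rows]),
        vel=np.array([[r["vx"], r["vy"], r["vz"]] for r in rows]),
        mass=np.array([r["mass"] for r in rows]),
        radius=np.where(
            is_cell, config.evolution.cell_radius, config.ecology.particle_radius
        ),
        pclass=np.array([r["class"] for r in rows], dtype=np.int16),
        eff=eff,
        wall_adh=np.nan_to_num(np.array([r["wall_adhesion"] for r in rows])),
        cell_adh=np.nan_to_num(np.array([r["cell_adhesion"] for r in rows])),
        wall_attached=np.zeros(n, dtype=bool),
        wall_anchor=np.zeros((n, 3)),
        wall_id=np.full(n, -1, dtype=np.int8),
    )
    # preserve the original identities, not the freshly assigned ones
    state.ids = np.array([r["id"] for r in rows], dtype=np.int64)
    state.next_id = int(state.ids.max()) + 1
    return state


def write_events(events: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, separators=(",", ":")) + "\n")


def read_events(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        text = fh.read()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    elif lines:
        warnings.warn(f"{path}: dropping partial trailing line")
        lines.pop()
    for line in lines:
        try:
            out.append(json.loads(line))
        except json.JSONDecodeError:
            warnings.warn(f"{path}: dropping malformed event line")
    return out


def write_manifest(config: RunConfig, seed: int, path: str | Path, **extra) -> None:
    """Record the config (and its hash) plus the seed next to every output,
    so any two outputs with equal hash and seed are identical."""
    doc = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "config": config_to_dict(config),
        **extra,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
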