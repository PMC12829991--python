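"""File I/O: FCS event data, CSV schemas, run configuration.

A focused reader for list-mode FCS 3.0/3.1 files (float or integer data,
either byte order) extracts one fluorescence channel into a
:class:`~divnoise.cytometry.CytometrySnapshot`; a matching minimal writer
exists so the test suite can round-trip fixtures.  CSV schemas:

* cytometry events — columns ``time_h, intensity`` (optional
  ``true_generation`` for synthetic data);
* microscopy traces — long table ``event_id, role, t_h, intensity,
  area_px`` with role in {mother, d1, d2}.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cytometry import CytometrySnapshot
from .microscopy import CellTrace, DivisionEvent

__all__ = [
    "read_fcs",
    "write_fcs",
    "read_cytometry_csv",
    "write_cytometry_csv",
    "read_trace_csv",
    "write_trace_csv",
    "RunConfig",
    "config_hash",
]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)[1:]  # leading delimiter
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[0::2], parts[1::2])}


def read_fcs(path: str | Path, channel: str, time_h: float | None = None) -> CytometrySnapshot:
    """Read one channel of a list-mode FCS 3.0/3.1 file.

    The channel is matched against $PnN (short name) first, then $PnS
    (stain name).  Only uncompensated raw channel values are returned;
    the acquisition time is taken from the argument (FCS time keywords
    are free-text and instrument-specific).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(58)
        version = header[:6].decode("latin-1")
        if not version.startswith("FCS3"):
            raise ValueError(f"{path.name}: unsupported FCS version {version!r}")
        try:
            text_start = int(header[10:18])
            text_end = int(header[18:26])
            data_start = int(header[26:34])
            data_end = int(header[34:42])
        except ValueError as exc:
            raise ValueError(f"{path.name}: malformed FCS header") from exc
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))
        if data_start == 0:
            data_start = int(text.get("$BEGINDATA", 0))
            data_end = int(text.get("$ENDDATA", 0))
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        dtype_code = text["$DATATYPE"].upper()
        byteord = text.get("$BYTEORD", "1,2,3,4")
        little = byteord.startswith("1")
        order = "<" if little else ">"

        names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
        stains = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
        if channel in names:
            col = names.index(channel)
        elif channel in stains:
            col = stains.index(channel)
        else:
            avail = sorted(set(filter(None, names + stains)))
            raise ValueError(
                f"{path.name}: channel {channel!r} not found; available: {avail}"
            )

        fh.seek(data_start)
        raw = fh.read(data_end - data_start + 1)
        if dtype_code == "F":
            arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=f"{order}f4")
        elif dtype_code == "D":
            arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=f"{order}f8")
        elif dtype_code == "I":
            bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
            if len(bits) != 1 or bits.pop() not in (16, 32):
                raise ValueError(f"{path.name}: only uniform 16/32-bit integer data supported")
            width = int(text["$P1B"]) // 8
            arr = np.frombuffer(
                raw[: width * n_par * n_tot], dtype=f"{order}u{width}"
            )
        else:
            raise ValueError(f"{path.name}: unsupported $DATATYPE {dtype_code!r}")
        values = arr.reshape(n_tot, n_par)[:, col].astype(float)

    return CytometrySnapshot(
        time_h=float(time_h) if time_h is not None else float("nan"),
        channel=channel,
        intensities=values,
    )


def write_fcs(path: str | Path, data: dict[str, np.ndarray]) -> None:
    """Write a minimal list-mode FCS 3.1 file (float32, little-endian).

    Intended for test fixtures and exports only.
    """
    names = list(data)
    cols = [np.asarray(data[k], dtype="<f4") for k in names]
    n_tot = cols[0].size
    if any(c.size != n_tot for c in cols):
        raise ValueError("all channels must have the same length")
    matrix = np.column_stack(cols).astype("<f4")
    payload = matrix.tobytes()

    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(len(names)),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(float(cols[i - 1].max(initial=0.0)), 1.0)) + 1)
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    text_bytes = text.encode("latin-1")
    text_start = 58
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}{text_end:>8d}{data_start:>8d}{data_end:>8d}".encode()
        + f"{0:>8d}{0:>8d}".encode()
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(payload)


def read_cytometry_csv(path: str | Path, channel: str = "CTV") -> list[CytometrySnapshot]:
    """Read cytometry events (columns time_h, intensity), one snapshot per time."""
    df = pd.read_csv(path)
    missing = {"time_h", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"cytometry CSV missing columns: {sorted(missing)}")
    out = []
    for t, grp in df.groupby("time_h", sort=True):
        out.append(
            CytometrySnapshot(
                time_h=float(t), channel=channel, intensities=grp["intensity"].to_numpy()
            )
        )
    return out


def write_cytometry_csv(
    path: str | Path,
    snapshots: list[CytometrySnapshot],
    labels: list[np.ndarray] | None = None,
) -> None:
    frames = []
    for i, snap in enumerate(snapshots):
        df = pd.DataFrame({"time_h": snap.time_h, "intensity": snap.intensities})
        if labels is not None:
            df["true_generation"] = labels[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_ROLES = ("mother", "d1", "d2")


def read_trace_csv(path: str | Path) -> list[DivisionEvent]:
    """Read division events from the long trace table.

    Columns: event_id, role in {mother, d1, d2}, t_h, intensity, area_px
    (area may be empty).  The division time is the mother's last frame.
    """
    df = pd.read_csv(path)
    required = {"event_id", "role", "t_h", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    has_area = "area_px" in df.columns
    events = []
    for eid, grp in df.groupby("event_id", sort=True):
        traces = {}
        for role in _ROLES:
            sub = grp[grp["role"] == role].sort_values("t_h")
            if sub.empty:
                raise ValueError(f"event {eid!r}: missing {role} trace")
            area = sub["area_px"].to_numpy() if has_area and sub["area_px"].notna().all() else None
            traces[role] = CellTrace(
                sub["t_h"].to_numpy(), sub["intensity"].to_numpy(), area
            )
        events.append(
            DivisionEvent(
                mother=traces["mother"],
                daughter1=traces["d1"],
                daughter2=traces["d2"],
                division_time=float(traces["mother"].times[-1]),
                event_id=eid,
            )
        )
    return events


def write_trace_csv(path: str | Path, events: list[DivisionEvent]) -> None:
    rows = []
    for i, ev in enumerate(events):
        eid = ev.event_id if ev.event_id != "" else i
        for role, tr in (("mother", ev.mother), ("d1", ev.daughter1), ("d2", ev.daughter2)):
            for k in range(tr.times.size):
                rows.append(
                    {
                        "event_id": eid,
                        "role": role,
                        "t_h": tr.times[k],
                        "intensity": tr.intensity[k],
                        "area_px": tr.area[k] if tr.area is not None else np.nan,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


_CONFIG_FIELDS = {
    "inputs": list,
    "channel": str,
    "times_h": list,
    "anchor_mu0": float,
    "spacing": float,
    "tied_sigma": bool,
    "mean_mode": str,
    "max_generations": int,
    "n_bootstrap": int,
    "sigma_f": float,
    "family": str,
    "mode": str,
    "n_lineages": int,
    "max_generation": int,
    "cycle_time_mean_h": float,
    "cycle_time_cv": float,
    "growth_rate": float,
    "division_size": float,
    "threshold_cv": float,
    "events_per_acquisition": int,
    "noise_cv": float,
    "brightness": float,
    "background": float,
    "n_events": int,
    "frames_per_side": int,
    "frame_interval_h": float,
    "min_hours": float,
    "r_max": float,
    "seed": int,
    "out_dir": str,
}


@dataclass
class RunConfig:
    """Validated run configuration: YAML file values overridden by flags."""

    values: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(values) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(values=values)

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def require_seed(self) -> int:
        if "seed" not in self.values:
            raise ValueError("a seed is mandatory for stochastic commands")
        return int(self.values["seed"])


def config_hash(values: dict) -> str:
    """Stable short hash identifying a run configuration."""
    blob = json.dumps(values, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
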