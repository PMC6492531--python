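"""Data model and on-disk format for two-region electrophysiology sessions.

A :class:`RecordingSession` bundles multi-channel LFP per region (µV,
common sampling rate), sorted spike trains, and an event table on one
session-relative clock (seconds, float64).  Sessions round-trip to a plain
directory layout::

    lfp_<region>.h5   HDF5, dataset "lfp" (channels x samples, float32 µV),
                      attrs "fs", "channel_ids"
    spikes.csv        unit_id, region, time_s
    events.csv        event_id, kind, onset_s, paw_withdrawal_latency_s,
                      stimulus_intensity_mw
    session.json      regions, t0, provenance
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

DEFAULT_REGIONS = ("ACC", "S1")

EVENT_KINDS = ("stimulus", "spontaneous_behavior", "control")

EVENT_COLUMNS = (
    "event_id",
    "kind",
    "onset_s",
    "paw_withdrawal_latency_s",
    "stimulus_intensity_mw",
)


class SessionError(ValueError):
    """Invalid session content (invariant violation or format error)."""


class BoundsError(SessionError):
    """A requested window falls outside the session extent."""


@dataclass
class SpikeTrain:
    """Sorted unit: spike times in seconds, strictly increasing."""

    unit_id: str
    region: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SessionError(f"unit {self.unit_id}: times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise SessionError(f"unit {self.unit_id}: spike times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class EpisodeWindow:
    """Analysis window [t_start, t_end] in s relative to an event onset.

    Defaults used throughout: evoked [0, 5] s from stimulus onset,
    spontaneous [-5, 5] s around the behavior onset.
    """

    event_id: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise SessionError(f"window [{self.t_start}, {self.t_end}] has t_start >= t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def make_event_table(rows: list[dict] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a validated event table with the canonical columns.

    Missing optional values (withdrawal latency, stimulus intensity) are NaN,
    never silently zero.
    """
    if rows is None:
        rows = []
    df = pd.DataFrame(rows)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float if col.endswith(("_s", "_mw")) else object)
    df = df[list(EVENT_COLUMNS)].copy()
    df["event_id"] = df["event_id"].astype(str)
    if len(df) and df["event_id"].duplicated().any():
        dups = df.loc[df["event_id"].duplicated(), "event_id"].tolist()
        raise SessionError(f"duplicate event ids: {dups}")
    bad = set(df["kind"].dropna()) - set(EVENT_KINDS)
    if bad:
        raise SessionError(f"unknown event kinds: {sorted(bad)}")
    return df.reset_index(drop=True)


@dataclass
class RecordingSession:
    """Two-region session: LFP matrices, spike trains, events, one clock.

    ``region_lfp`` maps region name -> (channels x samples) float array in µV.
    All regions share a time axis starting at ``t0`` with rate ``fs_lfp``.
    """

    region_lfp: dict[str, np.ndarray]
    fs_lfp: float
    spikes: list[SpikeTrain] = field(default_factory=list)
    events: pd.DataFrame = field(default_factory=make_event_table)
    t0: float = 0.0
    channel_ids: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_lfp = {r: np.atleast_2d(np.asarray(x)) for r, x in self.region_lfp.items()}
        self.events = make_event_table(self.events)
        for region, lfp in self.region_lfp.items():
            if region not in self.channel_ids:
                self.channel_ids[region] = [f"{region}_ch{i}" for i in range(lfp.shape[0])]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.fs_lfp < 200.0:
            raise SessionError(f"fs_lfp={self.fs_lfp} Hz below the 200 Hz analysis minimum")
        lengths = {lfp.shape[1] for lfp in self.region_lfp.values()}
        if len(lengths) > 1:
            raise SessionError(f"regions disagree on LFP length: {sorted(lengths)}")
        for region, lfp in self.region_lfp.items():
            if np.isnan(lfp).any():
                raise SessionError(f"NaN in LFP of region {region}")
            if len(self.channel_ids[region]) != lfp.shape[0]:
                raise SessionError(f"channel_ids mismatch in region {region}")
        t_end = self.t_end
        for train in self.spikes:
            if train.region not in self.region_lfp:
                raise SessionError(f"unit {train.unit_id} references unknown region {train.region}")
            if train.n_spikes and (train.times[0] < self.t0 - 1e-9 or train.times[-1] > t_end + 1e-9):
                raise SessionError(
                    f"unit {train.unit_id} has spikes outside the session extent "
                    f"[{self.t0}, {t_end}]"
                )
        onsets = self.events["onset_s"].to_numpy(float)
        if onsets.size and (np.nanmin(onsets) < self.t0 - 1e-9 or np.nanmax(onsets) > t_end + 1e-9):
            raise SessionError("event onsets outside the session extent")

    # -- geometry ------------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return list(self.region_lfp)

    @property
    def n_samples(self) -> int:
        return next(iter(self.region_lfp.values())).shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_lfp

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_lfp

    def event_onset(self, event_id: str) -> float:
        hit = self.events.loc[self.events["event_id"] == str(event_id), "onset_s"]
        if hit.empty:
            raise SessionError(f"unknown event id {event_id!r}")
        return float(hit.iloc[0])

    def units(self, region: str | None = None) -> list[SpikeTrain]:
        return [s for s in self.spikes if region is None or s.region == region]


# ---------------------------------------------------------------------------
# window slicing


def slice_window(session: RecordingSession, window: EpisodeWindow) -> RecordingSession:
    """Crop a session to an episode window around an event onset.

    LFP is cropped sample-exactly, spike times are re-referenced to the
    window start, and the event table is filtered to events whose onset
    falls inside the window (onsets re-referenced as well).
    """
    onset = session.event_onset(window.event_id)
    t_lo = onset + window.t_start
    t_hi = onset + window.t_end
    if t_lo < session.t0 - 1e-9 or t_hi > session.t_end + 1e-9:
        raise BoundsError(
            f"window [{t_lo:.3f}, {t_hi:.3f}] s outside session extent "
            f"[{session.t0:.3f}, {session.t_end:.3f}] s"
        )
    i_lo = int(round((t_lo - session.t0) * session.fs_lfp))
    i_hi = int(round((t_hi - session.t0) * session.fs_lfp))
    lfp = {r: x[:, i_lo:i_hi].copy() for r, x in session.region_lfp.items()}

    spikes = []
    for train in session.spikes:
        m = (train.times >= t_lo) & (train.times < t_hi)
        spikes.append(SpikeTrain(train.unit_id, train.region, train.times[m] - t_lo))

    ev = session.events
    keep = (ev["onset_s"] >= t_lo) & (ev["onset_s"] < t_hi)
    ev = ev.loc[keep].copy()
    ev["onset_s"] = ev["onset_s"] - t_lo

    return RecordingSession(
        region_lfp=lfp,
        fs_lfp=session.fs_lfp,
        spikes=spikes,
        events=ev,
        t0=0.0,
        channel_ids={r: list(c) for r, c in session.channel_ids.items()},
        provenance=dict(session.provenance, sliced_from=window.event_id),
    )


# ---------------------------------------------------------------------------
# on-disk format


def save_session(session: RecordingSession, path: str | Path) -> None:
    """Write the directory layout (HDF5 LFP + CSV spikes/events + JSON)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for region, lfp in session.region_lfp.items():
        with h5py.File(path / f"lfp_{region}.h5", "w") as f:
            ds = f.create_dataset("lfp", data=lfp.astype(np.float32))
            ds.attrs["fs"] = float(session.fs_lfp)
            ds.attrs["channel_ids"] = [str(c) for c in session.channel_ids[region]]
    rows = [
        {"unit_id": tr.unit_id, "region": tr.region, "time_s": t}
        for tr in session.spikes
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        path / "spikes.csv", index=False
    )
    session.events.to_csv(path / "events.csv", index=False)
    meta = {
        "regions": session.regions,
        "t0": session.t0,
        "fs_lfp": session.fs_lfp,
        "unit_order": [tr.unit_id for tr in session.spikes],
        "provenance": session.provenance,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2))


def load_session(path: str | Path) -> RecordingSession:
    """Read a session directory written by :func:`save_session`."""
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise SessionError(f"not a session directory (missing session.json): {path}")
    meta = json.loads(meta_file.read_text())

    region_lfp: dict[str, np.ndarray] = {}
    channel_ids: dict[str, list[str]] = {}
    fs_values = set()
    for region in meta["regions"]:
        h5file = path / f"lfp_{region}.h5"
        if not h5file.exists():
            raise SessionError(f"missing LFP file for region {region}: {h5file}")
        with h5py.File(h5file, "r") as f:
            ds = f["lfp"]
            region_lfp[region] = np.asarray(ds, dtype=np.float32)
            channel_ids[region] = [
                c.decode() if isinstance(c, bytes) else str(c) for c in ds.attrs["channel_ids"]
            ]
            fs_values.add(float(ds.attrs["fs"]))
    fs_values.add(float(meta["fs_lfp"]))
    if len(fs_values) != 1:
        raise SessionError(f"clock mismatch between files: fs values {sorted(fs_values)}")

    spikes_df = pd.read_csv(path / "spikes.csv")
    order = meta.get("unit_order") or sorted(spikes_df["unit_id"].astype(str).unique())
    trains = []
    for unit_id in order:
        sub = spikes_df[spikes_df["unit_id"].astype(str) == str(unit_id)]
        region = str(sub["region"].iloc[0]) if len(sub) else meta["regions"][0]
        trains.append(SpikeTrain(str(unit_id), region, np.sort(sub["time_s"].to_numpy(float))))

    events = make_event_table(pd.read_csv(path / "events.csv"))
    return RecordingSession(
        region_lfp=region_lfp,
        fs_lfp=float(meta["fs_lfp"]),
        spikes=trains,
        events=events,
        t0=float(meta["t0"]),
        channel_ids=channel_ids,
        provenance=meta.get("provenance", {}),
    )
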