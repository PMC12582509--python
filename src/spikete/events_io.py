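"""Event-timestamp containers and preprocessing.

All times are seconds as 64-bit floats, end to end.  The containers are
deliberately thin: a :class:`SpikeTrain` is a unit id plus a strictly
increasing array of spike times, a :class:`Recording` is a collection of
trains with an observation window, optionally carrying the electrode layout
of the recording apparatus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "Recording",
    "ElectrodeLayout",
    "read_spikes",
    "write_spikes",
    "read_layout",
    "jitter_spikes",
    "extract_window",
    "filter_min_spikes",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike timestamps of one unit, strictly increasing, in seconds."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError(f"train {self.unit_id!r}: times must be 1-D")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError(f"train {self.unit_id!r}: non-finite spike time")
        if t.size > 1:
            d = np.diff(t)
            if np.any(d < 0):
                raise ValueError(f"train {self.unit_id!r}: times not sorted")
            if np.any(d == 0):
                raise ValueError(f"train {self.unit_id!r}: duplicate spike times")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ElectrodeLayout:
    """Integer grid coordinates per unit and the electrode pitch (micron)."""

    positions: dict
    pitch_um: float = 200.0

    def __post_init__(self):
        seen = set()
        for uid, rc in self.positions.items():
            rc = (int(rc[0]), int(rc[1]))
            if rc in seen:
                raise ValueError(f"duplicate electrode coordinate {rc}")
            seen.add(rc)


@dataclass(frozen=True)
class Recording:
    """A set of spike trains observed on a common window [t_start, t_end]."""

    trains: tuple
    t_start: float
    t_end: float
    layout: ElectrodeLayout | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        trains = tuple(self.trains)
        object.__setattr__(self, "trains", trains)
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        ids = [tr.unit_id for tr in trains]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique")
        for tr in trains:
            if tr.times.size and (
                tr.times[0] < self.t_start or tr.times[-1] > self.t_end
            ):
                raise ValueError(
                    f"train {tr.unit_id!r} has spikes outside "
                    f"[{self.t_start}, {self.t_end}]"
                )
        object.__setattr__(self, "_index", {tr.unit_id: tr for tr in trains})

    @property
    def unit_ids(self):
        return [tr.unit_id for tr in self.trains]

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def train(self, unit_id) -> SpikeTrain:
        return self._index[unit_id]

    def replace_trains(self, trains) -> "Recording":
        return Recording(tuple(trains), self.t_start, self.t_end, self.layout)

    @classmethod
    def from_trains(cls, trains, t_start=None, t_end=None, layout=None):
        trains = tuple(trains)
        all_times = np.concatenate([tr.times for tr in trains if len(tr)] or [[0.0]])
        if t_start is None:
            t_start = float(all_times.min())
        if t_end is None:
            t_end = float(all_times.max())
        if t_end <= t_start:  # single spike time or empty
            t_end = t_start + np.finfo(float).eps * max(1.0, abs(t_start))
        return cls(trains, t_start, t_end, layout)


def read_spikes(path, format: str = "long", t_start=None, t_end=None) -> Recording:
    """Read spike timestamps from disk.

    ``format="long"`` expects a TSV with header ``unit_id<TAB>time_s``;
    ``format="per-unit"`` expects a directory of ``<unit_id>.txt`` files,
    one timestamp per line.  Unsorted input is sorted with a warning;
    duplicate timestamps within a train are an error.
    """
    path = Path(path)
    groups: dict[str, np.ndarray] = {}
    if format == "long":
        try:
            df = pd.read_csv(
                path, sep="\t", dtype={"unit_id": str},
                float_precision="round_trip",
            )
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: no events") from None
        if not {"unit_id", "time_s"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'unit_id' and 'time_s'")
        bad = ~np.isfinite(pd.to_numeric(df["time_s"], errors="coerce"))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}: unparseable time on line {line}")
        for uid, sub in df.groupby("unit_id", sort=True):
            groups[str(uid)] = sub["time_s"].to_numpy(dtype=np.float64)
    elif format == "per-unit":
        files = sorted(path.glob("*.txt"))
        if not files:
            raise ValueError(f"{path}: no events")
        for f in files:
            arr = np.loadtxt(f, dtype=np.float64, ndmin=1)
            groups[f.stem] = arr
    else:
        raise ValueError(f"unknown format {format!r}")

    if not groups or all(a.size == 0 for a in groups.values()):
        raise ValueError(f"{path}: no events")

    trains = []
    for uid, arr in groups.items():
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            warnings.warn(f"train {uid!r}: input times unsorted; sorting")
            arr = np.sort(arr)
        trains.append(SpikeTrain(uid, arr))
    return Recording.from_trains(trains, t_start=t_start, t_end=t_end)


def write_spikes(recording: Recording, path, format: str = "long") -> None:
    """Write a recording; a long-table round-trip is lossless at float64."""
    path = Path(path)
    if format == "long":
        rows = []
        for tr in recording.trains:
            for t in tr.times:
                rows.append((tr.unit_id, repr(float(t))))
        with open(path, "w") as fh:
            fh.write("unit_id\ttime_s\n")
            for uid, t in rows:
                fh.write(f"{uid}\t{t}\n")
    elif format == "per-unit":
        path.mkdir(parents=True, exist_ok=True)
        for tr in recording.trains:
            with open(path / f"{tr.unit_id}.txt", "w") as fh:
                for t in tr.times:
                    fh.write(repr(float(t)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_layout(path, pitch_um: float = 200.0) -> ElectrodeLayout:
    """Read an electrode-layout TSV with columns ``unit_id row col``."""
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    positions = {
        str(r.unit_id): (int(r.row), int(r.col)) for r in df.itertuples(index=False)
    }
    return ElectrodeLayout(positions, pitch_um=pitch_um)


def jitter_spikes(train: SpikeTrain, half_width: float, rng) -> SpikeTrain:
    """Add independent Uniform(-half_width, +half_width) noise to spike times.

    Used to break grid quantisation of acquisition-clock timestamps before
    estimation.  Colliding pairs (exact duplicates after the jitter) are
    re-drawn.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0 or len(train) == 0:
        return train
    t = train.times + rng.uniform(-half_width, half_width, size=len(train))
    t = np.sort(t)
    for _ in range(100):
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size == 0:
            break
        redraw = np.unique(np.concatenate([dup, dup + 1]))
        t[redraw] = np.sort(t)[redraw] + rng.uniform(
            -half_width, half_width, size=redraw.size
        )
        t = np.sort(t)
    else:  # pragma: no cover
        raise RuntimeError("could not resolve duplicate times by re-drawing")
    return SpikeTrain(train.unit_id, t)


def jitter_recording(recording: Recording, half_width: float, rng) -> Recording:
    """Jitter every train; the window is widened by half_width on each side."""
    trains = [jitter_spikes(tr, half_width, rng) for tr in recording.trains]
    return Recording(
        tuple(trains),
        recording.t_start - half_width,
        recording.t_end + half_width,
        recording.layout,
    )


def extract_window(recording: Recording, start: float, duration: float) -> Recording:
    """Keep only spikes in [start, start + duration]; reset the window bounds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    end = start + duration
    trains = []
    for tr in recording.trains:
        lo = np.searchsorted(tr.times, start, side="left")
        hi = np.searchsorted(tr.times, end, side="right")
        trains.append(SpikeTrain(tr.unit_id, tr.times[lo:hi]))
    return Recording(tuple(trains), start, end, recording.layout)


def filter_min_spikes(recording: Recording, min_count: int) -> Recording:
    """Drop trains with fewer than ``min_count`` spikes (removal is logged)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    kept, removed = [], []
    for tr in recording.trains:
        (kept if len(tr) >= min_count else removed).append(tr)
    if removed:
        logger.info(
            "filter_min_spikes: removed %d unit(s): %s",
            len(removed),
            [tr.unit_id for tr in removed],
        )
    if not kept:
        raise ValueError("no units remain after spike-count filtering")
    return recording.replace_trains(kept)
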