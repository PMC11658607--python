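"""Event-coded dyadic behavior: reading, validation, rasterization, budgets.

Coded behavior arrives as intervals — one row per gaze fixation on an item,
pointing gesture, or conversational turn — with onsets/offsets in seconds.
Within one (actor, track) the intervals must be mutually exclusive, and the
turn track of the two actors together must tile the conversation with no gaps
("always one of the two participants' turn").  Intervals are rasterized to
categorical series by instantaneous sampling on the half-open convention:
sample k (at time k/rate) takes the category of the interval with
onset <= k/rate < offset, else OFF.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .series import DEFAULT_ITEMS, MASK, OFF, CategoricalSeries

ACTORS = ("trained", "untrained")
TRACKS = ("gaze", "point", "turn")
EVENT_COLUMNS = ["dyad_id", "actor", "track", "category", "onset_s", "offset_s"]

_TOL = 1e-9


class EventParseError(ValueError):
    """A row of the event table could not be parsed."""


class EventValidationError(ValueError):
    """The event table violates an interval invariant."""


@dataclass
class EventTable:
    """Validated coded-behavior intervals for one dyad."""

    df: pd.DataFrame
    item_set: tuple[str, ...] = DEFAULT_ITEMS
    dyad_id: str = field(init=False)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise EventParseError(f"missing columns: {missing}")
        self.df = df[EVENT_COLUMNS].copy()
        self.item_set = tuple(self.item_set)
        ids = sorted(set(self.df["dyad_id"].astype(str)))
        if len(ids) != 1:
            raise EventValidationError(f"expected exactly one dyad_id, got {ids}")
        self.dyad_id = ids[0]
        self._validate()

    def _validate(self) -> None:
        df = self.df
        for col in ("onset_s", "offset_s"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad):
                raise EventParseError(f"non-numeric {col} in row {bad[0]}")
            df[col] = vals.astype(float)
        if (df["onset_s"] < 0).any():
            row = int(df.index[df["onset_s"] < 0][0])
            raise EventValidationError(f"negative onset in row {row}")
        short = df["offset_s"] <= df["onset_s"]
        if short.any():
            row = int(df.index[short][0])
            raise EventValidationError(f"offset <= onset in row {row}")
        bad_actor = ~df["actor"].isin(ACTORS)
        if bad_actor.any():
            raise EventParseError(
                f"unknown actor {df['actor'][bad_actor].iloc[0]!r} (expected {ACTORS})")
        bad_track = ~df["track"].isin(TRACKS)
        if bad_track.any():
            raise EventParseError(
                f"unknown track {df['track'][bad_track].iloc[0]!r} (expected {TRACKS})")

        items = set(self.item_set)
        for (actor, track), sub in df.groupby(["actor", "track"], sort=False):
            cats = set(sub["category"])
            if track == "turn":
                bad = cats - set(ACTORS)
            else:
                bad = cats - items
            if bad:
                raise EventValidationError(
                    f"category {sorted(bad)} not allowed on ({actor}, {track})")
            sub = sub.sort_values("onset_s")
            overlap = sub["onset_s"].values[1:] < sub["offset_s"].values[:-1] - _TOL
            if overlap.any():
                t = sub["onset_s"].values[1:][overlap][0]
                raise EventValidationError(
                    f"overlapping intervals on ({actor}, {track}) near t={t:g}s")

        turns = df[df["track"] == "turn"].sort_values("onset_s")
        if len(turns):
            on = turns["onset_s"].values
            off = turns["offset_s"].values
            if abs(on[0]) > _TOL:
                raise EventValidationError(f"turn track starts at t={on[0]:g}s, not 0")
            gaps = np.abs(on[1:] - off[:-1]) > _TOL
            if gaps.any():
                t = off[:-1][gaps][0]
                raise EventValidationError(f"turn track gap/overlap near t={t:g}s")

    @property
    def duration_s(self) -> float:
        turns = self.df[self.df["track"] == "turn"]
        if len(turns):
            return float(turns["offset_s"].max())
        return float(self.df["offset_s"].max())

    def track(self, actor: str, track: str) -> pd.DataFrame:
        sel = (self.df["actor"] == actor) & (self.df["track"] == track)
        return self.df[sel].sort_values("onset_s").reset_index(drop=True)

    def turn_intervals(self) -> pd.DataFrame:
        """Turn intervals across both actors, sorted; category = speaker."""
        sel = self.df["track"] == "turn"
        return self.df[sel].sort_values("onset_s").reset_index(drop=True)


@dataclass
class DyadRecord:
    """All six rasterized series of one dyad, sharing rate and length."""

    dyad_id: str
    gaze_trained: CategoricalSeries
    gaze_untrained: CategoricalSeries
    point_trained: CategoricalSeries
    point_untrained: CategoricalSeries
    turn: CategoricalSeries

    def __post_init__(self) -> None:
        ref = self.gaze_trained
        for s in self.series_dict().values():
            if len(s) != len(ref) or s.rate_hz != ref.rate_hz:
                raise EventValidationError("all series must share rate and length")
        if any(v in (OFF, MASK) for v in self.turn.values):
            raise EventValidationError("turn series may not contain OFF/MASK")
        if set(self.turn.labels) != set(ACTORS):
            raise EventValidationError(f"turn labels must be {ACTORS}")

    def series_dict(self) -> dict[str, CategoricalSeries]:
        return {
            "gaze_trained": self.gaze_trained,
            "gaze_untrained": self.gaze_untrained,
            "point_trained": self.point_trained,
            "point_untrained": self.point_untrained,
            "turn": self.turn,
        }

    @property
    def rate_hz(self) -> float:
        return self.gaze_trained.rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.gaze_trained)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


def read_events(source, item_set: Iterable[str] = DEFAULT_ITEMS) -> EventTable:
    """Read an event CSV (columns dyad_id,actor,track,category,onset_s,offset_s)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype={"category": str, "dyad_id": str})
    return EventTable(df, item_set=tuple(item_set))


def write_events(table: EventTable, path) -> None:
    table.df.to_csv(path, index=False)


def _raster_indices(onset_s: float, offset_s: float, rate_hz: float) -> tuple[int, int]:
    # half-open [onset, offset): smallest k with k/rate >= onset up to
    # (exclusive) smallest k with k/rate >= offset
    k0 = int(math.ceil(onset_s * rate_hz - _TOL))
    k1 = int(math.ceil(offset_s * rate_hz - _TOL))
    return max(k0, 0), k1


def events_to_series(
    events: EventTable,
    rate_hz: float = 10.0,
    duration_s: float | None = None,
) -> DyadRecord:
    """Rasterize an event table into a :class:`DyadRecord` at ``rate_hz``."""
    max_off = float(events.df["offset_s"].max())
    if duration_s is None:
        duration_s = events.duration_s
    if duration_s < max_off - _TOL:
        raise EventValidationError(
            f"duration_s={duration_s:g} shorter than last offset {max_off:g}")
    n = int(math.ceil(duration_s * rate_hz - _TOL))

    def raster(sub: pd.DataFrame, labels: tuple[str, ...], name: str) -> CategoricalSeries:
        vals = np.full(n, OFF, dtype=object)
        for row in sub.itertuples(index=False):
            k0, k1 = _raster_indices(row.onset_s, row.offset_s, rate_hz)
            vals[k0:min(k1, n)] = row.category
        return CategoricalSeries(vals, labels=labels, rate_hz=rate_hz, name=name)

    turn_vals = np.full(n, OFF, dtype=object)
    for row in events.turn_intervals().itertuples(index=False):
        k0, k1 = _raster_indices(row.onset_s, row.offset_s, rate_hz)
        turn_vals[k0:min(k1, n)] = row.category
    if OFF in set(turn_vals):
        k = int(np.argmax(turn_vals == OFF))
        raise EventValidationError(f"turn gap at sample {k} (t={k / rate_hz:g}s)")
    turn = CategoricalSeries(turn_vals, labels=ACTORS, rate_hz=rate_hz, name="turn")

    kw = dict(dyad_id=events.dyad_id, turn=turn)
    for actor in ACTORS:
        for track in ("gaze", "point"):
            kw[f"{track}_{actor}"] = raster(
                events.track(actor, track), events.item_set, f"{track}_{actor}")
    return DyadRecord(**kw)


def series_to_events(
    series: CategoricalSeries, dyad_id: str, actor: str, track: str
) -> pd.DataFrame:
    """Convert a series back to interval rows (inverse of rasterization).

    Runs of identical non-OFF labels become intervals on sample boundaries.
    MASK is an analysis-time construct and is never serialized.
    """
    if MASK in set(series.values):
        raise EventValidationError("MASK samples cannot be serialized to events")
    rows = []
    vals = series.values
    n = len(vals)
    k = 0
    while k < n:
        lab = vals[k]
        k1 = k + 1
        while k1 < n and vals[k1] == lab:
            k1 += 1
        if lab != OFF:
            rows.append((dyad_id, actor, track, lab,
                         k / series.rate_hz, k1 / series.rate_hz))
        k = k1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def record_to_events(record: DyadRecord) -> EventTable:
    """Serialize a DyadRecord as an event table (turn rows attributed to the speaker)."""
    frames = []
    for actor in ACTORS:
        for track in ("gaze", "point"):
            s = getattr(record, f"{track}_{actor}")
            frames.append(series_to_events(s, record.dyad_id, actor, track))
    turn_rows = series_to_events(record.turn, record.dyad_id, ACTORS[0], "turn")
    turn_rows["actor"] = turn_rows["category"]
    frames.append(turn_rows)
    frames = [f for f in frames if len(f)]
    df = pd.concat(frames, ignore_index=True)
    item_set = record.gaze_trained.labels
    return EventTable(df, item_set=item_set)


def record_to_frame(record: DyadRecord) -> pd.DataFrame:
    """Wide series table: time_s plus one column per (actor, track); OFF -> ''."""
    out = {"time_s": record.gaze_trained.times_s}
    for name, s in record.series_dict().items():
        col = np.asarray(s.values, dtype=object).copy()
        col[col == OFF] = ""
        out[name] = col
    return pd.DataFrame(out)


def time_budget(record: DyadRecord) -> pd.DataFrame:
    """Per-actor fractions of the conversation spent speaking and pointing."""
    turn = np.asarray(record.turn.values)
    rows = []
    for actor in ACTORS:
        point = getattr(record, f"point_{actor}")
        rows.append({
            "actor": actor,
            "speaking_frac": float(np.mean(turn == actor)),
            "pointing_frac": point.fraction_on(),
        })
    return pd.DataFrame(rows)


def cohens_kappa(coder_a: CategoricalSeries, coder_b: CategoricalSeries) -> float:
    """Cohen's kappa between two coders' series of the same stream.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the two coders' marginal label frequencies (OFF counts
    as a coding decision).  When p_e = 1 (both coders constant and identical)
    agreement is trivially perfect and 1.0 is returned.
    """
    if len(coder_a) != len(coder_b):
        raise EventValidationError("coder series must have equal length")
    if set(coder_a.labels) != set(coder_b.labels):
        raise EventValidationError("coder series must share the label set")
    a = np.asarray(coder_a.values)
    b = np.asarray(coder_b.values)
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = sorted(set(a) | set(b), key=str)
    p = np.array([np.mean(a == c) for c in cats])
    q = np.array([np.mean(b == c) for c in cats])
    p_e = float(p @ q)
    if p_e >= 1.0 - _TOL:
        if p_o >= 1.0 - _TOL:
            return 1.0
        raise EventValidationError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)
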