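"""Nominal cross-recurrence: point sets, diagonal profiles, baselines, CORM.

Two categorical series recur at index pair (i, j) when X[i] == Y[j] and
neither sample is OFF or MASK.  The lag of a point is d = j - i, so positive
lags mean the row series X visits a state before the column series Y matches
it (X leads).  The diagonal cross-recurrence profile (DCRP) is the recurrence
rate per lag over a window of +/- L samples, aggregated into equal-width lag
bins; the banded center of recurrence mass (CORM) is the normalized signed
mean lag of recurrent points within +/- B samples of the line of coincidence,
quantifying which stream leads even when the DCRP peaks at lag 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import ACTORS, DyadRecord
from .series import CategoricalSeries


class RecurrenceConfigError(ValueError):
    """Invalid lag-window / bin configuration."""


@dataclass
class RecurrenceSet:
    """Sparse set of recurrent (i, j) index pairs for one series pair."""

    n: int
    i: np.ndarray
    j: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        if self.i.shape != self.j.shape:
            raise ValueError("i and j must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.i)

    @property
    def lags(self) -> np.ndarray:
        """Signed lag d = j - i of every point."""
        return self.j - self.i

    def as_pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def transpose(self) -> "RecurrenceSet":
        """The recurrence set of (Y, X): points mirrored across the diagonal."""
        meta = dict(self.meta)
        meta["x"], meta["y"] = meta.get("y"), meta.get("x")
        return RecurrenceSet(self.n, self.j.copy(), self.i.copy(), meta)


def recurrence_points(x: CategoricalSeries, y: CategoricalSeries) -> RecurrenceSet:
    """All recurrent index pairs of x (rows) and y (columns)."""
    if len(x) != len(y):
        raise ValueError(f"series lengths differ: {len(x)} vs {len(y)}")
    if x.rate_hz != y.rate_hz:
        raise ValueError("series rates differ")
    xc, yc = x.codes(), y.codes()
    match = (xc[:, None] == yc[None, :]) & (xc[:, None] >= 0)
    i, j = np.nonzero(match)
    return RecurrenceSet(len(x), i, j, meta={"x": x.name, "y": y.name, "rate_hz": x.rate_hz})


def lag_counts(rec: RecurrenceSet, L: int) -> np.ndarray:
    """Number of recurrent points on each diagonal d = -L..L."""
    d = rec.lags
    d = d[np.abs(d) <= L]
    return np.bincount(d + L, minlength=2 * L + 1)


@dataclass
class DCRP:
    """Diagonal cross-recurrence profile with its binned form.

    ``rr[k]`` is the recurrence rate at lag ``lags[k]``, normalized by the
    diagonal length n - |d|; ``binned_rr`` averages rr over ``n_bins``
    equal-width contiguous lag groups whose central lags are ``bin_lags``.
    """

    L: int
    n_bins: int
    rr: np.ndarray
    rate_hz: float = 10.0
    meta: dict = field(default_factory=dict)
    shuffle_binned: np.ndarray | None = None  # per-shuffle binned profiles, if any

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if len(self.rr) != 2 * self.L + 1:
            raise RecurrenceConfigError("rr must have 2L+1 entries")
        if (2 * self.L + 1) % self.n_bins:
            raise RecurrenceConfigError(
                f"2L+1 = {2 * self.L + 1} lags not divisible by n_bins = {self.n_bins}")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.L, self.L + 1)

    @property
    def lags_s(self) -> np.ndarray:
        return self.lags / self.rate_hz

    @property
    def bin_width(self) -> int:
        return (2 * self.L + 1) // self.n_bins

    @property
    def bin_lags(self) -> np.ndarray:
        w = self.bin_width
        return self.lags[w // 2::w][: self.n_bins]

    @property
    def bin_lags_s(self) -> np.ndarray:
        return self.bin_lags / self.rate_hz

    @property
    def binned_rr(self) -> np.ndarray:
        return self.rr.reshape(self.n_bins, self.bin_width).mean(axis=1)

    def peak_lag(self, binned: bool = False) -> int:
        """Lag (samples) of maximal rr; ties break toward 0, then negative."""
        lags = self.bin_lags if binned else self.lags
        vals = self.binned_rr if binned else self.rr
        top = np.flatnonzero(vals == vals.max())
        best = min(top, key=lambda k: (abs(int(lags[k])), int(lags[k])))
        return int(lags[best])


def _diag_lengths(n: int, L: int) -> np.ndarray:
    return n - np.abs(np.arange(-L, L + 1))


def dcrp(rec: RecurrenceSet, L: int = 150, n_bins: int = 43) -> DCRP:
    """Recurrence rate per lag d = -L..L, with equal-width bin aggregation."""
    if L >= rec.n:
        raise RecurrenceConfigError(f"L = {L} must be < series length {rec.n}")
    if (2 * L + 1) % n_bins:
        raise RecurrenceConfigError(
            f"2L+1 = {2 * L + 1} lags not divisible by n_bins = {n_bins}")
    counts = lag_counts(rec, L)
    rr = counts / _diag_lengths(rec.n, L)
    rate = float(rec.meta.get("rate_hz", 10.0))
    return DCRP(L=L, n_bins=n_bins, rr=rr, rate_hz=rate, meta=dict(rec.meta))


def rr_by_lag(xc: np.ndarray, yc: np.ndarray, L: int) -> np.ndarray:
    """Recurrence rate per lag from integer codes, without the full plot.

    Equivalent to ``dcrp(recurrence_points(x, y), L, ...).rr``; used where the
    point set itself is not needed (shuffle baselines, large batch runs).
    """
    n = len(xc)
    rr = np.empty(2 * L + 1)
    valid_x = xc >= 0
    for d in range(-L, L + 1):
        if d >= 0:
            a, b, v = xc[: n - d], yc[d:], valid_x[: n - d]
        else:
            a, b, v = xc[-d:], yc[: n + d], valid_x[-d:]
        rr[d + L] = np.count_nonzero((a == b) & v) / (n - abs(d))
    return rr


def dcrp_fast(x: CategoricalSeries, y: CategoricalSeries,
              L: int = 150, n_bins: int = 43) -> DCRP:
    """DCRP computed directly from the series (no materialized point set)."""
    if len(x) != len(y):
        raise ValueError(f"series lengths differ: {len(x)} vs {len(y)}")
    if L >= len(x):
        raise RecurrenceConfigError(f"L = {L} must be < series length {len(x)}")
    if (2 * L + 1) % n_bins:
        raise RecurrenceConfigError(
            f"2L+1 = {2 * L + 1} lags not divisible by n_bins = {n_bins}")
    rr = rr_by_lag(x.codes(), y.codes(), L)
    return DCRP(L=L, n_bins=n_bins, rr=rr, rate_hz=x.rate_hz,
                meta={"x": x.name, "y": y.name})


def shuffle_baseline(
    x: CategoricalSeries,
    y: CategoricalSeries,
    L: int = 150,
    n_bins: int = 43,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> DCRP:
    """Chance-level DCRP from within-dyad shuffling.

    Each shuffle applies an independent uniform permutation to the sample
    order of x and of y (OFF samples permuted along with the rest), which
    preserves label frequencies but destroys temporal structure; the mean
    profile over shuffles is returned, with the per-shuffle binned profiles
    attached as ``shuffle_binned`` for Monte-Carlo error estimates.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xc, yc = x.codes(), y.codes()
    acc = np.zeros(2 * L + 1)
    binned = np.empty((n_shuffles, n_bins))
    w = (2 * L + 1) // n_bins
    if (2 * L + 1) % n_bins:
        raise RecurrenceConfigError(
            f"2L+1 = {2 * L + 1} lags not divisible by n_bins = {n_bins}")
    for s in range(n_shuffles):
        rr = rr_by_lag(rng.permutation(xc), rng.permutation(yc), L)
        acc += rr
        binned[s] = rr.reshape(n_bins, w).mean(axis=1)
    out = DCRP(L=L, n_bins=n_bins, rr=acc / n_shuffles, rate_hz=x.rate_hz,
               meta={"x": x.name, "y": y.name, "baseline": "shuffle",
                     "n_shuffles": n_shuffles})
    out.shuffle_binned = binned
    return out


def condition_on_turn(
    record: DyadRecord,
    speaker: str,
    track_x: str = "gaze_trained",
    track_y: str = "gaze_untrained",
) -> tuple[CategoricalSeries, CategoricalSeries]:
    """Restrict a series pair to one speaker's conversational turns.

    Every sample whose turn label differs from ``speaker`` is replaced by
    MASK in both series; the time axis is unchanged, so a recurrence point of
    the conditioned pair requires both of its coordinates to lie inside the
    speaker's turns (no spurious lags across turn boundaries).
    """
    if speaker not in ACTORS:
        raise ValueError(f"unknown speaker {speaker!r} (expected one of {ACTORS})")
    keep = np.asarray(record.turn.values) == speaker
    out = []
    for track in (track_x, track_y):
        s = record.series_dict()[track]
        vals = np.asarray(s.values, dtype=object).copy()
        vals[~keep] = "MASK"
        out.append(s.replace(vals, name=f"{s.name}|{speaker}_speaking"))
    return out[0], out[1]


@dataclass
class CORMResult:
    """Banded center-of-recurrence-mass lead/lag statistic.

    ``value`` is the mean signed lag of recurrent points within the band,
    divided by the band half-width B: dimensionless, in [-1, 1], positive when
    the row series leads.  ``empty_band`` flags a band with no points (value 0).
    """

    value: float
    band_samples: int
    n_points: int
    meta: dict = field(default_factory=dict)

    @property
    def empty_band(self) -> bool:
        return self.n_points == 0


def corm(rec: RecurrenceSet, B: int = 40) -> CORMResult:
    """CORM of the points with |j - i| <= B."""
    if B < 1:
        raise ValueError("band B must be >= 1 sample")
    d = rec.lags
    d = d[np.abs(d) <= B]
    if len(d) == 0:
        return CORMResult(0.0, B, 0, meta=dict(rec.meta))
    value = float(d.sum()) / (B * len(d))
    return CORMResult(value, B, len(d), meta=dict(rec.meta))


def corm_fast(x: CategoricalSeries, y: CategoricalSeries, B: int = 40) -> CORMResult:
    """CORM computed without materializing the recurrence plot."""
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    xc, yc = x.codes(), y.codes()
    n = len(xc)
    valid_x = xc >= 0
    total = 0
    count = 0
    for d in range(-B, B + 1):
        if d >= 0:
            m = np.count_nonzero((xc[: n - d] == yc[d:]) & valid_x[: n - d])
        else:
            m = np.count_nonzero((xc[-d:] == yc[: n + d]) & valid_x[-d:])
        total += d * m
        count += m
    if count == 0:
        return CORMResult(0.0, B, 0, meta={"x": x.name, "y": y.name})
    return CORMResult(total / (B * count), B, count, meta={"x": x.name, "y": y.name})
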