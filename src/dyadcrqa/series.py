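"""Categorical time series sampled at a fixed rate.

A series holds one label per sample drawn from a declared item set plus two
sentinels: ``OFF`` ("not on any task item") and ``MASK`` ("excluded by a
conditioning filter", e.g. samples outside a speaker's conversational turns).
Neither sentinel ever counts as a recurrence match, including with itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OFF = "OFF"
MASK = "MASK"

#: integer codes used internally; any negative code is a non-matching state
OFF_CODE = -1
MASK_CODE = -2

DEFAULT_ITEMS = tuple("ABCDEFGHI")


class SeriesError(ValueError):
    """Invalid categorical series."""


@dataclass
class CategoricalSeries:
    """A fixed-rate sequence of category labels.

    Parameters
    ----------
    values
        Label per sample; members of ``labels`` or the ``OFF``/``MASK``
        sentinels.
    labels
        The ordered item set (default: nine items ``A``..``I``).
    rate_hz
        Samples per second (default 10).
    """

    values: np.ndarray
    labels: tuple[str, ...] = DEFAULT_ITEMS
    rate_hz: float = 10.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=object)
        self.labels = tuple(self.labels)
        if self.rate_hz <= 0:
            raise SeriesError("rate_hz must be positive")
        if OFF in self.labels or MASK in self.labels:
            raise SeriesError(f"labels may not contain the sentinels {OFF!r}/{MASK!r}")
        allowed = set(self.labels) | {OFF, MASK}
        bad = {v for v in self.values if v not in allowed}
        if bad:
            raise SeriesError(f"values outside label set: {sorted(map(str, bad))}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz

    def codes(self) -> np.ndarray:
        """Integer codes: label index, ``-1`` for OFF, ``-2`` for MASK."""
        lut = {lab: k for k, lab in enumerate(self.labels)}
        lut[OFF] = OFF_CODE
        lut[MASK] = MASK_CODE
        return np.fromiter((lut[v] for v in self.values), dtype=np.int64, count=len(self))

    @classmethod
    def from_codes(
        cls,
        codes: np.ndarray,
        labels: tuple[str, ...] = DEFAULT_ITEMS,
        rate_hz: float = 10.0,
        name: str = "",
    ) -> "CategoricalSeries":
        labels = tuple(labels)
        out = np.empty(len(codes), dtype=object)
        codes = np.asarray(codes)
        for k, lab in enumerate(labels):
            out[codes == k] = lab
        out[codes == OFF_CODE] = OFF
        out[codes == MASK_CODE] = MASK
        if any(v is None for v in out):
            raise SeriesError("codes outside the declared label range")
        return cls(out, labels=labels, rate_hz=rate_hz, name=name)

    def replace(self, values: np.ndarray, name: str | None = None) -> "CategoricalSeries":
        return CategoricalSeries(
            values, labels=self.labels, rate_hz=self.rate_hz,
            name=self.name if name is None else name,
        )

    def fraction_on(self) -> float:
        """Fraction of samples on some item (neither OFF nor MASK)."""
        return float(np.mean([(v != OFF and v != MASK) for v in self.values])) if len(self) else 0.0
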