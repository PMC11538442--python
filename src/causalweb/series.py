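"""Core time-series containers.

A :class:`UniformSeries` is a regularly sampled abundance series: values on a
0-based integer time index with unit steps, optionally tagged with calendar
months (1..12) so that season-preserving surrogates can be built from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SeriesLengthError(ValueError):
    """Raised when a series is too short for a requested operation."""


class ConstantSeriesError(ValueError):
    """Raised when an operation is undefined on a constant series."""


@dataclass(frozen=True)
class UniformSeries:
    """One regularly sampled time series.

    Parameters
    ----------
    values:
        Abundance (arbitrary units). May contain NaN for missing samples.
    time_index:
        Strictly increasing integer sample times with unit steps. Defaults
        to ``0..len(values)-1``.
    month_labels:
        Optional calendar month (1..12) per sample.
    name:
        Identifier used in networks and file output.
    """

    values: np.ndarray
    time_index: np.ndarray = None  # type: ignore[assignment]
    month_labels: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) < 1:
            raise ValueError("values must be a non-empty 1-D array")
        object.__setattr__(self, "values", values)
        if self.time_index is None:
            time_index = np.arange(len(values))
        else:
            time_index = np.asarray(self.time_index, dtype=int)
        if len(time_index) != len(values):
            raise ValueError("time_index and values must have equal length")
        if len(time_index) > 1 and not np.all(np.diff(time_index) == 1):
            raise ValueError("time_index must increase in unit steps")
        object.__setattr__(self, "time_index", time_index)
        if self.month_labels is not None:
            months = np.asarray(self.month_labels, dtype=int)
            if len(months) != len(values):
                raise ValueError("month_labels must match values in length")
            if months.min() < 1 or months.max() > 12:
                raise ValueError("month_labels must lie in 1..12")
            object.__setattr__(self, "month_labels", months)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_time(self) -> int:
        return int(self.time_index[0])

    def value_at(self, t: int) -> float:
        """Value at integer time ``t``; NaN if ``t`` is outside the series."""
        pos = t - self.start_time
        if pos < 0 or pos >= len(self.values):
            return float("nan")
        return float(self.values[pos])

    def with_values(self, values: np.ndarray, name: str | None = None) -> "UniformSeries":
        """Copy of this series with new values on the same time index."""
        return UniformSeries(
            values=np.asarray(values, dtype=float),
            time_index=self.time_index,
            month_labels=self.month_labels,
            name=self.name if name is None else name,
        )


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters.

    ``E`` is the embedding dimension, ``tau`` the delay between coordinates
    (in sample steps) and ``tp`` the prediction offset: cross-map predictions
    target the driver at time ``t + tp`` (negative values predict the past).
    """

    E: int
    tau: int = 1
    tp: int = 0

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError(f"E must be >= 1, got {self.E}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")

    @property
    def span(self) -> int:
        """Temporal span of one delay vector, ``(E-1)*tau``."""
        return (self.E - 1) * self.tau

    def min_length(self) -> int:
        """Shortest series that admits at least one delay vector."""
        return self.span + 1
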