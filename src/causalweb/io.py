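"""Reading and writing the pipeline's file formats.

Time series travel as wide CSV: a first column holding either an integer
sample index or an ISO year-month (``2001-05``), then one numeric column per
taxon.  Month labels are derived from year-month dates.  Missing cells
(empty or ``NA``) become NaN.  Group maps and run configuration are JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .series import UniformSeries

logger = logging.getLogger(__name__)

_MISSING = {"", "NA", "NaN", "nan"}


class SeriesCSVError(ValueError):
    """Parse error in a wide series CSV, with the offending line number."""


def _parse_time_column(raw: list[str]) -> tuple[np.ndarray, np.ndarray | None]:
    """Integer time index plus month labels (if the column is year-month)."""
    first = raw[0].strip()
    if "-" in first and not first.lstrip("-").isdigit():
        months = []
        for i, cell in enumerate(raw):
            try:
                year_s, month_s = cell.strip().split("-")[:2]
                months.append((int(year_s), int(month_s)))
            except (ValueError, IndexError) as err:
                raise SeriesCSVError(
                    f"line {i + 2}: cannot parse year-month {cell!r}"
                ) from err
        labels = np.array([m for (_, m) in months])
        if labels.min() < 1 or labels.max() > 12:
            raise SeriesCSVError("month outside 1..12 in time column")
        serial = np.array([y * 12 + (m - 1) for (y, m) in months])
        time_index = serial - serial[0]
        return time_index, labels
    try:
        time_index = np.array([int(c) for c in raw])
    except ValueError as err:
        raise SeriesCSVError(f"non-integer time value in time column: {err}") from err
    time_index = time_index - time_index[0]
    return time_index, None


def read_series_csv(path: str | Path) -> list[UniformSeries]:
    """Read a wide CSV into one :class:`UniformSeries` per data column."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesCSVError(f"{path}: empty file") from None
        rows = list(reader)
    if len(header) < 2:
        raise SeriesCSVError(f"{path}: need a time column plus at least one series")
    names = [h.strip() for h in header[1:]]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise SeriesCSVError(f"{path}: duplicate column names {sorted(dupes)}")
    n_cols = len(header)
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise SeriesCSVError(
                f"{path} line {i + 2}: expected {n_cols} cells, got {len(row)}"
            )
    if not rows:
        raise SeriesCSVError(f"{path}: no data rows")
    time_index, month_labels = _parse_time_column([r[0] for r in rows])
    if len(time_index) > 1:
        d = np.diff(time_index)
        if (d <= 0).any():
            bad = int(np.argmax(d <= 0))
            raise SeriesCSVError(
                f"{path} line {bad + 3}: time column not strictly increasing"
            )
        if (d != 1).any():
            bad = int(np.argmax(d != 1))
            raise SeriesCSVError(
                f"{path} line {bad + 3}: time column must advance in unit steps"
            )
    values = np.empty((len(rows), len(names)))
    for i, row in enumerate(rows):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in _MISSING:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as err:
                    raise SeriesCSVError(
                        f"{path} line {i + 2}: bad numeric value {cell!r} "
                        f"in column {names[j]!r}"
                    ) from err
    return [
        UniformSeries(values[:, j], time_index=time_index,
                      month_labels=month_labels, name=names[j])
        for j in range(len(names))
    ]


def write_series_csv(
    path: str | Path, series: Sequence[UniformSeries], float_fmt: str = "%.10g"
) -> None:
    """Write aligned series as a wide CSV (integer time column ``t``)."""
    if not series:
        raise ValueError("nothing to write")
    t0 = series[0]
    for s in series[1:]:
        if len(s) != len(t0) or s.start_time != t0.start_time:
            raise ValueError(f"series {s.name!r} not aligned with {t0.name!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t"] + [s.name for s in series])
        for i, t in enumerate(t0.time_index):
            row = [str(int(t))]
            for s in series:
                v = s.values[i]
                row.append("" if np.isnan(v) else float_fmt % v)
            writer.writerow(row)


def filter_taxa(
    series: Sequence[UniformSeries], min_nonzero: int = 35
) -> list[UniformSeries]:
    """Drop series with fewer than ``min_nonzero`` non-zero samples.

    Sparse, intermittently observed taxa carry too little dynamical signal
    for state-space reconstruction; the boundary is inclusive (a series
    with exactly ``min_nonzero`` non-zero points is retained).
    """
    kept = []
    for s in series:
        n_nonzero = int(np.sum(~np.isnan(s.values) & (s.values != 0)))
        if n_nonzero >= min_nonzero:
            kept.append(s)
        else:
            logger.info(
                "filter_taxa: dropping %r (%d non-zero points < %d)",
                s.name, n_nonzero, min_nonzero,
            )
    if series and not kept:
        raise ValueError(
            f"all {len(series)} series removed by the min_nonzero={min_nonzero} filter"
        )
    return kept


def read_group_map(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        mapping = json.load(fh)
    if not isinstance(mapping, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()
    ):
        raise ValueError(f"{path}: group map must be a JSON object of strings")
    return mapping


def write_edge_list_csv(path: str | Path, network) -> None:
    """Write every tested link of a network as CSV."""
    rows = [
        {
            "source": l.source, "target": l.target, "rho": l.rho,
            "null_kind": l.null_kind, "null_value": l.null_value,
            "accepted": l.accepted, "E": l.E_used, "tau": l.tau, "tp": l.tp,
            "degenerate": l.degenerate, "untestable": l.untestable,
        }
        for l in network.links
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def network_to_adjacency_json(path: str | Path, network) -> None:
    """Accepted links as a simple adjacency JSON."""
    adj = {node: [] for node in network.nodes}
    for (s, t) in sorted(network.accepted_edges()):
        adj[s].append(t)
    with open(path, "w") as fh:
        json.dump({"scale": network.scale_label, "adjacency": adj}, fh, indent=2)
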