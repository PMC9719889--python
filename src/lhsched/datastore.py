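"""File-backed time-series store for process and application data.

Stands in for the time-series database of the production system: every
persisted record is a tagged data point (measurement name, simulated
timestamp, tag map, field map) and the key ``(measurement, timestamp,
tags)`` is unique — rewriting an existing key overwrites the point rather
than duplicating it.  Queries filter by measurement, tag equality and a
half-open time range; exports (CSV or JSON-lines) round-trip losslessly.

Storage is a JSON-lines append log plus an in-memory index per run; the
log is the durable artifact of an experiment and is what the greedy-replay
verification reads back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd


@dataclass(frozen=True)
class TimeSeriesPoint:
    measurement: str
    timestamp: float
    tags: dict
    fields: dict

    def key(self) -> tuple:
        return (
            self.measurement,
            float(self.timestamp),
            tuple(sorted(self.tags.items())),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "measurement": self.measurement,
                "timestamp": self.timestamp,
                "tags": dict(sorted(self.tags.items())),
                "fields": dict(sorted(self.fields.items())),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "TimeSeriesPoint":
        d = json.loads(line)
        return cls(d["measurement"], float(d["timestamp"]), d["tags"], d["fields"])


@dataclass(frozen=True)
class QueryFilter:
    """Measurement + tag-equality + half-open time-range filter."""

    measurement: str
    tag_equals: dict = field(default_factory=dict)
    time_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.time_range is not None and self.time_range[0] > self.time_range[1]:
            raise ValueError("time_range start must be <= end")

    def matches(self, p: TimeSeriesPoint) -> bool:
        if p.measurement != self.measurement:
            return False
        for k, v in self.tag_equals.items():
            if p.tags.get(k) != v:
                return False
        if self.time_range is not None:
            start, end = self.time_range
            if not (start <= p.timestamp < end):
                return False
        return True


class StoreClosedError(RuntimeError):
    pass


def _sort_key(p: TimeSeriesPoint) -> tuple:
    return (p.timestamp, p.tags.get("reactor", ""), tuple(sorted(p.tags.items())))


class DataStore:
    """Append-log time-series store with unique-key overwrite semantics."""

    def __init__(self, path: str | Path | None = None):
        self._points: dict[tuple, TimeSeriesPoint] = {}
        self._path = Path(path) if path is not None else None
        self._fh: IO[str] | None = None
        if self._path is not None:
            self._path.parent.mkdir(parents=True, exist_ok=True)
            self._fh = open(self._path, "w")
        self._closed = False

    def write_points(self, points: Iterable[TimeSeriesPoint]) -> int:
        """Persist points; returns the number of *new* unique keys written."""
        if self._closed:
            raise StoreClosedError("write after store closed")
        new = 0
        for p in points:
            k = p.key()
            if k not in self._points:
                new += 1
            self._points[k] = p
            if self._fh is not None:
                self._fh.write(p.to_json() + "\n")
        return new

    def query(self, flt: QueryFilter) -> list[TimeSeriesPoint]:
        """Exact filter scan, sorted by timestamp then reactor tag."""
        hits = [p for p in self._points.values() if flt.matches(p)]
        hits.sort(key=_sort_key)
        return hits

    def export(self, flt: QueryFilter, path: str | Path, fmt: str = "csv") -> Path:
        """Export a query result; columns are measurement, timestamp, tags, fields.

        Tag columns are prefixed ``tag_`` and field columns ``field_`` so a
        re-import can reconstruct the exact point set (round-trip).
        """
        path = Path(path)
        hits = self.query(flt)
        tag_keys = sorted({k for p in hits for k in p.tags})
        field_keys = sorted({k for p in hits for k in p.fields})
        if fmt == "jsonl":
            with open(path, "w") as fh:
                for p in hits:
                    fh.write(p.to_json() + "\n")
            return path
        if fmt != "csv":
            raise ValueError(f"unknown export format {fmt!r}")
        cols = (
            ["measurement", "timestamp"]
            + [f"tag_{k}" for k in tag_keys]
            + [f"field_{k}" for k in field_keys]
        )
        rows = []
        for p in hits:
            row = {"measurement": p.measurement, "timestamp": p.timestamp}
            for k in tag_keys:
                row[f"tag_{k}"] = p.tags.get(k, "")
            for k in field_keys:
                row[f"field_{k}"] = p.fields.get(k, "")
            rows.append(row)
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    def flush(self) -> None:
        if self._fh is not None:
            self._fh.flush()

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None
        self._closed = True

    def __len__(self) -> int:
        return len(self._points)

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "DataStore":
        """Load a persisted append log into a read-only in-memory store."""
        store = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    p = TimeSeriesPoint.from_json(line)
                    store._points[p.key()] = p
        return store


def import_csv(path: str | Path) -> list[TimeSeriesPoint]:
    """Reconstruct points from a CSV export (inverse of DataStore.export)."""
    df = pd.read_csv(path, dtype={"measurement": str}, keep_default_na=False)
    points = []
    for _, row in df.iterrows():
        tags = {
            c[4:]: str(row[c])
            for c in df.columns
            if c.startswith("tag_") and row[c] != ""
        }
        fields = {
            c[6:]: float(row[c])
            for c in df.columns
            if c.startswith("field_") and row[c] != ""
        }
        points.append(
            TimeSeriesPoint(row["measurement"], float(row["timestamp"]), tags, fields)
        )
    return points
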