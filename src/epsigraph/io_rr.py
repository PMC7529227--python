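"""Readers and writers for R-R interval text files and cohort manifests.

RR files are whitespace-delimited text with one or two numeric columns
(the last column is the interval; an optional first column of timestamps
is ignored); ``#`` starts a comment.  Units are seconds or milliseconds,
with auto-detection by magnitude.  PhysioNet WFDB binary records are
deliberately not parsed — convert them to text RR first, e.g. with
``ann2rr -r <record> -a <annotator> -i s``.

A cohort manifest is a CSV with columns ``subject_id, group, path, units``
where group is VT (pre-tachyarrhythmia record), CR (matched control
record from the same subject) or HS (healthy subject); relative paths are
resolved against the manifest's directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["CohortRecord", "read_rr_file", "write_rr_file", "load_cohort", "write_cohort", "pair_records"]

GROUPS = ("VT", "CR", "HS")


@dataclass(frozen=True)
class CohortRecord:
    """One subject's RR series with its group label (RR in seconds)."""

    subject_id: str
    group: str
    rr: TimeSeries

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


class RRParseError(ValueError):
    """Raised for malformed RR text files; message names the line."""


def read_rr_file(path, units: str = "auto", max_rr_seconds: float = 5.0) -> TimeSeries:
    """Read an RR-interval text file into a series in seconds.

    Parameters
    ----------
    path:
        Whitespace-delimited text, 1 or 2 numeric columns (last = RR),
        ``#`` comments allowed.
    units:
        ``"s"``, ``"ms"``, or ``"auto"`` (median > 10 implies
        milliseconds, which are divided by 1000).
    max_rr_seconds:
        Physiological sanity bound; intervals at or above it (after unit
        conversion) are rejected.
    """
    if units not in ("s", "ms", "auto"):
        raise ValueError(f"units must be 's', 'ms' or 'auto', got {units!r}")
    values: list[float] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) > 2:
                raise RRParseError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(cols)}")
            try:
                v = float(cols[-1])
            except ValueError:
                raise RRParseError(f"{path}:{lineno}: non-numeric RR value {cols[-1]!r}") from None
            if not np.isfinite(v) or v <= 0:
                raise RRParseError(f"{path}:{lineno}: non-positive or non-finite RR value {cols[-1]}")
            values.append(v)
            lines.append(lineno)
    if not values:
        raise RRParseError(f"{path}: no RR samples found")
    arr = np.asarray(values)
    if units == "auto":
        units = "ms" if float(np.median(arr)) > 10 else "s"
    if units == "ms":
        arr = arr / 1000.0
    bad = np.nonzero(arr >= max_rr_seconds)[0]
    if bad.size:
        k = bad[0]
        raise RRParseError(
            f"{path}:{lines[k]}: RR interval {arr[k]:g} s exceeds the sanity bound {max_rr_seconds} s"
        )
    return TimeSeries(arr, units_label="s")


def write_rr_file(path, series: TimeSeries) -> None:
    """Write one RR value per line at full float precision (seconds)."""
    with open(path, "w") as fh:
        for v in series.values:
            fh.write(f"{float(v)!r}\n")


def pair_records(records: list[CohortRecord]) -> list[tuple[CohortRecord, CohortRecord]]:
    """Match VT records with their CR counterpart by subject_id."""
    vt = {r.subject_id: r for r in records if r.group == "VT"}
    cr = {r.subject_id: r for r in records if r.group == "CR"}
    missing = sorted(set(vt) ^ set(cr))
    if missing:
        raise ValueError(f"unpaired VT/CR subjects: {', '.join(missing)}")
    return [(vt[s], cr[s]) for s in sorted(vt)]


def load_cohort(
    manifest_path, require_pairs: bool = True, max_rr_seconds: float = 5.0
) -> list[CohortRecord]:
    """Load all records listed in a cohort manifest CSV.

    Verifies group labels, parses every RR file, and (by default) checks
    that every VT record has exactly one CR counterpart and vice versa.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype=str, comment="#", skipinitialspace=True)
    required = {"subject_id", "group", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}; got {list(table.columns)}")
    if len(table) == 0:
        raise ValueError(f"{manifest_path}: manifest lists no records")
    records = []
    for row in table.itertuples(index=False):
        group = str(row.group).strip()
        if group not in GROUPS:
            raise ValueError(f"{manifest_path}: invalid group {group!r} for subject {row.subject_id}")
        units = getattr(row, "units", None)
        units = "auto" if units is None or pd.isna(units) else str(units).strip()
        p = Path(str(row.path))
        if not p.is_absolute():
            p = manifest_path.parent / p
        rr = read_rr_file(p, units=units, max_rr_seconds=max_rr_seconds)
        records.append(CohortRecord(str(row.subject_id), group, rr))
    dup = pd.Series([(r.subject_id, r.group) for r in records])
    if dup.duplicated().any():
        raise ValueError(f"{manifest_path}: duplicate (subject_id, group) rows")
    if require_pairs:
        pair_records(records)
    return records


def write_cohort(records: list[CohortRecord], out_dir) -> Path:
    """Write records as RR text files plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        fname = f"{r.subject_id}_{r.group}.rr"
        write_rr_file(out_dir / fname, r.rr)
        rows.append({"subject_id": r.subject_id, "group": r.group, "path": fname, "units": "s"})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
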