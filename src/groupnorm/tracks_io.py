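"""Probe-level data model and track I/O.

Holds the in-memory containers shared by the whole package — an ordered
:class:`ProbeTable` of genomic probes, a :class:`SignalMatrix` of per-array
intensities aligned to it, and a :class:`NormalizedTrack` carrying one
normalized signal — plus readers and writers for the plain-text formats the
tool touches (tab-delimited probe tables, BED repeat masks, bedGraph, wiggle
and TSV output tracks).

Coordinates are 0-based half-open everywhere, matching BED/bedGraph.
Intensities are taken on the scale given in the input file; an optional
``log2`` flag on :func:`read_probe_table` is provided for users with raw
linear-scale values, default off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("groupnorm")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GroupNormError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GroupNormError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GroupNormError):
    """Input data violate a structural requirement."""


class ParameterError(GroupNormError):
    """A parameter value is outside its allowed range."""


class UsageError(GroupNormError):
    """The operation was invoked incorrectly (e.g. unknown format name)."""


class UndefinedResultError(GroupNormError):
    """The requested quantity is mathematically undefined for these inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeTable:
    """Ordered genomic probes with coordinates, ids and eligibility flags.

    Probes are sorted by (chromosome, start).  ``eligible`` is False exactly
    for probes whose interval overlaps a repeat-mask interval by >= 1 bp;
    ineligible probes are still normalized, they are only barred from serving
    as reference probes.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    probe_id: np.ndarray
    eligible: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.eligible = np.asarray(self.eligible, dtype=bool)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def centers(self) -> np.ndarray:
        """Midpoint of each probe interval, in bp (float)."""
        return (self.start + self.end) / 2.0

    def validate(self) -> None:
        n = len(self)
        for name in ("chrom", "end", "probe_id", "eligible"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name!r} length mismatch")
        if np.any(self.start >= self.end):
            i = int(np.flatnonzero(self.start >= self.end)[0])
            raise ValidationError(
                f"probe {self.probe_id[i]!r}: start ({self.start[i]}) >= end ({self.end[i]})"
            )
        ids, counts = np.unique(self.probe_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValidationError(f"duplicate probe_id {ids[counts > 1][0]!r}")
        if not self.is_sorted():
            raise ValidationError("probes are not sorted by (chromosome, start)")

    def is_sorted(self) -> bool:
        order = self.sort_order()
        return bool(np.all(order == np.arange(len(self))))

    def sort_order(self) -> np.ndarray:
        """Stable permutation sorting probes by (chromosome, start)."""
        return np.lexsort((self.start, self.chrom.astype(str)))

    def take(self, order: np.ndarray) -> "ProbeTable":
        return ProbeTable(
            chrom=self.chrom[order],
            start=self.start[order],
            end=self.end[order],
            probe_id=self.probe_id[order],
            eligible=self.eligible[order],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "start": self.start,
                "end": self.end,
                "probe_id": self.probe_id.astype(str),
                "eligible": self.eligible,
            }
        )


@dataclass
class SignalMatrix:
    """Per-array intensity vectors aligned to a :class:`ProbeTable`.

    ``values`` has one row per probe and one column per condition; every
    entry is finite.
    """

    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.conditions = list(self.conditions)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("SignalMatrix values must be 2-dimensional")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")
        if self.values.shape[1] != len(self.conditions):
            raise ValidationError("number of columns must equal number of conditions")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("SignalMatrix values must all be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, condition: str) -> np.ndarray:
        """The intensity vector for one named condition."""
        try:
            j = self.conditions.index(condition)
        except ValueError:
            raise ValidationError(f"unknown condition column {condition!r}") from None
        return self.values[:, j]

    def take(self, order: np.ndarray) -> "SignalMatrix":
        return SignalMatrix(self.conditions, self.values[order])


@dataclass
class NormalizedTrack:
    """Per-probe normalized signal; NaN marks undefined values.

    Undefined values arise only from the degenerate-denominator rule of
    binary group normalization.  ``method`` and ``params`` record provenance.
    """

    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


# ---------------------------------------------------------------------------
# Interval mask machinery
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge 0-based half-open intervals per chromosome.

    Returns ``{chrom: (starts, ends)}`` with the intervals sorted and
    non-overlapping.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValidationError(f"mask interval {chrom}:{start}-{end} has start >= end")
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out_s, out_e = [], []
        for s, e in ivs:
            if out_e and s <= out_e[-1]:
                out_e[-1] = max(out_e[-1], e)
            else:
                out_s.append(s)
                out_e.append(e)
        merged[chrom] = (np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64))
    return merged


def _overlaps_mask(table: ProbeTable, merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Boolean vector: probe interval overlaps some mask interval by >= 1 bp."""
    hit = np.zeros(len(table), dtype=bool)
    chroms = table.chrom.astype(str)
    known = set(np.unique(chroms))
    for chrom in merged:
        if chrom not in known:
            logger.warning("mask interval on unknown chromosome %r ignored", chrom)
    for chrom, (ms, me) in merged.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        ps, pe = table.start[sel], table.end[sel]
        # merged intervals are sorted & disjoint, so ends are increasing:
        # candidate intervals with start < probe.end are [0, idx); overlap iff
        # the largest of their ends exceeds probe.start.
        idx = np.searchsorted(ms, pe, side="left")
        has = idx > 0
        ov = np.zeros(sel.size, dtype=bool)
        ov[has] = me[idx[has] - 1] > ps[has]
        hit[sel] = ov
    return hit


def apply_repeat_mask(
    table: ProbeTable, mask: Iterable[tuple[str, int, int]]
) -> ProbeTable:
    """Mark probes overlapping any mask interval (>= 1 bp) as ineligible.

    Probe set and order are unchanged; eligibility is recomputed from the
    mask alone, so masking is idempotent.  Mask intervals on chromosomes not
    present in the table are ignored with a logged warning.
    """
    merged = merge_intervals(mask)
    hit = _overlaps_mask(table, merged)
    return replace(table, eligible=~hit)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file (0-based half-open); extra columns are ignored."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer BED coordinate"
                ) from None
            intervals.append((parts[0], s, e))
    return intervals


# ---------------------------------------------------------------------------
# Probe-table reading
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("chrom", "start", "end", "probe_id")


def read_probe_table(
    path, mask_path=None, *, log2: bool = False
) -> tuple[ProbeTable, SignalMatrix]:
    """Read a tab-delimited probe table (and optional BED mask).

    The file must have a header row ``chrom  start  end  probe_id`` followed
    by >= 1 numeric condition column.  Probes are re-sorted by
    (chromosome, start) if needed, with signal rows permuted consistently.
    Eligibility is computed from the mask (all-eligible when no mask).

    With ``log2=True`` intensities are log2-transformed on load (for users
    whose input is raw linear-scale values); default is to use values
    as given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if tuple(cols[:4]) != REQUIRED_COLUMNS:
        raise ParseError(
            f"{path}: header must start with {' '.join(REQUIRED_COLUMNS)}; got {cols[:4]}"
        )
    cond_cols = cols[4:]
    if not cond_cols:
        raise ParseError(f"{path}: no condition columns after probe_id")

    def _numeric(col: str, as_int: bool) -> np.ndarray:
        # python float() parsing is exact, so repr-formatted TSVs round-trip
        raw = df[col].tolist()
        arr = np.empty(len(raw), dtype=np.float64)
        for i, s in enumerate(raw):
            try:
                v = float(s)
                if math.isnan(v):
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {i + 2}: malformed numeric value "
                    f"{s!r} in column {col!r}"
                ) from None
            arr[i] = v
        if as_int:
            if np.any(arr != np.floor(arr)):
                row = int(np.flatnonzero(arr != np.floor(arr))[0])
                raise ParseError(
                    f"{path}: line {row + 2}: non-integer coordinate in column {col!r}"
                )
            return arr.astype(np.int64)
        return arr

    start = _numeric("start", as_int=True)
    end = _numeric("end", as_int=True)
    values = np.column_stack([_numeric(c, as_int=False) for c in cond_cols])
    if log2:
        if np.any(values <= 0):
            raise ValidationError(f"{path}: log2 transform requires positive intensities")
        values = np.log2(values)

    table = ProbeTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=start,
        end=end,
        probe_id=df["probe_id"].to_numpy(dtype=object),
        eligible=np.ones(len(df), dtype=bool),
    )
    order = table.sort_order()
    if not np.all(order == np.arange(len(table))):
        table = table.take(order)
        values = values[order]
    table.validate()
    if mask_path is not None:
        table = apply_repeat_mask(table, read_bed(mask_path))
    return table, SignalMatrix(cond_cols, values)


# ---------------------------------------------------------------------------
# Track writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # shortest decimal representation that round-trips to the same float
    return repr(float(v))


def write_track(table: ProbeTable, track: NormalizedTrack, path, format: str = "bedgraph") -> None:
    """Write a normalized track as bedGraph, wiggle (variableStep) or TSV.

    bedGraph/wiggle omit undefined (NaN) values; TSV writes the sentinel
    token ``NA`` so the full probe set round-trips.  TSV values use decimal
    round-trip formatting, so reading them back reproduces the floats
    bit-exactly.
    """
    if len(track) != len(table):
        raise ValidationError("track is not aligned to the probe table")
    vals = track.values
    if format == "bedgraph":
        with open(path, "w") as fh:
            for i in range(len(table)):
                if math.isnan(vals[i]):
                    continue
                fh.write(f"{table.chrom[i]}\t{table.start[i]}\t{table.end[i]}\t{_fmt(vals[i])}\n")
    elif format == "wiggle":
        with open(path, "w") as fh:
            cur = (None, None)  # (chrom, span)
            for i in range(len(table)):
                if math.isnan(vals[i]):
                    continue
                span = int(table.end[i] - table.start[i])
                key = (table.chrom[i], span)
                if key != cur:
                    fh.write(f"variableStep chrom={table.chrom[i]} span={span}\n")
                    cur = key
                fh.write(f"{table.start[i] + 1}\t{_fmt(vals[i])}\n")  # wiggle is 1-based
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tprobe_id\tvalue\n")
            for i in range(len(table)):
                v = "NA" if math.isnan(vals[i]) else _fmt(vals[i])
                fh.write(f"{table.chrom[i]}\t{table.start[i]}\t{table.end[i]}\t{table.probe_id[i]}\t{v}\n")
    else:
        raise UsageError(f"unknown track format {format!r} (expected bedgraph, wiggle or tsv)")


def read_track_tsv(path) -> tuple[ProbeTable, NormalizedTrack]:
    """Read back a TSV track written by :func:`write_track` (NA -> NaN)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["chrom", "start", "end", "probe_id", "value"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    # python float() parsing is exact, so repr-formatted values round-trip
    vals = np.array(
        [np.nan if s == "NA" else float(s) for s in df["value"]], dtype=np.float64
    )
    table = ProbeTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        probe_id=df["probe_id"].to_numpy(dtype=object),
        eligible=np.ones(len(df), dtype=bool),
    )
    return table, NormalizedTrack(vals, method="tsv", params={"path": str(path)})


def write_bed(intervals: Sequence[tuple[str, int, int]], path) -> None:
    """Write intervals as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")
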