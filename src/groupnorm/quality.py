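"""Signal Quality (S/N) evaluation and the autocorrelation diagnostic.

Signal Quality compares two experimental conditions A and B plus a
replicate of B.  Significantly changed probes are the top fraction (2% by
default) ranked by the absolute difference of the two tracks after spatial
averaging over a 147 bp window (the nucleosome footprint); to avoid biasing
the comparison toward one normalization approach, the intersection of the
changed sets from each approach is used.  The signal power S is the mean
square change over those probes between conditions A and B; the noise power
is the mean square change over all probes between condition B and its
replicate; Signal Quality in dB is ``10 * log10(S / noise)``.

The autocorrelation diagnostic computes the lagged Pearson correlation of a
track with itself along the genome.  Nucleosome packing makes occupancy
tracks periodic on the scale of the ~147 bp footprint plus linker, so a
recurrence near ~170 bp indicates preserved biological structure.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tracks_io import (
    NormalizedTrack,
    ParameterError,
    ProbeTable,
    UndefinedResultError,
    ValidationError,
)

logger = logging.getLogger("groupnorm")

#: Nucleosome-footprint smoothing window for changed-probe selection, bp.
DEFAULT_WINDOW_BP = 147
#: Fraction of probes taken as significantly changed.
DEFAULT_CHANGED_FRACTION = 0.02


@dataclass
class QualityReport:
    """Signal Quality summary: powers, dB, and the changed set used."""

    signal_power: float
    noise_power: float
    quality_db: float
    changed_set: np.ndarray
    window_bp: int

    @property
    def n_changed(self) -> int:
        return int(self.changed_set.size)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"signal_power\t{self.signal_power!r}\n")
            fh.write(f"noise_power\t{self.noise_power!r}\n")
            fh.write(f"quality_db\t{self.quality_db!r}\n")
            fh.write(f"n_changed\t{self.n_changed}\n")
            fh.write(f"window_bp\t{self.window_bp}\n")


def _as_values(track) -> np.ndarray:
    if isinstance(track, NormalizedTrack):
        return track.values
    return np.asarray(track, dtype=np.float64)


def running_average(values, table: ProbeTable, window_bp: int) -> np.ndarray:
    """Spatial running average over a genomic window.

    Each probe's smoothed value is the unweighted mean over all probes on
    the same chromosome whose centre lies within +/- window_bp/2 of its own
    centre (inclusive); windows truncate at chromosome ends.
    """
    values = _as_values(values)
    if window_bp < 1:
        raise ParameterError(f"window_bp must be >= 1, got {window_bp}")
    if len(values) != len(table):
        raise ValidationError("track is not aligned to the probe table")
    centers = table.centers
    half = window_bp / 2.0
    out = np.empty(len(values))
    chroms = table.chrom.astype(str)
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        c = centers[sel]
        v = values[sel]
        csum = np.concatenate(([0.0], np.cumsum(v)))
        lo = np.searchsorted(c, c - half, side="left")
        hi = np.searchsorted(c, c + half, side="right")
        out[sel] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def select_changed_probes(
    track_a,
    track_b,
    table: ProbeTable,
    window_bp: int = DEFAULT_WINDOW_BP,
    fraction: float = DEFAULT_CHANGED_FRACTION,
) -> np.ndarray:
    """Top-fraction probes by absolute spatially averaged difference.

    Both tracks are smoothed with ``window_bp``; probes are ranked by the
    absolute smoothed difference descending (ties broken by probe index)
    and the top ``ceil(fraction * n)`` indices are returned, sorted
    ascending.
    """
    a = _as_values(track_a)
    b = _as_values(track_b)
    if a.shape != b.shape or len(a) != len(table):
        raise ValidationError("tracks are not aligned")
    if not (0 < fraction <= 1):
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    diff = np.abs(
        running_average(a, table, window_bp) - running_average(b, table, window_bp)
    )
    order = np.argsort(-diff, kind="stable")  # descending; ties by probe index
    k = math.ceil(fraction * len(a))
    return np.sort(order[:k])


def intersect_changed(sets: Sequence[np.ndarray]) -> np.ndarray:
    """Intersection of changed-probe index sets."""
    if len(sets) == 0:
        raise ParameterError("need at least one changed-probe set")
    out = np.asarray(sets[0], dtype=np.int64)
    for s in sets[1:]:
        out = np.intersect1d(out, np.asarray(s, dtype=np.int64))
    return out


def signal_quality_db(
    norm_a,
    norm_b,
    norm_b_replicate,
    changed: np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> QualityReport:
    """Signal Quality in dB from two conditions and a replicate.

    ``S`` is the mean square difference between conditions A and B over the
    changed probes (unsmoothed tracks); the noise power is the mean square
    difference between condition B and its replicate over all probes;
    ``quality_db = 10 * log10(S / noise)``.
    """
    a = _as_values(norm_a)
    b = _as_values(norm_b)
    br = _as_values(norm_b_replicate)
    if not (a.shape == b.shape == br.shape):
        raise ValidationError("tracks are not aligned")
    changed = np.asarray(changed, dtype=np.int64)
    if changed.size == 0:
        raise ParameterError("changed-probe set is empty")
    with np.errstate(invalid="ignore"):
        s_terms = (a[changed] - b[changed]) ** 2
        n_terms = (b - br) ** 2
    signal_power = float(np.nanmean(s_terms))
    noise_power = float(np.nanmean(n_terms))
    if noise_power == 0:
        raise UndefinedResultError("zero noise power: condition B equals its replicate")
    return QualityReport(
        signal_power=signal_power,
        noise_power=noise_power,
        quality_db=10.0 * math.log10(signal_power / noise_power),
        changed_set=changed,
        window_bp=window_bp,
    )


def signal_noise_combinations(
    group_a: Sequence[str], group_b: Sequence[str], symmetric: bool = True
) -> list[tuple[str, str, str]]:
    """Enumerate (A-array, B-array, B-replicate) combinations.

    For each array in the first group and each ordered pair of distinct
    arrays in the second, yields one (a, b, b_replicate) triple; with
    ``symmetric`` the roles of the two groups are also swapped, e.g. three
    arrays per condition give 2 * 3 * 3 * 2 = 36 combinations.
    """
    combos = [
        (a, b, br)
        for a in group_a
        for b, br in itertools.permutations(group_b, 2)
    ]
    if symmetric:
        combos += [
            (b, a, ar)
            for b in group_b
            for a, ar in itertools.permutations(group_a, 2)
        ]
    return combos


def autocorrelation(
    track,
    table: ProbeTable,
    max_lag_bp: int,
    step_bp: int,
) -> dict[int, float]:
    """Genomic autocorrelation of a track at lags 0, step, 2*step, ...

    At each lag, probes are paired with the probe (same chromosome) whose
    centre is nearest to their own centre plus the lag, within a tolerance
    of step_bp/2; the Pearson correlation over all pairs is reported.  Lags
    with fewer than 3 pairs (or zero variance) are omitted.  Lag 0 is 1 by
    definition.
    """
    v = _as_values(track)
    if len(v) != len(table):
        raise ValidationError("track is not aligned to the probe table")
    if step_bp < 1 or max_lag_bp < 0:
        raise ParameterError("step_bp must be >= 1 and max_lag_bp >= 0")
    centers = table.centers
    chroms = table.chrom.astype(str)
    chrom_sel = {c: np.flatnonzero(chroms == c) for c in np.unique(chroms)}
    tol = step_bp / 2.0
    result: dict[int, float] = {}
    for lag in range(0, max_lag_bp + 1, step_bp):
        if lag == 0:
            result[0] = 1.0
            continue
        xs, ys = [], []
        for sel in chrom_sel.values():
            c = centers[sel]
            target = c + lag
            j = np.searchsorted(c, target)
            # candidates j and j-1; pick the nearest
            j_lo = np.clip(j - 1, 0, c.size - 1)
            j_hi = np.clip(j, 0, c.size - 1)
            d_lo = np.abs(c[j_lo] - target)
            d_hi = np.abs(c[j_hi] - target)
            best = np.where(d_hi < d_lo, j_hi, j_lo)
            dist = np.minimum(d_lo, d_hi)
            ok = dist <= tol
            if np.any(ok):
                xs.append(v[sel[ok]])
                ys.append(v[sel[best[ok]]])
        if not xs:
            continue
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        good = ~(np.isnan(x) | np.isnan(y))
        x, y = x[good], y[good]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        result[lag] = float(np.corrcoef(x, y)[0, 1])
    return result
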