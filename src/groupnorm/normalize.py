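"""Normalization core.

Observed probe signal is modelled as

    y_i = A_i * x_i + B_i + eps_i

with x_i the unitless biological signal (0 for fully unbound, 1 for fully
bound in the nucleosome-occupancy case), A_i a probe-specific efficiency,
B_i a probe-specific background and eps_i random noise.  Group
Normalization estimates the per-probe dynamics from each probe's reference
set rather than from a sequence model:

* **binary group normalization** — sort the reference-set members by their
  treatment value and take the means of a low and a high rank window,
  mu_low and mu_high, which stand in for B_i and A_i + B_i; the normalized
  value is ``(y_i - mu_low) / (mu_high - mu_low)``.  It is not clipped to
  [0, 1].
* **quantile-based group normalization** — average the sorted reference-set
  distributions over all probes, then map each probe's fractional rank
  within its own reference set onto that average distribution.
* **cross normalization** — normalize condition A using reference sets
  built from condition B and vice versa, amplifying the differences between
  the two conditions; both asymmetric tracks are returned.
* **global quantile normalization** — the conventional baseline that forces
  all conditions onto the rank-wise mean distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .reference_sets import (
    FILL,
    ReferenceAssignment,
    assign_single_reference,
)
from .tracks_io import (
    NormalizedTrack,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger("groupnorm")

#: Relative threshold below which mu_high - mu_low is treated as degenerate.
DEGENERATE_DELTA = 1e-9


@dataclass(frozen=True)
class RangeSpec:
    """Fractional rank ranges defining the low and high signal windows.

    ``low = (f1, f2]`` and ``high = (g1, g2]`` are fraction intervals with
    ``0 <= f1 < f2 <= g1 < g2 <= 1``.  Over a size-N reference set the
    interval (a, b] selects 1-based ranks ``floor(a*N)+1 .. floor(b*N)``, so
    the default 30%/30% split at N = 1000 selects ranks 1-300 and 701-1000
    when given as (0, 0.3) and (0.7, 1.0).  The default windows are the
    10-40% / 60-90% ranges used throughout.
    """

    low: tuple[float, float] = (0.10, 0.40)
    high: tuple[float, float] = (0.60, 0.90)

    def __post_init__(self) -> None:
        f1, f2 = self.low
        g1, g2 = self.high
        if not (0 <= f1 < f2 <= g1 < g2 <= 1):
            raise ParameterError(
                f"invalid ranges low={self.low} high={self.high}: "
                "need 0 <= f1 < f2 <= g1 < g2 <= 1"
            )

    def window(self, which: str, n: int) -> slice:
        """0-based slice of sorted positions for the named window."""
        a, b = self.low if which == "low" else self.high
        start = math.floor(a * n)
        stop = math.floor(b * n)
        if stop <= start:
            raise ParameterError(
                f"{which} range ({a}, {b}] selects no ranks for set size {n}"
            )
        return slice(start, stop)


@dataclass
class ProbeDynamics:
    """Per-probe low/high signal-level estimates (mu_low <= mu_high)."""

    mu_low: np.ndarray
    mu_high: np.ndarray


def _member_values(treatment: np.ndarray, assignment: ReferenceAssignment) -> np.ndarray:
    members = assignment.members
    if members.size and (members.max() >= len(treatment)):
        raise ValidationError("treatment vector is not aligned to the assignment")
    return members


def estimate_dynamics(
    treatment: np.ndarray,
    assignment: ReferenceAssignment,
    ranges: RangeSpec = RangeSpec(),
) -> ProbeDynamics:
    """Estimate mu_low/mu_high for every probe.

    Each probe's reference-set members are sorted ascending by their value
    in the treatment condition; mu_low and mu_high are the means over the
    low and high rank windows of ``ranges``.
    """
    treatment = np.asarray(treatment, dtype=np.float64)
    members = _member_values(treatment, assignment)
    n, k = members.shape
    mu_low = np.empty(n)
    mu_high = np.empty(n)
    if assignment.uniform:
        ranges.window("low", k)  # validate windows non-empty up front
        ranges.window("high", k)
        vals = treatment[members]
        vals.sort(axis=1)
        mu_low[:] = vals[:, ranges.window("low", k)].mean(axis=1)
        mu_high[:] = vals[:, ranges.window("high", k)].mean(axis=1)
    else:
        counts = assignment.counts
        for i in range(n):
            row = members[i]
            vals = np.sort(treatment[row[row != FILL]])
            m = counts[i]
            mu_low[i] = vals[ranges.window("low", m)].mean()
            mu_high[i] = vals[ranges.window("high", m)].mean()
    return ProbeDynamics(mu_low=mu_low, mu_high=mu_high)


def binary_group_normalize(
    treatment: np.ndarray,
    assignment: ReferenceAssignment,
    ranges: RangeSpec = RangeSpec(),
) -> NormalizedTrack:
    """Binary group normalization: ``(y - mu_low) / (mu_high - mu_low)``.

    Probes whose reference set is degenerate — ``mu_high - mu_low`` at or
    below :data:`DEGENERATE_DELTA` relative to the magnitudes involved — get
    an undefined (NaN) value, and the count is logged.  Output is not
    clipped to [0, 1].
    """
    treatment = np.asarray(treatment, dtype=np.float64)
    dyn = estimate_dynamics(treatment, assignment, ranges)
    denom = dyn.mu_high - dyn.mu_low
    scale = np.maximum(np.maximum(np.abs(dyn.mu_high), np.abs(dyn.mu_low)), 1.0)
    degenerate = denom <= DEGENERATE_DELTA * scale
    values = np.full(len(treatment), np.nan)
    ok = ~degenerate
    values[ok] = (treatment[ok] - dyn.mu_low[ok]) / denom[ok]
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("binary group normalization: %d probes with degenerate reference sets", n_deg)
    return NormalizedTrack(
        values,
        method="binary_gn",
        params={
            "N": assignment.N,
            "ranges": (ranges.low, ranges.high),
            "assignment": assignment.method,
            "n_degenerate": n_deg,
        },
    )


def quantile_group_normalize(
    treatment: np.ndarray, assignment: ReferenceAssignment
) -> NormalizedTrack:
    """Quantile-based group normalization.

    (i) each probe's reference-set member values are sorted ascending;
    (ii) the sorted distributions are averaged componentwise over all probes
    (shrunken sets are excluded from the average, with a warning);
    (iii) each probe's fractional rank within its own reference set — the
    count of members <= its value, linearly interpolated between the
    bracketing member values — is mapped onto the average distribution,
    clamped to its ends outside the support.
    """
    treatment = np.asarray(treatment, dtype=np.float64)
    members = _member_values(treatment, assignment)
    n, k = members.shape
    if k < 2 or assignment.N < 2:
        raise ParameterError("quantile group normalization requires reference sets of size >= 2")
    counts = assignment.counts
    full = counts == k
    if not np.all(full):
        logger.warning(
            "quantile group normalization: %d shrunken reference sets excluded "
            "from the average distribution",
            int((~full).sum()),
        )
        if not np.any(full):
            raise ValidationError("no full-size reference sets to average")
    sorted_full = treatment[members[full]]
    sorted_full.sort(axis=1)
    avg = sorted_full.mean(axis=0)  # ascending by construction

    values = np.empty(n)
    for i in range(n):
        row = members[i]
        s = np.sort(treatment[row[row != FILL]])
        m = s.size
        y = treatment[i]
        j = int(np.searchsorted(s, y, side="right"))  # count of members <= y
        if j == 0:
            rho = 1.0
        elif j == m or y >= s[-1]:
            rho = float(m)
        else:
            span = s[j] - s[j - 1]
            frac = 0.0 if span == 0 else (y - s[j - 1]) / span
            rho = j + frac
        # continuous rank in [1, m] -> position on the averaged distribution
        p = (rho - 1.0) / (m - 1.0) * (k - 1.0)
        lo = int(math.floor(p))
        if lo >= k - 1:
            values[i] = avg[-1]
        else:
            values[i] = avg[lo] + (p - lo) * (avg[lo + 1] - avg[lo])
    return NormalizedTrack(
        values,
        method="quantile_gn",
        params={"N": assignment.N, "assignment": assignment.method},
    )


def cross_normalize(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    eligible: np.ndarray,
    N: int = 1000,
    method: str = "binary",
    ranges: RangeSpec = RangeSpec(),
) -> tuple[NormalizedTrack, NormalizedTrack]:
    """Cross normalization of two experimental conditions.

    Condition B serves as the reference condition for normalizing condition
    A, and vice versa; this amplifies the differences between the two
    signals.  The correspondence between the two asymmetric outputs is a
    measure of the reliability of detected changes and is left to the
    caller — both tracks are returned as ``(a_vs_b, b_vs_a)``.
    """
    cond_a = np.asarray(cond_a, dtype=np.float64)
    cond_b = np.asarray(cond_b, dtype=np.float64)
    if cond_a.shape != cond_b.shape:
        raise ValidationError("condition vectors are not aligned")

    def _run(treatment, reference):
        asg = assign_single_reference(reference, eligible, N)
        if method == "binary":
            return binary_group_normalize(treatment, asg, ranges)
        if method == "quantile":
            return quantile_group_normalize(treatment, asg)
        raise ParameterError(f"unknown method {method!r} (expected binary or quantile)")

    track_a = _run(cond_a, cond_b)
    track_b = _run(cond_b, cond_a)
    for t, lbl in ((track_a, "a_vs_b"), (track_b, "b_vs_a")):
        t.params["cross"] = lbl
    return track_a, track_b


def global_quantile_normalize(signals: list[np.ndarray]) -> list[np.ndarray]:
    """Conventional quantile normalization across >= 2 aligned conditions.

    Every condition is mapped onto the shared target distribution formed by
    the rank-wise mean of the sorted condition vectors; tied values receive
    the mean of the target values at their tied rank positions.
    """
    vecs = [np.asarray(v, dtype=np.float64) for v in signals]
    if len(vecs) < 2:
        raise ParameterError("global quantile normalization needs >= 2 conditions")
    if len({v.shape for v in vecs}) != 1 or vecs[0].ndim != 1:
        raise ValidationError("condition vectors are not aligned")
    n = vecs[0].size
    target = np.mean(np.sort(np.column_stack(vecs), axis=0), axis=1)
    out = []
    for v in vecs:
        order = np.argsort(v, kind="stable")
        sv = v[order]
        starts = np.r_[0, np.flatnonzero(np.diff(sv) != 0) + 1]
        lens = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(target, starts) / lens
        res = np.empty(n)
        res[order] = np.repeat(group_means, lens)
        out.append(res)
    return out
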