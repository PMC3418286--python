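"""Reference-set assignment.

The heart of Group Normalization is, for every probe p_i, a set Ref(p_i) of
N probes with similar probe effects — similar hybridization efficiency A_i
and background B_i — estimated from one or more reference (genomic control)
hybridizations, in which every probe sees the same amount of target DNA.
Three constructions are provided:

* **single**: sort all probes by their value in one reference condition and
  take the N sorted-order neighbours of each probe;
* **sorted_average**: the same, on the per-probe mean over multiple
  reference conditions;
* **min_distance**: the N nearest probes in the M-dimensional reference
  condition space, under a selectable metric (euclidean default; chebyshev
  and manhattan also supported).

Probes flagged ineligible (repeat regions) never serve as reference-set
members, and a probe is never a member of its own set.  Ties are always
broken by original probe index (stable), so assignments are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .tracks_io import ParameterError, ValidationError

logger = logging.getLogger("groupnorm")

#: Default reference-set size.
DEFAULT_N = 1000

_METRICS = {"euclidean": "euclidean", "chebyshev": "chebyshev", "manhattan": "cityblock"}

FILL = -1  # padding value for rows whose reference set is smaller than the widest


@dataclass
class ReferenceAssignment:
    """For each probe, the indices of its reference-set members.

    ``members`` is an ``(n_probes, k)`` integer array of probe indices into
    the originating probe table, padded with :data:`FILL` where a probe's set
    is smaller than ``k`` (only possible when fewer than N+1 eligible probes
    exist).  Members are always eligible probes and never the probe itself.
    """

    N: int
    members: np.ndarray
    method: str
    metric: str | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)

    def __len__(self) -> int:
        return self.members.shape[0]

    @property
    def set_size(self) -> int:
        """Width of the member matrix (= N when enough eligible probes exist)."""
        return self.members.shape[1]

    @property
    def counts(self) -> np.ndarray:
        """Actual member count per probe."""
        return (self.members != FILL).sum(axis=1)

    @property
    def uniform(self) -> bool:
        return not np.any(self.members == FILL)

    def member_sets(self) -> list[set[int]]:
        """Member indices as Python sets (mostly for tests and debugging)."""
        return [set(row[row != FILL].tolist()) for row in self.members]

    def write_debug_tsv(self, probe_ids: Sequence[str], path) -> None:
        """Dump ``probe_id -> member ids`` for inspection."""
        ids = np.asarray(probe_ids)
        with open(path, "w") as fh:
            fh.write("probe_id\tmembers\n")
            for i, row in enumerate(self.members):
                mem = ",".join(str(ids[j]) for j in row if j != FILL)
                fh.write(f"{ids[i]}\t{mem}\n")


def _check_common(eligible: np.ndarray, N: int) -> np.ndarray:
    eligible = np.asarray(eligible, dtype=bool)
    if N < 2:
        raise ParameterError(f"reference-set size N must be >= 2, got {N}")
    if not np.any(eligible):
        raise ValidationError("all probes are ineligible; cannot build reference sets")
    n_elig = int(eligible.sum())
    if n_elig < N + 1:
        logger.warning(
            "only %d eligible probes for N=%d: reference sets will shrink", n_elig, N
        )
    return eligible


def assign_single_reference(
    ref_signal: np.ndarray, eligible: np.ndarray, N: int = DEFAULT_N
) -> ReferenceAssignment:
    """Reference sets from a single reference condition.

    Probes are sorted ascending by ``ref_signal`` (ties broken by probe
    index, stable).  For an eligible probe at sorted position r among n
    eligible probes, the member window is the ideal centred span
    [r - ceil(N/2), r + floor(N/2)] of sorted positions, clamped (shifted)
    into [1, n] so that exactly N members remain after excluding the probe
    itself.  An ineligible probe receives the window of its nearest eligible
    sorted position: the N consecutive sorted eligible positions centred on
    its insertion point.
    """
    ref_signal = np.asarray(ref_signal, dtype=np.float64)
    eligible = _check_common(eligible, N)
    n = len(ref_signal)
    elig_idx = np.flatnonzero(eligible)
    n_e = elig_idx.size
    order = np.argsort(ref_signal[elig_idx], kind="stable")
    sorted_probes = elig_idx[order]          # probe index at each sorted position
    sorted_vals = ref_signal[sorted_probes]
    pos_of = np.full(n, -1, dtype=np.int64)
    pos_of[sorted_probes] = np.arange(n_e)

    k_elig = min(N, n_e - 1)
    k_inel = min(N, n_e)
    width = k_elig if bool(np.all(eligible)) else max(k_elig, k_inel)
    members = np.full((n, width), FILL, dtype=np.int64)

    # --- eligible probes -------------------------------------------------
    r = pos_of[elig_idx]
    if n_e - 1 <= N:
        # every other eligible probe is a member
        for i, pi in enumerate(elig_idx):
            others = sorted_probes[sorted_probes != pi]
            members[pi, : others.size] = others
    else:
        lo = r - (N + 1) // 2
        hi = r + N // 2
        shift = np.where(lo < 0, -lo, 0)
        lo += shift
        hi += shift
        shift = np.where(hi > n_e - 1, hi - (n_e - 1), 0)
        lo -= shift
        hi -= shift
        # windows are N+1 positions wide and contain r; drop self
        pos = lo[:, None] + np.arange(N + 1)[None, :]
        keep = pos != r[:, None]
        win = sorted_probes[pos]
        members[elig_idx, :] = win[keep].reshape(n_e, N)

    # --- ineligible probes ------------------------------------------------
    inel_idx = np.flatnonzero(~eligible)
    if inel_idx.size:
        ins = np.searchsorted(sorted_vals, ref_signal[inel_idx], side="left")
        lo = np.clip(ins - k_inel // 2, 0, n_e - k_inel)
        pos = lo[:, None] + np.arange(k_inel)[None, :]
        members[inel_idx, :k_inel] = sorted_probes[pos]

    return ReferenceAssignment(N=N, members=members, method="single")


def assign_sorted_average(
    ref_signals: Sequence[np.ndarray] | np.ndarray,
    eligible: np.ndarray,
    N: int = DEFAULT_N,
) -> ReferenceAssignment:
    """Reference sets from the mean over multiple reference conditions.

    Identical to :func:`assign_single_reference` applied to the per-probe
    arithmetic mean across the reference conditions; with a single reference
    condition the output equals the single-reference assignment exactly.
    """
    X = _stack_refs(ref_signals)
    asg = assign_single_reference(X.mean(axis=1), eligible, N)
    return ReferenceAssignment(N=N, members=asg.members, method="sorted_average")


def assign_min_distance(
    ref_signals: Sequence[np.ndarray] | np.ndarray,
    eligible: np.ndarray,
    N: int = DEFAULT_N,
    metric: str = "euclidean",
    *,
    chunk: int = 512,
) -> ReferenceAssignment:
    """Reference sets as the N nearest probes in reference-condition space.

    For each probe the members are the N eligible probes (excluding itself)
    at smallest distance in the M-dimensional space of reference-condition
    signals; ties are broken by probe index.  Distances are computed exactly
    (all pairs, in chunks); with a single reference condition this agrees
    with :func:`assign_single_reference` except for clamping differences at
    the rank extremes.
    """
    if metric not in _METRICS:
        raise ParameterError(
            f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}"
        )
    X = _stack_refs(ref_signals)
    eligible = _check_common(eligible, N)
    n = X.shape[0]
    elig_idx = np.flatnonzero(eligible)
    n_e = elig_idx.size
    XE = X[elig_idx]
    pos_in_elig = np.full(n, -1, dtype=np.int64)
    pos_in_elig[elig_idx] = np.arange(n_e)

    k_elig = min(N, n_e - 1)
    k_inel = min(N, n_e)
    width = k_elig if bool(np.all(eligible)) else max(k_elig, k_inel)
    members = np.full((n, width), FILL, dtype=np.int64)

    scipy_metric = _METRICS[metric]
    for lo in range(0, n, chunk):
        rows = np.arange(lo, min(lo + chunk, n))
        D = cdist(X[rows], XE, metric=scipy_metric)
        self_pos = pos_in_elig[rows]
        has_self = self_pos >= 0
        D[np.flatnonzero(has_self), self_pos[has_self]] = np.inf
        # stable argsort over eligible positions = ties by ascending probe index
        order = np.argsort(D, axis=1, kind="stable")
        for a, i in enumerate(rows):
            k = k_elig if has_self[a] else k_inel
            members[i, :k] = elig_idx[order[a, :k]]
    return ReferenceAssignment(N=N, members=members, method="min_distance", metric=metric)


def pairwise_distances(
    points: Sequence[np.ndarray] | np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """All-pairs distance matrix under a named metric (the one the
    assignment uses internally)."""
    if metric not in _METRICS:
        raise ParameterError(f"unknown metric {metric!r}")
    P = np.atleast_2d(np.asarray(points, dtype=np.float64))
    return cdist(P, P, metric=_METRICS[metric])


def _stack_refs(ref_signals) -> np.ndarray:
    if isinstance(ref_signals, np.ndarray) and ref_signals.ndim == 2:
        X = np.asarray(ref_signals, dtype=np.float64)
    else:
        vecs = [np.asarray(v, dtype=np.float64) for v in ref_signals]
        if not vecs:
            raise ParameterError("at least one reference condition is required")
        if len({v.shape for v in vecs}) != 1:
            raise ValidationError("reference condition vectors are not aligned")
        X = np.column_stack(vecs)
    if X.shape[1] == 0:
        raise ParameterError("at least one reference condition is required")
    return X
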