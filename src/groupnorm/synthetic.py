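"""Synthetic tiling-array experiments with realistic probe effects.

Generates probe-level data with the statistical structure the normalization
method assumes, so every stage of the pipeline can be exercised at desk
scale:

* probe-specific efficiency ``A_i`` and background ``B_i`` driven by a
  shared latent "GC" covariate (smooth monotone curves plus lognormal
  probe-level jitter) — no actual sequences are generated, since the
  mechanism only needs one covariate driving both parameters;
* a bounded biological signal ``x_i`` in [0, 1] with ~147 bp spatial
  structure, laid down as alternating nucleosome footprints and
  exponentially distributed linkers;
* observed intensities ``y_i = copy_i * (A_i x_i + B_i) + eps_i`` with
  additive Gaussian noise, optional per-array global scale/offset biases
  and per-array probe-response jitter (arrays never respond identically);
* repeat regions with elevated apparent copy number, emitted as a BED mask.

All generators are pure functions of (config, seed): the same inputs
regenerate bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .tracks_io import (
    ParameterError,
    ProbeTable,
    SignalMatrix,
    apply_repeat_mask,
    write_bed,
)

logger = logging.getLogger("groupnorm")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectConfig:
    """Probe-effect generator: A(gc) and B(gc) curves plus jitter.

    Efficiency A = (a_intercept + a_slope * gc) * lognormal jitter, and
    likewise for background B; gc is uniform on (gc_low, gc_high).  Defaults
    give roughly a threefold efficiency range across probes, in the spirit
    of the strong probe-to-probe variation seen on high-density arrays.
    """

    tiling_step: int = 4
    probe_len: int = 25
    gc_low: float = 0.2
    gc_high: float = 0.8
    a_intercept: float = 1.0
    a_slope: float = 8.0
    b_intercept: float = 0.5
    b_slope: float = 2.0
    a_jitter_sd: float = 0.10
    b_jitter_sd: float = 0.10


@dataclass(frozen=True)
class OccupancyConfig:
    """Nucleosome-occupancy generator.

    Alternating bound footprints of ``footprint_bp`` and linkers of
    ``min_linker_bp`` plus an exponential tail, with the mean linker length
    chosen so that the expected bound fraction equals ``bound_fraction``
    (~75-80% of the genome is nucleosome bound in vivo; default 0.77).
    """

    bound_fraction: float = 0.77
    footprint_bp: int = 147
    min_linker_bp: int = 2

    @property
    def mean_linker_bp(self) -> float:
        p = self.bound_fraction
        return self.footprint_bp * (1.0 - p) / p


@dataclass(frozen=True)
class ExperimentConfig:
    """A full simulated two-condition study.

    ``n_control`` genomic-control arrays (x = 1 everywhere), ``n_a``
    pre-stimulus and ``n_b`` post-stimulus arrays sharing one set of probe
    effects.  Condition B re-draws occupancy inside randomly placed
    "response" blocks; repeat blocks get copy number 2..repeat_copy_max and
    are reported as a BED mask.  Array-level variation: global lognormal
    scale (sd ``array_scale_sd``), global additive offset (sd
    ``array_offset_sd``) and per-array per-probe lognormal response jitter
    (sd ``response_jitter_sd``).
    """

    n_probes: int = 10000
    effects: EffectConfig = field(default_factory=EffectConfig)
    occupancy: OccupancyConfig = field(default_factory=OccupancyConfig)
    occupancy_b: OccupancyConfig = field(default_factory=OccupancyConfig)
    n_control: int = 2
    n_a: int = 3
    n_b: int = 3
    noise_sd: float = 0.3
    array_scale_sd: float = 0.10
    array_offset_sd: float = 0.20
    response_jitter_sd: float = 0.05
    repeat_fraction: float = 0.02
    repeat_mean_bp: int = 1000
    repeat_copy_max: int = 5
    response_fraction: float = 0.10
    response_mean_bp: int = 1000
    chrom: str = "chrSim"


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    Per probe: biological signals ``x_a``/``x_b`` (x = 1 on control
    arrays), efficiency ``A``, background ``B``, ``copy_number`` and the
    latent ``gc`` covariate.  ``array_scale``/``array_offset``/``array_seed``
    map condition labels to the per-array parameters, so the observed
    arrays regenerate bit-identically from (SimTruth, seed).
    """

    gc: np.ndarray
    A: np.ndarray
    B: np.ndarray
    copy_number: np.ndarray
    x_a: np.ndarray
    x_b: np.ndarray
    noise_sd: float
    seed: int
    repeat_intervals: list[tuple[str, int, int]]
    response_intervals: list[tuple[str, int, int]]
    array_scale: dict[str, float] = field(default_factory=dict)
    array_offset: dict[str, float] = field(default_factory=dict)
    array_seed: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_probe_effects(
    n_probes: int, config: EffectConfig = EffectConfig(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (gc, A, B) for ``n_probes`` probes; deterministic given seed."""
    if n_probes <= 0:
        raise ParameterError(f"n_probes must be positive, got {n_probes}")
    rng = np.random.default_rng(seed)
    gc = rng.uniform(config.gc_low, config.gc_high, size=n_probes)
    A = (config.a_intercept + config.a_slope * gc) * np.exp(
        rng.normal(0.0, config.a_jitter_sd, size=n_probes)
    )
    B = (config.b_intercept + config.b_slope * gc) * np.exp(
        rng.normal(0.0, config.b_jitter_sd, size=n_probes)
    )
    if np.any(A <= 0):
        raise ParameterError("effect config yields non-positive efficiencies A")
    return gc, A, B


def _genome_length(n_probes: int, cfg: EffectConfig) -> int:
    return (n_probes - 1) * cfg.tiling_step + cfg.probe_len


def simulate_occupancy(
    n_probes: int,
    config: OccupancyConfig = OccupancyConfig(),
    seed: int = 0,
    *,
    effects: EffectConfig = EffectConfig(),
) -> np.ndarray:
    """Simulate a nucleosome-occupancy track x in [0, 1].

    Bound footprints of ``footprint_bp`` alternate with linkers of
    ``min_linker_bp`` plus an exponential tail along the tiled genome;
    each probe's x is the fraction of its interval covered by bound bp, so
    runs of high x have bp-lengths concentrated near the footprint and the
    realized bound fraction matches the configured one for large n.
    """
    if not (0 < config.bound_fraction <= 1):
        raise ParameterError(
            f"bound_fraction must be in (0, 1], got {config.bound_fraction}"
        )
    rng = np.random.default_rng(seed)
    L = _genome_length(n_probes, effects)
    bound = np.zeros(L, dtype=bool)
    if config.bound_fraction == 1.0:
        bound[:] = True
    else:
        mean_tail = max(config.mean_linker_bp - config.min_linker_bp, 1e-9)
        pos = -int(rng.integers(0, config.footprint_bp))  # random phase
        while pos < L:
            pos += config.min_linker_bp + int(round(rng.exponential(mean_tail)))
            bound[max(pos, 0) : pos + config.footprint_bp] = True
            pos += config.footprint_bp
    cov = np.concatenate(([0], np.cumsum(bound)))
    starts = np.arange(n_probes) * effects.tiling_step
    ends = starts + effects.probe_len
    return (cov[ends] - cov[starts]) / effects.probe_len


def simulate_hybridization(
    x: np.ndarray,
    effects: tuple[np.ndarray, np.ndarray],
    copy_number: np.ndarray | int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    scale: float = 1.0,
    offset: float = 0.0,
    response_jitter_sd: float = 0.0,
) -> np.ndarray:
    """One observed array: ``y = scale * copy * (A x + B) + offset + eps``.

    ``eps`` is i.i.d. Gaussian(0, noise_sd).  ``response_jitter_sd``
    multiplies A by per-probe lognormal jitter specific to this array,
    emulating array-to-array variability in probe response.  A genomic
    control array is obtained by passing x = 1 everywhere.
    """
    x = np.asarray(x, dtype=np.float64)
    A, B = (np.asarray(a, dtype=np.float64) for a in effects)
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    A_eff = A
    if response_jitter_sd > 0:
        A_eff = A * np.exp(rng.normal(0.0, response_jitter_sd, size=x.size))
    y = scale * (np.asarray(copy_number) * (A_eff * x + B)) + offset
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return y


def _random_blocks(
    rng: np.random.Generator, L: int, fraction: float, mean_bp: int, chrom: str
) -> list[tuple[str, int, int]]:
    """Random merged blocks covering roughly ``fraction`` of L bp."""
    target = fraction * L
    raw: list[tuple[int, int]] = []
    covered = 0.0
    while covered < target:
        length = max(int(round(rng.exponential(mean_bp))), 100)
        start = int(rng.integers(0, max(L - length, 1)))
        raw.append((start, min(start + length, L)))
        covered += min(length, L - start)
    raw.sort()
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(chrom, s, e) for s, e in merged]


def _probe_block_overlap(
    starts: np.ndarray, ends: np.ndarray, blocks: list[tuple[str, int, int]]
) -> np.ndarray:
    hit = np.zeros(starts.size, dtype=bool)
    for _, s, e in blocks:
        hit |= (starts < e) & (ends > s)
    return hit


def simulate_experiment(
    config: ExperimentConfig = ExperimentConfig(), seed: int = 0
) -> tuple[ProbeTable, SignalMatrix, SimTruth]:
    """Compose a full ready-to-normalize two-condition experiment.

    Emits an aligned (ProbeTable, SignalMatrix, SimTruth).  Condition
    columns are labelled ``control_1..``, ``a_1..`` and ``b_1..``; probe
    eligibility reflects the generated repeat mask.
    """
    rng = np.random.default_rng(seed)

    def _sub() -> int:
        return int(rng.integers(0, 2**31))

    n = config.n_probes
    eff = config.effects
    gc, A, B = simulate_probe_effects(n, eff, _sub())
    x_a = simulate_occupancy(n, config.occupancy, _sub(), effects=eff)
    x_b_alt = simulate_occupancy(n, config.occupancy_b, _sub(), effects=eff)

    L = _genome_length(n, eff)
    starts = np.arange(n) * eff.tiling_step
    ends = starts + eff.probe_len

    repeat_iv = _random_blocks(
        rng, L, config.repeat_fraction, config.repeat_mean_bp, config.chrom
    )
    response_iv = _random_blocks(
        rng, L, config.response_fraction, config.response_mean_bp, config.chrom
    )
    copy_number = np.ones(n, dtype=np.int64)
    for chrom, s, e in repeat_iv:
        cn = int(rng.integers(2, config.repeat_copy_max + 1))
        copy_number[(starts < e) & (ends > s)] = cn

    in_response = _probe_block_overlap(starts, ends, response_iv)
    x_b = np.where(in_response, x_b_alt, x_a)

    table = ProbeTable(
        chrom=np.full(n, config.chrom, dtype=object),
        start=starts,
        end=ends,
        probe_id=np.array([f"p{i:06d}" for i in range(n)], dtype=object),
        eligible=np.ones(n, dtype=bool),
    )
    table = apply_repeat_mask(table, repeat_iv)

    truth = SimTruth(
        gc=gc,
        A=A,
        B=B,
        copy_number=copy_number,
        x_a=x_a,
        x_b=x_b,
        noise_sd=config.noise_sd,
        seed=seed,
        repeat_intervals=repeat_iv,
        response_intervals=response_iv,
    )

    labels: list[str] = []
    columns: list[np.ndarray] = []
    ones = np.ones(n)
    groups = [
        ("control", config.n_control, ones),
        ("a", config.n_a, x_a),
        ("b", config.n_b, x_b),
    ]
    for prefix, count, x in groups:
        for rep in range(1, count + 1):
            label = f"{prefix}_{rep}"
            scale = float(np.exp(rng.normal(0.0, config.array_scale_sd)))
            offset = float(rng.normal(0.0, config.array_offset_sd))
            aseed = _sub()
            y = simulate_hybridization(
                x,
                (A, B),
                copy_number,
                config.noise_sd,
                aseed,
                scale=scale,
                offset=offset,
                response_jitter_sd=config.response_jitter_sd,
            )
            labels.append(label)
            columns.append(y)
            truth.array_scale[label] = scale
            truth.array_offset[label] = offset
            truth.array_seed[label] = aseed

    return table, SignalMatrix(labels, np.column_stack(columns)), truth


# ---------------------------------------------------------------------------
# On-disk experiment
# ---------------------------------------------------------------------------

def write_experiment(
    out_dir, table: ProbeTable, signals: SignalMatrix, truth: SimTruth
) -> dict[str, str]:
    """Write probes.tsv, mask.bed and truth.tsv into ``out_dir``.

    Output is deterministic: the same (table, signals, truth) always
    produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    probes_path = os.path.join(out_dir, "probes.tsv")
    mask_path = os.path.join(out_dir, "mask.bed")
    truth_path = os.path.join(out_dir, "truth.tsv")

    with open(probes_path, "w") as fh:
        fh.write("chrom\tstart\tend\tprobe_id\t" + "\t".join(signals.conditions) + "\n")
        for i in range(len(table)):
            row = "\t".join(repr(float(v)) for v in signals.values[i])
            fh.write(f"{table.chrom[i]}\t{table.start[i]}\t{table.end[i]}\t{table.probe_id[i]}\t{row}\n")
    write_bed(truth.repeat_intervals, mask_path)
    with open(truth_path, "w") as fh:
        fh.write("probe_id\tgc\tA\tB\tcopy_number\tx_a\tx_b\n")
        for i in range(len(table)):
            fh.write(
                f"{table.probe_id[i]}\t{truth.gc[i]!r}\t{truth.A[i]!r}\t{truth.B[i]!r}"
                f"\t{truth.copy_number[i]}\t{truth.x_a[i]!r}\t{truth.x_b[i]!r}\n"
            )
    return {"probes": probes_path, "mask": mask_path, "truth": truth_path}


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a plain (YAML-loaded) dict."""
    d = dict(d or {})
    kwargs: dict = {}
    if "effects" in d:
        kwargs["effects"] = EffectConfig(**d.pop("effects"))
    if "occupancy" in d:
        kwargs["occupancy"] = OccupancyConfig(**d.pop("occupancy"))
    if "occupancy_b" in d:
        kwargs["occupancy_b"] = OccupancyConfig(**d.pop("occupancy_b"))
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(f"unknown experiment config keys: {sorted(unknown)}")
    kwargs.update(d)
    return ExperimentConfig(**kwargs)
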