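"""Synthetic cohorts, behavioral sessions and BOLD runs.

This module is the ground-truth generator for the whole pipeline: it draws
subject profiles (PSS, TIW, SJ amplitude, TOJ responder phenotype), simulates
binomial SJ/TOJ responses across cue-onset-asynchrony (COA) levels, and
renders 4D BOLD runs containing sustained 25-s block responses and transient
3-s stimulus responses plus cosine drift and AR(1) Gaussian noise — exactly
the signal structure the two-timescale GLM assumes, so recovery can be
checked against known truth.

Responder phenotypes follow the behavioral observation that some subjects
cannot perform temporal-order judgments: an "able" subject answers from the
cumulative-Gaussian model, a "random" one at chance, and a "biased" one gives
the same response on every trial.  The phenotype affects the TOJ task only;
synchrony judgments always follow the subject's Gaussian SJ model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import COA_CONDITIONS, Event, RunSequence, DesignMatrix, TASKS
from .psychometrics import FRAME_MS, sj_model, toj_model

__all__ = [
    "SubjectProfile",
    "EffectSpec",
    "NoiseSpec",
    "BoldRun",
    "DEFAULT_PARAMETER_RANGES",
    "PRE_FMRI_COA_LEVELS_MS",
    "make_cohort",
    "simulate_behavioral_session",
    "simulate_bold_run",
    "write_events",
    "read_events",
    "EventsParseError",
]

#: The 11 COA levels of the pre-scanner behavioral session: 0, +/-4, 8, 12,
#: 16 and 20 frames at 60 Hz (nominally 0, +/-67, 133, 200, 267, 333 ms).
PRE_FMRI_COA_LEVELS_MS = tuple(k * FRAME_MS for k in range(-20, 21, 4))

#: Sampling ranges for ground-truth subject parameters.  Centred on the
#: group-level behavioral estimates for these stimuli (SJ PSS ~ +70 ms,
#: SJ TIW ~ 127 ms, TOJ PSS ~ -55 ms, TOJ TIW ~ 190 ms).
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "sj_mu_ms": (40.0, 100.0),
    "sj_sigma_ms": (90.0, 165.0),
    "sj_amplitude": (0.75, 1.0),
    "toj_mu_ms": (-150.0, 40.0),
    "toj_sigma_ms": (100.0, 280.0),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth psychometric parameters of one simulated subject."""

    subject_id: str
    responder_mode: str  # able | random | biased
    sj_mu_ms: float
    sj_sigma_ms: float
    sj_amplitude: float
    toj_mu_ms: float
    toj_sigma_ms: float
    bias_response: int = 1

    def __post_init__(self) -> None:
        if self.sj_sigma_ms <= 0 or self.toj_sigma_ms <= 0:
            raise ValueError("sigma parameters must be positive")
        if not (0 < self.sj_amplitude <= 1):
            raise ValueError("sj_amplitude must be in (0, 1]")
        if self.responder_mode not in ("able", "random", "biased"):
            raise ValueError(f"unknown responder_mode {self.responder_mode!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model of a BOLD run: AR(1) Gaussian plus cosine drift."""

    sigma: float = 1.0            # marginal noise SD, BOLD units
    ar1_rho: float = 0.3
    drift_amplitude: float = 2.0  # BOLD units
    drift_period_s: float = 300.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("sigma and drift_amplitude must be nonnegative")
        if not (-1 < self.ar1_rho < 1):
            raise ValueError("|ar1_rho| must be < 1")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth spatial layout and amplitudes of BOLD effects."""

    volume_shape: tuple[int, int, int]
    mask: np.ndarray               # 3D bool
    region_map: np.ndarray         # 3D int; 0 = background
    sustained_amplitude: Mapping[tuple[int, str], float] = field(default_factory=dict)
    transient_amplitude: Mapping[tuple[int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask.shape != self.volume_shape or self.region_map.shape != self.volume_shape:
            raise ValueError("mask and region_map must match volume_shape")
        labels = set(np.unique(self.region_map)) - {0}
        keyed = {k[0] for k in self.sustained_amplitude} | {
            k[0] for k in self.transient_amplitude
        }
        if not labels <= keyed | {0} and (self.sustained_amplitude or self.transient_amplitude):
            missing = labels - keyed
            if missing:
                raise ValueError(f"region labels without amplitudes: {sorted(missing)}")
        if np.any((self.region_map > 0) & ~self.mask.astype(bool)):
            raise ValueError("all nonzero regions must lie inside the mask")


@dataclass(frozen=True)
class BoldRun:
    """One simulated 4D run."""

    data: np.ndarray  # (x, y, z, time) float
    tr_s: float
    sequence_ref: int | None = None
    seed: int | None = None


def _check_ranges(ranges: Mapping[str, tuple[float, float]]) -> dict:
    merged = dict(DEFAULT_PARAMETER_RANGES)
    merged.update(ranges or {})
    for key, (lo, hi) in merged.items():
        if key not in DEFAULT_PARAMETER_RANGES:
            raise ValueError(f"unknown parameter {key!r}")
        if lo > hi:
            raise ValueError(f"empty range for {key}")
        if key.endswith("sigma_ms") and lo <= 0:
            raise ValueError(f"{key} lower bound must be positive")
        if key == "sj_amplitude" and not (0 < lo <= hi <= 1):
            raise ValueError("sj_amplitude range must lie in (0, 1]")
    return merged


def make_cohort(
    n_able: int,
    n_unable: int,
    parameter_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = 0,
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    ``n_unable`` subjects are split evenly between the "random" and "biased"
    TOJ phenotypes (random gets the extra one when odd).  All subjects get
    valid SJ parameters regardless of phenotype.
    """
    if n_able + n_unable < 1:
        raise ValueError("cohort must contain at least one subject")
    ranges = _check_ranges(parameter_ranges or {})
    rng = np.random.default_rng(seed)

    n_random = (n_unable + 1) // 2
    modes = ["able"] * n_able + ["random"] * n_random + ["biased"] * (n_unable - n_random)
    profiles = []
    for i, mode in enumerate(modes):
        draw = {k: float(rng.uniform(*ranges[k])) for k in ranges}
        profiles.append(
            SubjectProfile(
                subject_id=f"sub-{i+1:02d}",
                responder_mode=mode,
                bias_response=int(rng.integers(0, 2)),
                **draw,
            )
        )
    return profiles


def simulate_behavioral_session(
    profiles: list[SubjectProfile],
    coa_levels_ms: tuple[float, ...] = PRE_FMRI_COA_LEVELS_MS,
    n_trials_per_level: int = 10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Binomial SJ and TOJ responses for every subject at every COA level.

    Returns a tidy response table with one row per (subject, task, COA):
    columns ``subject_id, task, coa_ms, n_trials, n_target`` where the
    target response is "synchronous" for SJ and "video-first" for TOJ.
    """
    if not coa_levels_ms:
        raise ValueError("coa_levels_ms must be nonempty")
    if n_trials_per_level < 1:
        raise ValueError("n_trials_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    coa = np.asarray(coa_levels_ms, dtype=float)

    rows = []
    for p in profiles:
        for task in TASKS:
            if task == "SJ":
                probs = sj_model(coa, p.sj_mu_ms, p.sj_sigma_ms, p.sj_amplitude)
            elif p.responder_mode == "able":
                probs = toj_model(coa, p.toj_mu_ms, p.toj_sigma_ms)
            elif p.responder_mode == "random":
                probs = np.full_like(coa, 0.5)
            else:  # biased: every response identical
                probs = np.full_like(coa, float(p.bias_response))
            n_target = rng.binomial(n_trials_per_level, np.clip(probs, 0, 1))
            for c, k in zip(coa, n_target):
                rows.append((p.subject_id, task, float(c), n_trials_per_level, int(k)))
    return pd.DataFrame(
        rows, columns=["subject_id", "task", "coa_ms", "n_trials", "n_target"]
    )


def simulate_bold_run(
    sequence: RunSequence,
    design: DesignMatrix,
    effects: EffectSpec,
    noise: NoiseSpec,
    seed: int | None = 0,
    baseline: float = 100.0,
) -> BoldRun:
    """Forward-model a 4D BOLD run from a design matrix and an effect map.

    Every in-mask voxel's series is the design matrix times that voxel's
    region amplitudes, plus the baseline, a single cosine drift, and
    stationary AR(1) Gaussian noise with marginal SD ``noise.sigma``.
    Out-of-mask voxels are zero.  Bitwise reproducible under ``seed``.
    """
    n_scans = int(np.ceil(sequence.duration_s / design.tr_s))
    if design.values.shape[0] != n_scans:
        raise ValueError(
            f"design has {design.values.shape[0]} rows but sequence needs {n_scans}"
        )
    rng = np.random.default_rng(seed)
    mask = effects.mask.astype(bool)
    n_vox = int(mask.sum())
    n_reg = len(design.labels)

    # per-voxel amplitude vectors over design columns
    amp = np.zeros((n_vox, n_reg))
    amp[:, design.labels.index("constant")] = baseline
    regions = effects.region_map[mask]
    for j, lab in enumerate(design.labels):
        if lab.endswith("_sustained"):
            task = lab.split("_")[0]
            for (reg, tk), a in effects.sustained_amplitude.items():
                if tk == task:
                    amp[regions == reg, j] = a
        elif "_" in lab and lab.split("_", 1)[1] in COA_CONDITIONS:
            task, cond = lab.split("_", 1)
            for (reg, tk, cd), a in effects.transient_amplitude.items():
                if tk == task and cd == cond:
                    amp[regions == reg, j] = a

    signal = amp @ design.values.T  # (n_vox, n_time)

    t = np.arange(n_scans) * design.tr_s
    drift = noise.drift_amplitude * np.cos(2.0 * np.pi * t / noise.drift_period_s)
    series = signal + drift

    if noise.sigma > 0:
        z = rng.standard_normal((n_vox, n_scans))
        innov = z * (noise.sigma * np.sqrt(1.0 - noise.ar1_rho**2))
        innov[:, 0] = z[:, 0] * noise.sigma  # stationary start
        series = series + lfilter([1.0], [1.0, -noise.ar1_rho], innov, axis=1)

    data = np.zeros(effects.volume_shape + (n_scans,), dtype=float)
    data[mask] = series
    return BoldRun(data=data, tr_s=design.tr_s, sequence_ref=sequence.seed, seed=seed)


# ---------------------------------------------------------------------------
# events TSV (BIDS-style: onset, duration, trial_type, task, coa_condition)

EVENTS_COLUMNS = ("onset", "duration", "trial_type", "task", "coa_condition")


class EventsParseError(ValueError):
    pass


def write_events(sequence, path) -> None:
    """Write a RunSequence (or an events DataFrame) as a BIDS-style TSV."""
    if isinstance(sequence, RunSequence):
        rows = [
            (ev.onset_s, ev.duration_s, ev.kind, ev.task, ev.coa_condition)
            for ev in sequence.events
        ]
    else:
        rows = [tuple(r) for r in sequence[list(EVENTS_COLUMNS)].itertuples(index=False)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENTS_COLUMNS)
        for r in rows:
            w.writerow([repr(float(r[0])), repr(float(r[1])), *r[2:]])


def read_events(path) -> RunSequence:
    """Read an events TSV back into a RunSequence (lossless round trip).

    Stimulation-block onsets are reconstructed from the instruction events
    (a block starts when its instruction screen ends).
    """
    events: list[Event] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return RunSequence((), (), 0)
        if tuple(header) != EVENTS_COLUMNS:
            raise EventsParseError(f"line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise EventsParseError(f"line {lineno}: expected 5 fields, got {len(row)}")
            try:
                onset, dur = float(row[0]), float(row[1])
            except ValueError as exc:
                raise EventsParseError(f"line {lineno}: {exc}") from None
            if dur < 0:
                raise EventsParseError(f"line {lineno}: negative duration {dur}")
            if onset < 0:
                raise EventsParseError(f"line {lineno}: negative onset {onset}")
            events.append(Event(onset, dur, row[2], row[3], row[4]))

    blocks = tuple(
        (ev.onset_s + ev.duration_s, ev.task) for ev in events if ev.kind == "instruction"
    )
    return RunSequence(tuple(events), blocks, len(blocks))
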