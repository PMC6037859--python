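"""Psychometric models for synchrony (SJ) and temporal-order (TOJ) judgments.

The SJ task asks "were the audio and video cues synchronous?"; the proportion
of "synchronous" responses as a function of the signed cue-onset asynchrony
(COA, ms; negative = audio leads) is modelled as a scaled Gaussian

    p(coa) = A * exp(-(coa - mu)^2 / (2 sigma^2)),

whose peak location ``mu`` is the point of subjective simultaneity (PSS) and
whose standard deviation ``sigma`` is the temporal integration window (TIW).
The TOJ task asks "which cue came first?"; the proportion of "video-first"
responses is a cumulative Gaussian whose 50% point is the PSS and whose slope
parameter is the TIW.  Subjects whose TOJ data cannot be fit (goodness of fit
R^2 < 0.5) are classified TOJ-unable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FRAME_MS",
    "MAX_FRAMES",
    "PsychometricFit",
    "ConditionSet",
    "sj_model",
    "toj_model",
    "fit_psychometric",
    "classify_toj_ability",
    "select_pss_condition",
    "assign_fallback_pss",
    "paired_t",
    "independent_t",
]

#: Duration of one video frame at a 60-Hz refresh, ms.  COA levels are
#: realisable only on this grid; the extreme levels are +/-20 frames.
FRAME_MS = 1000.0 / 60.0
MAX_FRAMES = 20


class InsufficientDataError(ValueError):
    """Fewer distinct COA levels than free parameters allow."""


@dataclass(frozen=True)
class PsychometricFit:
    """Result of fitting one subject x task psychometric function."""

    task: Literal["SJ", "TOJ"]
    mu_ms: float
    sigma_ms: float
    amplitude: float
    r_squared: float
    converged: bool
    classification: str | None = None  # "able"/"unable", TOJ only


@dataclass(frozen=True)
class ConditionSet:
    """The four COA conditions scanned per subject: extremes, zero, and PSS."""

    coa_conditions_ms: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a, zero, pss, v = self.coa_conditions_ms
        if not (a == -MAX_FRAMES * FRAME_MS and v == MAX_FRAMES * FRAME_MS and zero == 0.0):
            raise ValueError("condition set must contain -333.33, 0 and +333.33 ms")
        frames = pss / FRAME_MS
        if abs(frames - round(frames)) > 1e-9 or abs(frames) > MAX_FRAMES:
            raise ValueError("PSS condition must lie on the frame grid within +/-20 frames")


def sj_model(coa_ms, mu_ms: float, sigma_ms: float, amplitude: float = 1.0):
    """Probability of a "synchronous" response: scaled Gaussian in COA."""
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    coa = np.asarray(coa_ms, dtype=float)
    out = amplitude * np.exp(-((coa - mu_ms) ** 2) / (2.0 * sigma_ms**2))
    return out if out.ndim else float(out)


def toj_model(coa_ms, mu_ms: float, sigma_ms: float):
    """Probability of a "video-first" response: cumulative Gaussian in COA."""
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    coa = np.asarray(coa_ms, dtype=float)
    out = stats.norm.cdf((coa - mu_ms) / sigma_ms)
    return out if out.ndim else float(out)


def _predict(task: str, coa: np.ndarray, params: np.ndarray) -> np.ndarray:
    if task == "SJ":
        return sj_model(coa, params[0], params[1], params[2])
    return toj_model(coa, params[0], params[1])


_SIGMA_BOUNDS = (1.0, 2000.0)
_MU_BOUNDS = (-800.0, 800.0)


def _multistarts(task: str) -> list[np.ndarray]:
    """Eight deterministic starting points spanning the plausible range."""
    starts = []
    for mu0 in (-150.0, -50.0, 50.0, 150.0):
        for sigma0 in (60.0, 220.0):
            if task == "SJ":
                starts.append(np.array([mu0, sigma0, 0.9]))
            else:
                starts.append(np.array([mu0, sigma0]))
    return starts


def fit_psychometric(table: pd.DataFrame, task: str | None = None) -> PsychometricFit:
    """Least-squares fit of the SJ or TOJ model to one subject's responses.

    Parameters
    ----------
    table
        Rows of one subject x task with columns ``coa_ms``, ``n_trials``,
        ``n_target`` (and optionally ``task``).  Needs >= 4 distinct COA
        levels.
    task
        "SJ" or "TOJ"; taken from the table's ``task`` column if omitted.

    Notes
    -----
    The sum of squared errors between per-level observed proportions and the
    model is minimised with L-BFGS-B from 8 deterministic starting points;
    the best local optimum wins.  ``r_squared = 1 - SS_res / SS_tot`` over
    the per-level proportions; degenerate data with zero total variance get
    ``r_squared = 0`` (and hence an "unable" TOJ classification).
    """
    if task is None:
        tasks = set(table["task"])
        if len(tasks) != 1:
            raise ValueError("table must contain exactly one task, or pass task=")
        task = next(iter(tasks))
    if task not in ("SJ", "TOJ"):
        raise ValueError(f"unknown task {task!r}")

    grouped = table.groupby("coa_ms", as_index=True)[["n_trials", "n_target"]].sum()
    coa = grouped.index.to_numpy(dtype=float)
    if len(coa) < 4:
        raise InsufficientDataError(
            f"need >=4 distinct COA levels, got {len(coa)}"
        )
    if (grouped["n_trials"] < 1).any():
        raise InsufficientDataError("every COA level needs n_trials >= 1")
    prop = (grouped["n_target"] / grouped["n_trials"]).to_numpy(dtype=float)

    def sse(params: np.ndarray) -> float:
        resid = prop - _predict(task, coa, params)
        return float(resid @ resid)

    if task == "SJ":
        bounds = [_MU_BOUNDS, _SIGMA_BOUNDS, (1e-6, 1.0)]
    else:
        bounds = [_MU_BOUNDS, _SIGMA_BOUNDS]

    best = None
    converged = False
    for x0 in _multistarts(task):
        res = optimize.minimize(sse, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    params = best.x
    ss_res = best.fun
    ss_tot = float(np.sum((prop - prop.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot

    fit = PsychometricFit(
        task=task,
        mu_ms=float(params[0]),
        sigma_ms=float(params[1]),
        amplitude=float(params[2]) if task == "SJ" else 1.0,
        r_squared=float(r2),
        converged=converged,
        classification=None,
    )
    if task == "TOJ":
        fit = PsychometricFit(
            **{**fit.__dict__, "classification": classify_toj_ability(fit, _check=False)}
        )
    return fit


def classify_toj_ability(fit: PsychometricFit, _check: bool = True) -> str:
    """Classify a TOJ fit: "able" iff R^2 >= 0.5, else "unable"."""
    if _check and fit.task != "TOJ":
        raise ValueError("ability classification applies to TOJ fits only")
    return "able" if fit.r_squared >= 0.5 else "unable"


def select_pss_condition(pss_ms: float) -> float:
    """Quantize a PSS estimate to the nearest realisable frame-grid COA.

    The display runs at 60 Hz, so asynchronies can only be realised in steps
    of one frame (1000/60 ms), up to +/-20 frames (+/-333.33 ms).  Ties at
    exactly half a frame round toward zero.
    """
    if not math.isfinite(pss_ms):
        raise ValueError("pss_ms must be finite")
    q = abs(pss_ms) / FRAME_MS
    frac = q - math.floor(q)
    if abs(frac - 0.5) < 1e-12:
        k = math.floor(q)  # tie toward zero
    else:
        k = math.floor(q + 0.5)
    k = min(k, MAX_FRAMES)
    return math.copysign(k * FRAME_MS, pss_ms) if k else 0.0


def assign_fallback_pss(
    group_fits: Iterable[PsychometricFit] = (), constant_ms: float | None = None
) -> float:
    """PSS to scan for TOJ-unable subjects.

    Returns the configured constant if given, else the mean PSS of the
    TOJ-able group fits (the stand-in for a normative group average).
    """
    if constant_ms is not None:
        return float(constant_ms)
    mus = [f.mu_ms for f in group_fits]
    if not mus:
        raise ValueError("no able fits and no configured constant")
    return float(np.mean(mus))


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired-samples t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ZeroDivisionError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def independent_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Independent-samples t-test with pooled variance; (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs length >= 2")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        raise ZeroDivisionError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    df = nx + ny - 2
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))
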