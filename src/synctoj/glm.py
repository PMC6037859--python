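"""Two-timescale first-level GLM with DCT high-pass and AR(1) prewhitening.

Each voxel's time series is modelled as a linear combination of the design
matrix columns (sustained boxcars, transient impulses, nuisance terms, all
HRF-convolved).  Slow scanner drift is removed by residualizing both data
and design against a discrete-cosine basis of all components with period
longer than 128 s; serial correlation is handled by estimating a single
pooled lag-1 autocorrelation from the OLS residuals, prewhitening data and
design with the corresponding AR(1) transform, and refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "GLMFit",
    "ContrastImage",
    "dct_highpass_basis",
    "estimate_ar1",
    "fit_glm",
    "compute_contrast",
    "percent_signal_change",
    "DEFAULT_CUTOFF_S",
    "PSC_SCALE_FACTOR",
]

DEFAULT_CUTOFF_S = 128.0
#: peak of the convolved reference trial used to express effects as percent
#: signal change (supplied constant from the convention of Pernet 2014)
PSC_SCALE_FACTOR = 0.132


@dataclass(frozen=True)
class GLMFit:
    """Per-voxel parameter estimates from one session."""

    betas: np.ndarray          # (n_voxels, n_regressors)
    sigma2: np.ndarray         # (n_voxels,)
    dof: float
    ar1_rho: float
    filter_cutoff_s: float
    labels: tuple[str, ...]
    xtx_inv: np.ndarray        # (n_kept, n_kept), whitened+filtered design
    kept_columns: np.ndarray   # indices into labels of non-degenerate columns


@dataclass(frozen=True)
class ContrastImage:
    effect: np.ndarray
    t_stat: np.ndarray
    contrast_weights: np.ndarray
    subject_id: str | None = None
    condition: str | None = None


def dct_highpass_basis(
    n_timepoints: int, tr_s: float, cutoff_s: float = DEFAULT_CUTOFF_S
) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis (constant excluded).

    Contains every DCT component whose period 2*N*TR/k exceeds ``cutoff_s``,
    i.e. K = floor(2*N*TR/cutoff) columns.  Residualizing a time series
    against this basis removes fluctuations slower than 1/cutoff Hz while
    leaving the mean untouched (the k>=1 components are zero-mean).
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if cutoff_s <= 2.0 * tr_s:
        raise ValueError(
            f"cutoff {cutoff_s}s is at or below the Nyquist period {2 * tr_s}s"
        )
    n = n_timepoints
    k_max = min(int(math.floor(2.0 * n * tr_s / cutoff_s)), n - 1)
    if k_max < 1:
        raise ValueError(
            f"cutoff {cutoff_s}s leaves no drift components for N={n}, TR={tr_s}"
        )
    t = np.arange(n)
    basis = np.empty((n, k_max))
    for k in range(1, k_max + 1):
        basis[:, k - 1] = math.sqrt(2.0 / n) * np.cos(math.pi * (2 * t + 1) * k / (2.0 * n))
    return basis


def _residualize(y: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project out an orthonormal basis: y - C (C'y)."""
    return y - basis @ (basis.T @ y)


def estimate_ar1(residuals: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals, shape (n_voxels, n_time)."""
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.shape[1] < 3:
        raise ValueError("need at least 3 time points to estimate AR(1)")
    r = r - r.mean(axis=1, keepdims=True)
    denom = np.sum(r * r, axis=1)
    ok = denom > 0
    if not ok.any():
        raise ValueError("all residual series are constant")
    num = np.sum(r[:, 1:] * r[:, :-1], axis=1)
    return float(np.mean(num[ok] / denom[ok]))


def _whiten(y: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) prewhitening along the last axis."""
    out = np.empty_like(y)
    out[..., 0] = y[..., 0] * math.sqrt(1.0 - rho**2)
    out[..., 1:] = y[..., 1:] - rho * y[..., :-1]
    return out


def fit_glm(
    run,
    X: DesignMatrix,
    mask: np.ndarray | None = None,
    cutoff_s: float = DEFAULT_CUTOFF_S,
) -> GLMFit:
    """Fit the GLM to a BOLD run (two-pass OLS -> AR(1) -> whitened refit).

    Parameters
    ----------
    run
        A ``BoldRun`` (or any object with 4D ``data`` and ``tr_s``); data are
        (x, y, z, time).
    X
        Design matrix from :func:`synctoj.design.build_design_matrix`.
    mask
        Optional boolean 3D array restricting the fit; betas outside the mask
        are zero.

    Notes
    -----
    Both data and design are high-pass filtered by residualization against
    the DCT drift basis.  Exactly-zero design columns (motion placeholders in
    synthetic sessions) are excluded from estimation and get beta = 0; a
    genuine linear dependency among the remaining columns is an error.
    """
    data = np.asarray(run.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("run data must be 4D (x, y, z, time)")
    n_t = data.shape[-1]
    if X.values.shape[0] != n_t:
        raise ValueError(
            f"design has {X.values.shape[0]} time points, run has {n_t}"
        )
    if "constant" not in X.labels:
        raise ValueError("design must include a constant column")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    Y = data[mask].astype(float)  # (n_voxels, n_time)

    kept = np.flatnonzero(np.abs(X.values).max(axis=0) > 0)
    Xk = X.values[:, kept]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        _, r = np.linalg.qr(Xk)
        dep = [X.labels[kept[j]] for j in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise np.linalg.LinAlgError(f"design is rank-deficient; dependent columns: {dep}")

    basis = dct_highpass_basis(n_t, X.tr_s, cutoff_s)
    Yf = _residualize(Y.T, basis).T
    Xf = _residualize(Xk, basis)

    def solve(Ymat: np.ndarray, Xmat: np.ndarray):
        xtx_inv = np.linalg.inv(Xmat.T @ Xmat)
        betas = Ymat @ Xmat @ xtx_inv.T
        resid = Ymat - betas @ Xmat.T
        return betas, resid, xtx_inv

    betas, resid, xtx_inv = solve(Yf, Xf)

    # pooled AR(1) from OLS residuals; skip whitening for (near-)noiseless fits
    resid_scale = float(np.sqrt(np.mean(resid**2)))
    signal_scale = float(np.sqrt(np.mean(Yf**2))) or 1.0
    if resid_scale > 1e-10 * signal_scale:
        rho = estimate_ar1(resid)
    else:
        rho = 0.0
    if rho != 0.0:
        betas, resid, xtx_inv = solve(_whiten(Yf, rho), _whiten(Xf.T, rho).T)

    dof = n_t - basis.shape[1] - Xk.shape[1]
    sigma2 = np.sum(resid**2, axis=1) / dof

    full_betas = np.zeros((Y.shape[0], len(X.labels)))
    full_betas[:, kept] = betas
    return GLMFit(
        betas=full_betas,
        sigma2=sigma2,
        dof=float(dof),
        ar1_rho=float(rho),
        filter_cutoff_s=float(cutoff_s),
        labels=X.labels,
        xtx_inv=xtx_inv,
        kept_columns=kept,
    )


def compute_contrast(fit: GLMFit, weights, **meta) -> ContrastImage:
    """Contrast of parameter estimates with its t statistic per voxel."""
    c = np.asarray(weights, dtype=float)
    if c.shape != (len(fit.labels),):
        raise ValueError(f"weights must have length {len(fit.labels)}")
    effect = fit.betas @ c
    ck = c[fit.kept_columns]
    var_unit = float(ck @ fit.xtx_inv @ ck)
    var = var_unit * fit.sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastImage(effect=effect, t_stat=t, contrast_weights=c, **meta)


def percent_signal_change(
    fit: GLMFit, weights, scale_factor: float = PSC_SCALE_FACTOR
) -> np.ndarray:
    """Contrast effect as percent of baseline.

    PSC = 100 * (c . beta) * scale_factor / beta_constant, where the scale
    factor is the peak amplitude of the convolved reference trial.
    """
    c = np.asarray(weights, dtype=float)
    const = fit.betas[:, fit.labels.index("constant")]
    if np.any(const == 0):
        raise ZeroDivisionError("constant-term beta is zero in some voxels")
    return 100.0 * (fit.betas @ c) * scale_factor / const


def equivalent_z(p_upper: np.ndarray | float) -> np.ndarray | float:
    """Probit transform of an upper-tail p-value (z with the same tail area)."""
    return stats.norm.isf(p_upper)
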