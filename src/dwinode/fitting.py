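"""Inverse problem: per-curve and per-voxel parameter estimation.

The estimation strategy mirrors clinical multi-b-value DWI processing:

* mono-exponential and stretched-exponential models are fit in a single
  damped-least-squares (Levenberg-Marquardt) stage over the full
  protocol;
* for the FROC and CTRW models the diffusion coefficient D is first
  estimated from the low-b sub-protocol (b <= 1.0 ms/um^2, i.e.
  <= 1000 s/mm^2) where the decay is closest to mono-exponential, and
  the shape parameters are then fit over all b-values with D held
  fixed.  ``FitConfig.refit_d`` switches stage two to a joint refit of
  all free parameters (initialized at the stage-1 estimate), which is
  what exact inversion of a known generating model requires.

The stage-1 estimator is the closed-form through-origin regression of
``ln S`` on ``b`` over the sub-protocol — exactly the least-squares
mono-exponential fit in log-signal space.

Box constraints are enforced by a logistic reparameterization so the
unconstrained Levenberg-Marquardt solver can be used, with multi-start
initialization (deterministic first start from the log-linear estimate,
seeded perturbations after that) and the lowest-residual start kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .models import (
    BValueProtocol,
    CTRWParams,
    FROCParams,
    MODEL_NAMES,
    MonoExpParams,
    SEMParams,
    SignalDecay,
    forward_signal,
)

__all__ = [
    "PARAMETER_NAMES",
    "FitConfig",
    "FitResult",
    "ParameterMap",
    "ROIMask",
    "normalize_signal",
    "loglinear_adc",
    "fit_decay",
    "fit_parameter_maps",
    "extract_roi_means",
]

#: The nine diffusion parameters, in reporting order.
PARAMETER_NAMES = (
    "adc",
    "ddc_sem",
    "alpha_sem",
    "d_froc",
    "beta_froc",
    "mu_froc",
    "d_ctrw",
    "alpha_ctrw",
    "beta_ctrw",
)

# Parameter bounds: D-type in um^2/ms, mu in um, exponents dimensionless.
_D_BOUNDS = (1e-4, 5.0)
_SHAPE_BOUNDS = (0.01, 1.0)
_MU_BOUNDS = (0.1, 50.0)

_MODEL_FREE = {
    "monoexp": (("ADC", _D_BOUNDS),),
    "sem": (("DDC", _D_BOUNDS), ("alpha", _SHAPE_BOUNDS)),
    "froc": (("D", _D_BOUNDS), ("beta", _SHAPE_BOUNDS), ("mu", _MU_BOUNDS)),
    "ctrw": (("D", _D_BOUNDS), ("alpha", _SHAPE_BOUNDS), ("beta", _SHAPE_BOUNDS)),
}

_PARAM_CLS = {
    "monoexp": MonoExpParams,
    "sem": SEMParams,
    "froc": FROCParams,
    "ctrw": CTRWParams,
}


@dataclass(frozen=True)
class FitConfig:
    """Controls for the nonlinear estimation.

    d_estimation_b_max : upper b (ms/um^2) of the sub-protocol used for
        the stage-1 D estimate of the FROC/CTRW models.
    adc_b_max : optional upper b restricting the mono-exponential ADC
        fit; ``None`` uses the full protocol.  In the presence of
        non-Gaussian decay this choice shifts ADC, so it is explicit
        configuration rather than a constant.
    refit_d : jointly refit D in stage 2 for FROC/CTRW instead of
        keeping the stage-1 value fixed.
    """

    d_estimation_b_max: float = 1.0
    adc_b_max: float | None = None
    refit_d: bool = False
    n_starts: int = 5
    max_nfev: int = 400
    tol: float = 1e-12
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    model: str
    params: object
    rss: float
    converged: bool
    n_iterations: int
    d_stage1: float | None = None

    def __post_init__(self):
        if self.rss < 0:
            raise ValueError("residual sum of squares cannot be negative")


@dataclass
class ParameterMap:
    """Per-voxel values of one fitted parameter with a validity mask."""

    name: str
    data: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape:
            raise ValueError("data and validity mask shapes differ")
        if not np.all(np.isfinite(self.data[self.valid])):
            raise ValueError("non-finite value inside validity mask")


@dataclass
class ROIMask:
    """Region of interest, with an optional exclusion sub-mask for
    necrotic/cystic voxels that must not contribute to node means."""

    include: np.ndarray
    exclude: np.ndarray | None = None

    def effective(self) -> np.ndarray:
        inc = np.asarray(self.include, dtype=bool)
        if self.exclude is not None:
            inc = inc & ~np.asarray(self.exclude, dtype=bool)
        return inc


class DegenerateVoxelError(ValueError):
    """Raised when a signal cannot be normalized (S(0) <= 0)."""


def normalize_signal(raw, protocol: BValueProtocol) -> SignalDecay:
    """Divide a raw decay by its b=0 value.

    Raises :class:`DegenerateVoxelError` when S(0) <= 0 (such voxels are
    marked invalid during map fitting) and ValueError when any
    normalized value is non-positive.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size != len(protocol.b_values):
        raise ValueError("raw signal length does not match protocol")
    if raw[0] <= 0:
        raise DegenerateVoxelError("signal at b = 0 must be strictly positive")
    return SignalDecay(protocol, tuple(raw / raw[0]))


def loglinear_adc(b, y) -> float:
    """Through-origin least squares of -ln(y) on b: the closed-form
    mono-exponential fit in log-signal space."""
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("log-linear estimate requires positive signal")
    return float(-(b @ np.log(y)) / (b @ b))


def _to_unconstrained(values, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    frac = np.clip((np.asarray(values) - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return logit(frac)


def _from_unconstrained(u, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * expit(np.asarray(u))


def _clip(value, bounds):
    lo, hi = bounds
    return float(np.clip(value, lo * (1 + 1e-9) if lo > 0 else lo + 1e-12, hi))


def _default_start(model: str, d0: float) -> dict:
    start = {"ADC": d0, "DDC": d0, "D": d0, "alpha": 0.9, "beta": 0.9, "mu": 3.0}
    return start


def _fit_free(
    b: np.ndarray,
    y: np.ndarray,
    model: str,
    free: tuple,
    fixed: dict,
    start: dict,
    protocol: BValueProtocol,
    config: FitConfig,
):
    names = [f[0] for f in free]
    bounds = [f[1] for f in free]
    cls = _PARAM_CLS[model]

    def residuals(u):
        vals = _from_unconstrained(u, bounds)
        p = cls(**{**fixed, **dict(zip(names, vals))})
        return forward_signal(model, b, p, protocol) - y

    rng = np.random.default_rng(config.seed)
    u0_base = _to_unconstrained([_clip(start[n], bd) for n, bd in free], bounds)
    best = None
    nfev_total = 0
    for k in range(config.n_starts):
        u0 = u0_base if k == 0 else u0_base + rng.normal(0.0, 1.0, size=len(names))
        try:
            sol = least_squares(
                residuals,
                u0,
                method="lm",
                xtol=config.tol,
                ftol=config.tol,
                gtol=config.tol,
                max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        nfev_total += sol.nfev
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return None, 0.0, False, nfev_total
    rss, sol = best
    vals = _from_unconstrained(sol.x, bounds)
    params = cls(**{**fixed, **dict(zip(names, vals))})
    return params, rss, bool(sol.status > 0), nfev_total


def fit_decay(decay: SignalDecay, model: str, config: FitConfig = FitConfig()) -> FitResult:
    """Estimate one model's parameters from a normalized decay.

    For ``froc`` and ``ctrw`` the stage-1 D comes from the log-linear
    mono-exponential estimate on b <= ``config.d_estimation_b_max``; the
    remaining parameters are fit over the full protocol with D fixed
    (or, with ``config.refit_d``, jointly refit from that initial
    value).  ``monoexp``/``sem`` are single-stage fits.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    protocol = decay.protocol
    b = protocol.b
    y = decay.y
    free = _MODEL_FREE[model]
    n_free = len(free) if not (model in ("froc", "ctrw") and not config.refit_d) else len(free) - 1
    if b.size < n_free + 1:
        raise ValueError("need at least one more b-value than free parameters")

    d_stage1 = None
    fixed: dict = {}
    sub = b <= config.d_estimation_b_max
    if model in ("froc", "ctrw"):
        d_stage1 = _clip(loglinear_adc(b[sub], y[sub]), _D_BOUNDS)
        if not config.refit_d:
            fixed = {"D": d_stage1}
            free = free[1:]
        d0 = d_stage1
    elif model == "monoexp" and config.adc_b_max is not None:
        keep = b <= config.adc_b_max
        b, y = b[keep], y[keep]
        d0 = _clip(loglinear_adc(b, y), _D_BOUNDS)
    else:
        d0 = _clip(loglinear_adc(b, y), _D_BOUNDS)

    start = _default_start(model, d0)
    params, rss, converged, nfev = _fit_free(b, y, model, free, fixed, start, protocol, config)
    if params is None:
        raise RuntimeError(f"all {config.n_starts} optimizer starts failed for model {model}")
    return FitResult(model, params, rss, converged, nfev, d_stage1)


def _nine_params(decay: SignalDecay, config: FitConfig) -> dict:
    out = {}
    r = fit_decay(decay, "monoexp", config)
    out["adc"] = (r.params.ADC, r.converged)
    r = fit_decay(decay, "sem", config)
    out["ddc_sem"] = (r.params.DDC, r.converged)
    out["alpha_sem"] = (r.params.alpha, r.converged)
    r = fit_decay(decay, "froc", config)
    out["d_froc"] = (r.params.D, r.converged)
    out["beta_froc"] = (r.params.beta, r.converged)
    out["mu_froc"] = (r.params.mu, r.converged)
    r = fit_decay(decay, "ctrw", config)
    out["d_ctrw"] = (r.params.D, r.converged)
    out["alpha_ctrw"] = (r.params.alpha, r.converged)
    out["beta_ctrw"] = (r.params.beta, r.converged)
    return out


def fit_parameter_maps(
    image4d: np.ndarray,
    protocol: BValueProtocol,
    mask: np.ndarray,
    config: FitConfig = FitConfig(),
    affine: np.ndarray | None = None,
) -> dict:
    """Voxel-wise fitting of all four models over a masked 4-D image.

    Returns the nine named :class:`ParameterMap` objects (ADC; SEM DDC
    and alpha; FROC D, beta, mu; CTRW D, alpha, beta).  Voxels outside
    the mask, or whose signal cannot be normalized, are invalid in all
    nine maps.  Voxels are fit independently (no spatial coupling), so
    the result does not depend on iteration order.
    """
    image4d = np.asarray(image4d, dtype=float)
    if image4d.ndim != 4 or image4d.shape[-1] != len(protocol.b_values):
        raise ValueError("image last axis must match the protocol length")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image4d.shape[:-1]:
        raise ValueError("mask shape must match the image grid")
    affine = np.eye(4) if affine is None else affine

    shape = image4d.shape[:-1]
    data = {n: np.full(shape, np.nan) for n in PARAMETER_NAMES}
    valid = {n: np.zeros(shape, dtype=bool) for n in PARAMETER_NAMES}

    for idx in np.argwhere(mask):
        idx = tuple(idx)
        try:
            decay = normalize_signal(image4d[idx], protocol)
            nine = _nine_params(decay, config)
        except (DegenerateVoxelError, ValueError):
            continue
        for name, (value, ok) in nine.items():
            data[name][idx] = value
            valid[name][idx] = ok

    return {n: ParameterMap(n, data[n], valid[n], affine) for n in PARAMETER_NAMES}


def extract_roi_means(maps: dict, roi: ROIMask) -> dict:
    """Arithmetic means of each parameter map over the usable ROI.

    The effective ROI removes the exclusion sub-mask (necrosis, cysts)
    and, per map, any invalid voxels.  Returns ``{name: mean}`` plus
    ``voxel_count`` (minimum count across maps).  Raises ValueError if
    any map has an empty effective ROI.
    """
    eff = roi.effective()
    if not np.any(eff):
        raise ValueError("ROI is empty after exclusions")
    out = {}
    counts = []
    for name, pmap in maps.items():
        usable = eff & pmap.valid
        n = int(np.count_nonzero(usable))
        if n == 0:
            raise ValueError(f"ROI contains no valid voxels for map {name!r}")
        counts.append(n)
        out[name] = float(pmap.data[usable].mean())
    out["voxel_count"] = min(counts)
    return out
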