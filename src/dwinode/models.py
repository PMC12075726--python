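"""Forward signal models for multi-b-value diffusion-weighted MRI.

Four decay models of the normalized signal S(b)/S(0) are provided:

* mono-exponential (Gaussian diffusion): ``exp(-b * ADC)``
* stretched-exponential (SEM): ``exp(-(b * DDC)**alpha)``
* fractional-order calculus (FROC), a generalization of the
  Bloch-Torrey decay parameterized by a diffusion coefficient D, a
  heterogeneity exponent beta and a spatial scale mu (micrometres),
  which requires the gradient timing (delta, Delta) of the acquisition
* continuous-time random walk (CTRW): ``E_alpha(-(b * D)**beta)`` with
  the Mittag-Leffler function E_alpha.

Canonical internal units: b-values in ms/um^2 (1 ms/um^2 = 1000 s/mm^2),
diffusion coefficients in um^2/ms, lengths in um, times in ms.  Readers
of s/mm^2 b-value tables divide by 1000 on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mittag import mittag_leffler

__all__ = [
    "GAMMA_PROTON",
    "DEFAULT_BVALUES",
    "BValueProtocol",
    "MonoExpParams",
    "SEMParams",
    "FROCParams",
    "CTRWParams",
    "SignalDecay",
    "signal_monoexp",
    "signal_sem",
    "signal_froc",
    "signal_ctrw",
    "forward_signal",
    "MODEL_NAMES",
]

#: Proton gyromagnetic ratio, rad * ms^-1 * mT^-1.
GAMMA_PROTON = 2.675e5

#: The 12-point acquisition protocol, ms/um^2 (0-3000 s/mm^2).
DEFAULT_BVALUES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class BValueProtocol:
    """Diffusion weighting protocol plus the gradient timing.

    The b-value of a pulsed-gradient experiment is
    ``b = (gamma * G_d * delta)**2 * (Delta - delta/3)``; the gradient
    amplitude ``G_d`` for each b is back-computed from this relation, so
    the FROC model can be evaluated on protocols specified only by their
    b-values.  ``delta`` (pulse width) and ``Delta`` (pulse separation)
    are acquisition configuration, not fit parameters; FROC mu values
    are only comparable between runs with identical timing.
    """

    b_values: tuple = DEFAULT_BVALUES
    delta: float = 15.0  # gradient pulse width, ms
    Delta: float = 35.0  # gradient interval, ms
    gamma: float = GAMMA_PROTON

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", tuple(b))
        if b.size < 2 or b[0] != 0.0:
            raise ValueError("protocol must start at b = 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if not (self.delta > 0 and self.Delta > self.delta / 3.0):
            raise ValueError("gradient timing requires Delta > delta/3 > 0")

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def gradient_amplitude(self, b) -> np.ndarray:
        """G_d (mT/um) for each b via b = (gamma*G_d*delta)^2 (Delta - delta/3)."""
        b = np.asarray(b, dtype=float)
        return np.sqrt(b / (self.Delta - self.delta / 3.0)) / (self.gamma * self.delta)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class MonoExpParams:
    """Apparent diffusion coefficient, um^2/ms."""

    ADC: float

    def __post_init__(self):
        _require(self.ADC > 0, "ADC must be positive")


@dataclass(frozen=True)
class SEMParams:
    """Stretched-exponential model: distributed diffusion coefficient
    DDC (um^2/ms) and heterogeneity index alpha in (0, 1]."""

    DDC: float
    alpha: float

    def __post_init__(self):
        _require(self.DDC > 0, "DDC must be positive")
        _require(0 < self.alpha <= 1, "alpha must be in (0, 1]")


@dataclass(frozen=True)
class FROCParams:
    """Fractional-order calculus model: D (um^2/ms), heterogeneity
    exponent beta in (0, 1], spatial parameter mu (um)."""

    D: float
    beta: float
    mu: float

    def __post_init__(self):
        _require(self.D > 0, "D must be positive")
        _require(0 < self.beta <= 1, "beta must be in (0, 1]")
        _require(self.mu > 0, "mu must be positive")


@dataclass(frozen=True)
class CTRWParams:
    """Continuous-time random walk model: anomalous diffusion
    coefficient D (um^2/ms), temporal heterogeneity alpha and spatial
    heterogeneity beta, both in (0, 1]."""

    D: float
    alpha: float
    beta: float

    def __post_init__(self):
        _require(self.D > 0, "D must be positive")
        _require(0 < self.alpha <= 1, "alpha must be in (0, 1]")
        _require(0 < self.beta <= 1, "beta must be in (0, 1]")


@dataclass(frozen=True)
class SignalDecay:
    """One voxel's (or node's) normalized signal across a protocol."""

    protocol: BValueProtocol
    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", tuple(v))
        if v.size != len(self.protocol.b_values):
            raise ValueError("signal length does not match protocol")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValueError("normalized signal must equal 1 at b = 0")
        if np.any(v <= 0):
            raise ValueError("normalized signal must be positive")

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def signal_monoexp(b, p: MonoExpParams):
    """Mono-exponential decay exp(-b * ADC)."""
    return np.exp(-_check_b(b) * p.ADC)


def signal_sem(b, p: SEMParams):
    """Stretched-exponential decay exp(-(b * DDC)**alpha)."""
    return np.exp(-((_check_b(b) * p.DDC) ** p.alpha))


def signal_froc(b, protocol: BValueProtocol, p: FROCParams):
    """Fractional-order-calculus decay.

    exp(-D * mu^(2(beta-1)) * (gamma*G_d*delta)^(2 beta)
        * (Delta - (2 beta - 1)/(2 beta + 1) * delta))

    with G_d back-computed per b from the protocol timing; at beta = 1
    the exponent collapses to -b*D.
    """
    b = _check_b(b)
    q2 = b / (protocol.Delta - protocol.delta / 3.0)  # (gamma*G_d*delta)^2, um^-2
    t_eff = protocol.Delta - (2.0 * p.beta - 1.0) / (2.0 * p.beta + 1.0) * protocol.delta
    return np.exp(-p.D * p.mu ** (2.0 * (p.beta - 1.0)) * q2**p.beta * t_eff)


def signal_ctrw(b, p: CTRWParams):
    """CTRW decay E_alpha(-(b * D)**beta) via the Mittag-Leffler function."""
    b = _check_b(b)
    return mittag_leffler(p.alpha, -((b * p.D) ** p.beta))


MODEL_NAMES = ("monoexp", "sem", "froc", "ctrw")


def forward_signal(model: str, b, params, protocol: BValueProtocol | None = None):
    """Dispatch to one of the four forward models by name."""
    if model == "monoexp":
        return signal_monoexp(b, params)
    if model == "sem":
        return signal_sem(b, params)
    if model == "froc":
        if protocol is None:
            raise ValueError("froc model requires a protocol (gradient timing)")
        return signal_froc(b, protocol, params)
    if model == "ctrw":
        return signal_ctrw(b, params)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
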