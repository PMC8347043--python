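"""Time-domain NMR FID relaxation models and fitting.

Two standard models for the free induction decay of a low-moisture
carbohydrate system are implemented:

* model 1: Abragam component + exponential liquid component

      F1(t) = Ss exp(-(t/T2s*)^2) sinc(b t) + L exp(-t/T2L*)

* model 2: adds a Gaussian solid component

      F2(t) = Sg exp(-(t/T2g*)^2) + F1(t)

The Abragam function (Gaussian times sinc) describes strongly
dipolar-coupled, semi-crystalline-like protons; the pure Gaussian an
amorphous rigid fraction; the exponential the mobile (liquid-like)
protons.  The Gaussian exponent carries no factor 1/2 — T2* constants are
defined by exp(-(t/T2*)^2) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RelaxParams",
    "FIDSignal",
    "FitResult",
    "abragam",
    "eval_model",
    "fit_fid",
    "second_moment",
    "solid_fractions",
]

#: smallest b (rad/us) that still labels a component "Abragam" rather than
#: Gaussian; prevents Sg/Ss component swapping across temperature series.
B_MIN = 1e-3

PARAM_NAMES = {
    1: ("Ss", "T2s_star", "b", "L", "T2L_star"),
    2: ("Sg", "T2g_star", "Ss", "T2s_star", "b", "L", "T2L_star"),
}


@dataclass(frozen=True)
class RelaxParams:
    """FID relaxation parameters (amplitudes unitless, times in us, b in rad/us)."""

    Ss: float
    T2s_star: float
    b: float
    L: float
    T2L_star: float
    Sg: float = 0.0
    T2g_star: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Ss", "L", "Sg"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplitude {name} must be >= 0")
        for name in ("T2s_star", "T2L_star", "T2g_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")

    def as_array(self, model_id: int) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES[model_id]], float)

    @staticmethod
    def from_array(theta: np.ndarray, model_id: int) -> "RelaxParams":
        d = dict(zip(PARAM_NAMES[model_id], theta))
        return RelaxParams(**d)


@dataclass
class FIDSignal:
    """A sampled FID: uniform time grid (us), amplitudes, optional sigma."""

    times: np.ndarray
    amplitudes: np.ndarray
    sigma: Optional[np.ndarray] = None
    temperature: float = np.nan

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.times.shape:
                raise ValueError("sigma length mismatch")


@dataclass
class FitResult:
    params: RelaxParams
    chi2_min: float
    model_id: int
    covariance: Optional[np.ndarray] = None
    converged: bool = True
    message: str = ""
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.chi2_min < 0:
            raise ValueError("chi2_min cannot be negative")


def _sinc(x):
    """sin(x)/x with the x -> 0 limit taken as 1."""
    return np.sinc(np.asarray(x, float) / np.pi)


def abragam(t, Ss: float, T2s_star: float, b: float):
    """Abragam FID component Ss*exp(-(t/T2s*)^2)*sin(bt)/(bt)."""
    if T2s_star <= 0:
        raise ValueError("T2s_star must be > 0")
    t = np.asarray(t, float)
    out = Ss * np.exp(-((t / T2s_star) ** 2)) * _sinc(b * t)
    return float(out) if out.ndim == 0 else out


def eval_model(model_id: int, params: RelaxParams, t):
    """Evaluate model 1 or 2 at times t (us)."""
    if model_id not in (1, 2):
        raise ValueError("model_id must be 1 or 2")
    if model_id == 1 and params.Sg > 0:
        raise ValueError("model 1 has no Gaussian component; Sg must be 0")
    t = np.asarray(t, float)
    out = abragam(t, params.Ss, params.T2s_star, params.b)
    out = out + params.L * np.exp(-t / params.T2L_star)
    if model_id == 2:
        out = out + params.Sg * np.exp(-((t / params.T2g_star) ** 2))
    return float(out) if np.ndim(out) == 0 else out


def _model1_view(params: RelaxParams) -> RelaxParams:
    return replace(params, Sg=0.0)


def chi_square(signal: FIDSignal, model_id: int, params: RelaxParams) -> float:
    """chi^2 = sum(((y - F(t))/sigma)^2), unit sigma if absent."""
    p = _model1_view(params) if model_id == 1 else params
    model = eval_model(model_id, p, signal.times)
    sigma = signal.sigma if signal.sigma is not None else 1.0
    return float(np.sum(((signal.amplitudes - model) / sigma) ** 2))


def default_init(signal: FIDSignal, model_id: int) -> RelaxParams:
    """Heuristic starting point: amplitudes from a coarse signal partition
    (initial value, tail level), time constants from a small log-spaced
    grid search over the solid decay."""
    y = signal.amplitudes
    t = signal.times
    total = max(float(y[:3].mean()), 1e-12)
    tail = float(np.median(y[t > 0.4 * t[-1]]))
    tail = min(max(tail, 1e-3 * total), 0.95 * total)
    solid = max(total - tail, 1e-3 * total)

    best = None
    for t2s in np.geomspace(5.0, 80.0, 8):
        for b in (0.05, 0.15, 0.3, 0.5):
            if model_id == 2:
                cand = RelaxParams(Ss=0.4 * solid, T2s_star=1.3 * t2s, b=b,
                                   L=tail, T2L_star=max(t[-1] / 4, 50.0),
                                   Sg=0.6 * solid, T2g_star=t2s)
            else:
                cand = RelaxParams(Ss=solid, T2s_star=t2s, b=b,
                                   L=tail, T2L_star=max(t[-1] / 4, 50.0))
            c2 = chi_square(signal, model_id, cand)
            if best is None or c2 < best[0]:
                best = (c2, cand)
    return best[1]


def fit_fid(
    signal: FIDSignal,
    model_id: int,
    init: Optional[RelaxParams] = None,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    mask_leading: int = 0,
) -> FitResult:
    """Bounded nonlinear least-squares fit of a relaxation model to a FID.

    ``mask_leading`` drops that many leading points (receiver dead time);
    default keeps all.  Non-convergence is flagged on the result, never
    raised.  The Abragam component keeps b >= B_MIN so it cannot collapse
    onto the Gaussian and swap labels between temperatures.
    """
    names = PARAM_NAMES[model_id]
    if signal.times.size - mask_leading < len(names):
        raise ValueError("fewer points than free parameters")
    sig = signal
    if mask_leading:
        sig = FIDSignal(signal.times[mask_leading:], signal.amplitudes[mask_leading:],
                        None if signal.sigma is None else signal.sigma[mask_leading:],
                        signal.temperature)
    if init is None:
        init = default_init(sig, model_id)
    x0 = init.as_array(model_id)

    amp_hi = 10.0 * max(float(np.abs(sig.amplitudes).max()), 1e-9)
    default_bounds = {
        "Sg": (0.0, amp_hi), "T2g_star": (1.0, 200.0),
        "Ss": (0.0, amp_hi), "T2s_star": (1.0, 500.0),
        "b": (B_MIN, 2.0),
        "L": (0.0, amp_hi), "T2L_star": (10.0, 1e5),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[n][0] for n in names])
    hi = np.array([default_bounds[n][1] for n in names])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    w = 1.0 / sig.sigma if sig.sigma is not None else 1.0

    def residuals(theta):
        p = RelaxParams.from_array(theta, model_id)
        return (sig.amplitudes - eval_model(model_id, p, sig.times)) * w

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    params = RelaxParams.from_array(sol.x, model_id)
    chi2 = float(np.sum(sol.fun**2))

    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(sig.times.size - len(names), 1)
        scale = chi2 / dof if sig.sigma is None else 1.0
        cov = np.linalg.pinv(jtj) * scale
    except np.linalg.LinAlgError:
        pass
    return FitResult(params=params, chi2_min=chi2, model_id=model_id,
                     covariance=cov, converged=bool(sol.success),
                     message=sol.message, n_points=int(sig.times.size))


def second_moment(params: RelaxParams, model_id: int, component: str) -> float:
    """Second moment M2 = -F''(0)/F(0) of one unit-amplitude solid component.

    Abragam: 2/T2s*^2 + b^2/3.  Gaussian: 2/T2g*^2 (model 2 only).
    Units: us^-2.
    """
    if component == "abragam":
        return 2.0 / params.T2s_star**2 + params.b**2 / 3.0
    if component == "gaussian":
        if model_id != 2:
            raise ValueError("model 1 has no Gaussian component")
        return 2.0 / params.T2g_star**2
    raise ValueError(f"unknown component {component!r}")


def solid_fractions(params: RelaxParams) -> tuple[float, float, float]:
    """(Ss, Sg, L) as fractions of the total t=0 amplitude; sums to 1."""
    total = params.Ss + params.Sg + params.L
    if total <= 0:
        raise ValueError("all amplitudes are zero")
    return (params.Ss / total, params.Sg / total, params.L / total)
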