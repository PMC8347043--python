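"""Gordon-Taylor plasticization model and moisture/composition arithmetic.

The Gordon-Taylor equation is the standard two-component mixing rule for
the glass transition temperature of a water-plasticized biopolymer,

    Tg(Xw) = (Xs*Tgs + k*Xw*Tgw) / (Xs + k*Xw),   Xs = 1 - Xw,

with ``Tgs`` the dry-matter glass transition, ``Tgw`` the (literature)
glass transition of pure water and ``k`` a dimensionless fitting constant.
``Xw`` is the wet-basis water mass fraction; laboratory moisture values in
g water per g dry matter are converted with :func:`moisture_convert`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GTParams",
    "MoistureValue",
    "gt_tg",
    "fit_gt",
    "moisture_convert",
    "carbohydrate_residue",
]

#: Literature glass transition of pure (hyperquenched) water, deg C.
TGW_DEFAULT = -135.0


@dataclass(frozen=True)
class GTParams:
    """Gordon-Taylor parameters: dry-matter Tg, water Tg (deg C) and k."""

    Tgs: float
    Tgw: float = TGW_DEFAULT
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.Tgs <= self.Tgw:
            raise ValueError("Tgs must exceed Tgw")


@dataclass(frozen=True)
class MoistureValue:
    """Moisture content value with its basis.

    ``dry_matter`` means g water per g dry matter; ``wet`` means mass
    fraction of water in the total sample (must be < 1).
    """

    value: float
    basis: Literal["dry_matter", "wet"]

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("moisture cannot be negative")
        if self.basis == "wet" and self.value >= 1:
            raise ValueError("wet-basis moisture must be < 1")
        if self.basis not in ("dry_matter", "wet"):
            raise ValueError(f"unknown basis {self.basis!r}")


def gt_tg(Xw, params: GTParams):
    """Gordon-Taylor glass transition temperature at wet-basis water fraction Xw."""
    Xw = np.asarray(Xw, dtype=float)
    if np.any(Xw < 0) or np.any(Xw > 1):
        raise ValueError("Xw must lie in [0, 1]")
    Xs = 1.0 - Xw
    out = (Xs * params.Tgs + params.k * Xw * params.Tgw) / (Xs + params.k * Xw)
    return float(out) if out.ndim == 0 else out


def moisture_convert(m: MoistureValue, target_basis: str) -> MoistureValue:
    """Convert between dry-matter (g/g d.m.) and wet-basis mass fraction."""
    if target_basis not in ("dry_matter", "wet"):
        raise ValueError(f"unknown basis {target_basis!r}")
    if m.basis == target_basis:
        return m
    if m.basis == "dry_matter":
        return MoistureValue(m.value / (1.0 + m.value), "wet")
    return MoistureValue(m.value / (1.0 - m.value), "dry_matter")


def fit_gt(
    points: Sequence[tuple[float, float]],
    Tgw_fixed: float = TGW_DEFAULT,
    init: tuple[float, float] = (100.0, 2.0),
) -> tuple[GTParams, float]:
    """Fit (Tgs, k) to (Xw, Tg) data with Tgw held fixed.

    Returns the fitted parameters and the coefficient of determination
    R^2 = 1 - SSE/SST.  The water Tg is treated as a literature constant,
    not a free parameter.  Raises on rank-deficient data (fewer than three
    points or no spread in Xw).  A fit driven to the k -> 0 boundary (data
    carrying no plasticization signal) raises as degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (Xw, Tg) points")
    xw, tg = pts[:, 0], pts[:, 1]
    if np.ptp(xw) == 0:
        raise ValueError("Xw values are all equal; fit is rank-deficient")

    def residuals(theta):
        tgs, k = theta
        p = GTParams(Tgs=tgs, Tgw=Tgw_fixed, k=max(k, 1e-12))
        return gt_tg(xw, p) - tg

    sol = least_squares(
        residuals, x0=np.asarray(init, float),
        bounds=([Tgw_fixed + 1e-6, 1e-9], [np.inf, np.inf]),
        method="trf",
    )
    tgs_hat, k_hat = sol.x
    if k_hat < 1e-4:
        raise ValueError("fit collapsed to k ~ 0 (constant-Tg data?)")
    sse = float(np.sum(sol.fun**2))
    sst = float(np.sum((tg - tg.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return GTParams(Tgs=float(tgs_hat), Tgw=Tgw_fixed, k=float(k_hat)), r2


def carbohydrate_residue(
    moisture_pct: float, protein_pct: float, fat_pct: float, ash_pct: float
) -> float:
    """Total carbohydrates by difference: 100 minus the other constituents (percent)."""
    parts = (moisture_pct, protein_pct, fat_pct, ash_pct)
    for p in parts:
        if not 0 <= p <= 100:
            raise ValueError("constituent percentages must lie in [0, 100]")
    total = sum(parts)
    if total > 100:
        raise ValueError(f"constituents sum to {total} > 100%")
    return 100.0 - total
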