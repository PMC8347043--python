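"""Density estimation from transmission plateaus and diffraction backgrounds.

In the impulse-approximation (epithermal) regime the transmission plateau
is set solely by the scattering power s = n d Sigma_free, so with constant
composition the ratio of scattering powers across temperature is the
ratio of number densities.  Likewise, the flat incoherent background of a
diffraction pattern (hydrogen-dominated, away from the aluminium container
Bragg peaks) is proportional to the sample number density.  Both are
calibrated at the lowest measured temperature to a tabulated density, and
the two calibrated estimators serve as independent cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import AL_LATTICE_A, AVOGADRO
from .afga import AFGAModel, CrossSectionCurve, Stoichiometry, total_sigma, window_integral
from .synthetic import DiffractionPattern, TransmissionCurve, al_bragg_dspacings

__all__ = [
    "DensityEstimate",
    "scattering_power",
    "transmission_to_sigma",
    "density_from_transmission",
    "background_integral",
    "density_from_diffraction",
    "afga_discrepancy",
    "detect_transition",
]

#: default epithermal plateau window, eV
PLATEAU_WINDOW = (10.0, 100.0)

#: default diffraction background window, Angstrom (excludes all Al
#: reflections; the largest allowed fcc d-spacing is (111) at 2.338 A)
BACKGROUND_WINDOW = (2.5, 3.5)


@dataclass(frozen=True)
class DensityEstimate:
    temperature: float
    density: float
    error: float
    source: str  # "transmission" | "diffraction"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")


def scattering_power(curve: TransmissionCurve,
                     window: tuple[float, float] = PLATEAU_WINDOW) -> tuple[float, float]:
    """s = -ln(mean plateau transmission) over the epithermal window.

    Returns (s, error) with the error propagated from per-point
    uncertainties of the mean transmission (zero if the curve carries no
    errors).
    """
    lo, hi = window
    sel = (curve.energies >= lo) & (curve.energies <= hi)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 grid points in the plateau window")
    tbar = float(curve.transmission[sel].mean())
    s = -np.log(tbar)
    err = 0.0
    if curve.errors is not None:
        mean_err = float(np.sqrt(np.sum(curve.errors[sel] ** 2))) / sel.sum()
        err = mean_err / tbar
    return s, err


def transmission_to_sigma(curve: TransmissionCurve, rho: float,
                          stoich: Stoichiometry) -> CrossSectionCurve:
    """Effective cross-section sigma(E) = -ln T(E) / (n_fu d), barns per
    formula unit, correcting for the sample's (temperature-dependent)
    density."""
    if rho <= 0 or curve.thickness <= 0:
        raise ValueError("rho and thickness must be positive")
    nd = rho * AVOGADRO / stoich.molar_mass * curve.thickness * 1e-24  # 1/barn
    sigma = -np.log(curve.transmission) / nd
    err = None
    if curve.errors is not None:
        err = curve.errors / curve.transmission / nd
    return CrossSectionCurve(energies=curve.energies, sigma_total=sigma,
                             temperature=curve.temperature, errors=err)


def _calibrated_series(values, errors, temps, T_ref, rho_ref, source):
    temps = np.asarray(temps, float)
    if not np.any(np.isclose(temps, T_ref)):
        raise ValueError(f"reference temperature {T_ref} not in series")
    i_ref = int(np.argmin(np.abs(temps - T_ref)))
    v_ref = values[i_ref]
    out = []
    for i, (T, v, e) in enumerate(zip(temps, values, errors)):
        # the reference point is pinned exactly by construction
        rho = rho_ref if i == i_ref else rho_ref * (v / v_ref)
        # counting-noise propagation; the calibration factor itself is exact
        err = rho_ref * e / v_ref
        out.append(DensityEstimate(temperature=float(T), density=float(rho),
                                   error=float(err), source=source))
    return out


def density_from_transmission(
    series: Sequence[TransmissionCurve],
    calibration: tuple[float, float] = (-20.0, 1.3),
    window: tuple[float, float] = PLATEAU_WINDOW,
) -> list[DensityEstimate]:
    """rho(T) = rho_ref * s(T)/s(T_ref) from the transmission plateau,
    pinned exactly to rho_ref at the calibration temperature."""
    T_ref, rho_ref = calibration
    temps = [c.temperature for c in series]
    sp = [scattering_power(c, window) for c in series]
    values = [v for v, _ in sp]
    errors = [e for _, e in sp]
    return _calibrated_series(values, errors, temps, T_ref, rho_ref, "transmission")


def background_integral(
    pattern: DiffractionPattern,
    window: tuple[float, float] = BACKGROUND_WINDOW,
    al_lattice_a: float = AL_LATTICE_A,
    exclusion_widths: float = 3.0 * 0.01,
) -> tuple[float, float]:
    """Trapezoidal integral of counts over a d-spacing window that must
    avoid every allowed aluminium reflection by >= 3 peak widths.

    Raises naming the offending (hkl) when the window touches a Bragg
    position.  Returns (integral, propagated error) in counts*Angstrom.
    """
    lo, hi = window
    for hkl, d0 in al_bragg_dspacings(al_lattice_a, d_min=0.5):
        if lo - exclusion_widths <= d0 <= hi + exclusion_widths:
            raise ValueError(
                f"window [{lo}, {hi}] A overlaps the Al {hkl} reflection at d={d0:.3f} A")
    d = pattern.d_spacings
    sel = (d >= lo) & (d <= hi)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 grid points in the background window")
    integral = float(np.trapezoid(pattern.counts[sel], d[sel]))
    err = 0.0
    if pattern.errors is not None:
        dx = np.gradient(d[sel])
        err = float(np.sqrt(np.sum((pattern.errors[sel] * dx) ** 2)))
    return integral, err


def density_from_diffraction(
    series: Sequence[DiffractionPattern],
    calibration: tuple[float, float] = (-20.0, 1.3),
    window: tuple[float, float] = BACKGROUND_WINDOW,
) -> list[DensityEstimate]:
    """rho(T) = rho_ref * B(T)/B(T_ref) from the incoherent background."""
    T_ref, rho_ref = calibration
    temps = [p.temperature for p in series]
    bi = [background_integral(p, window) for p in series]
    values = [v for v, _ in bi]
    errors = [e for _, e in bi]
    return _calibrated_series(values, errors, temps, T_ref, rho_ref, "diffraction")


def afga_discrepancy(
    measured: Sequence[CrossSectionCurve],
    model: AFGAModel,
    lo_mev: float = 2.6,
    hi_mev: float = 10.0,
) -> list[tuple[float, float, float]]:
    """Difference between measured and AFGA-predicted window integrals.

    Returns rows (T, delta_integral, error) where delta = integral of the
    measured effective cross-section over [2.6, 10] meV minus the AFGA
    prediction's integral at the same temperature.  Errors are propagated
    from the measured curve's per-point uncertainties.
    """
    rows = []
    for curve in measured:
        pred = total_sigma(curve.energies, model, curve.temperature)
        i_meas = window_integral(curve, lo_mev, hi_mev)
        i_pred = window_integral(pred, lo_mev, hi_mev)
        err = 0.0
        if curve.errors is not None:
            sel = (curve.energies >= lo_mev * 1e-3) & (curve.energies <= hi_mev * 1e-3)
            de = np.gradient(curve.energies[sel]) * 1000.0
            err = float(np.sqrt(np.sum((curve.errors[sel] * de) ** 2)))
        rows.append((curve.temperature, i_meas - i_pred, err))
    return rows


def detect_transition(series: Sequence[DensityEstimate],
                      factor: float = 3.0) -> Optional[tuple[float, float]]:
    """Bracket the density drop: the run of consecutive inter-point drops
    each exceeding ``factor`` x the median absolute inter-point change.

    Returns the bracketing measured temperatures (never interpolated), or
    None when no drop stands out (flat or uniformly sloped series).
    """
    if len(series) < 4:
        raise ValueError("need at least 4 temperatures")
    pts = sorted(series, key=lambda e: e.temperature)
    T = np.array([p.temperature for p in pts])
    rho = np.array([p.density for p in pts])
    changes = np.diff(rho)
    med = float(np.median(np.abs(changes)))
    threshold = factor * med
    big_drop = (-changes) > threshold
    if med == 0.0:
        big_drop = (-changes) > 0
    if not np.any(big_drop):
        return None
    # merge consecutive flagged intervals; keep the run with the largest total drop
    runs = []
    i = 0
    while i < big_drop.size:
        if big_drop[i]:
            j = i
            while j + 1 < big_drop.size and big_drop[j + 1]:
                j += 1
            runs.append((i, j, float(-(rho[j + 1] - rho[i]))))
            i = j + 1
        else:
            i += 1
    i0, j0, _ = max(runs, key=lambda r: r[2])
    return float(T[i0]), float(T[j0 + 1])
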