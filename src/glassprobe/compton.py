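"""Neutron Compton scattering on an inverse-geometry TOF spectrometer.

An inverse-geometry instrument fixes the *final* neutron energy E1 at each
detector; the incident energy follows from the time of flight over the
incident (L0) and final (L1) paths.  In the impulse approximation each
mass M produces a recoil peak at the TOF where energy and momentum
conservation is satisfied exactly (y = 0), and the peak shape maps the
nuclear momentum distribution J(y) — here purely Gaussian with width
sigma_y — into the TOF domain through the local Jacobian dy/dt.

Fits follow the variable-projection (separable least squares) scheme: peak
centres are fixed by kinematics, intensities are linear parameters solved
by non-negative linear least squares for every trial width vector, and
only the widths are searched nonlinearly.  Detector-by-detector fits are
aggregated by an iterative inverse-variance average of the widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, nnls

from .constants import HBAR2_OVER_2MN, HBAR2_OVER_MN, MASS_RATIO, NEUTRON_VELOCITY_CONST, SIGMA_BOUND
from .afga import AFGAModel, free_cross_section, hydrogen_nmd_width

__all__ = [
    "DetectorGeometry",
    "NCSSpectrum",
    "NMDResult",
    "recoil_incident_energy",
    "tof_of",
    "energy_from_tof",
    "y_of_tof",
    "y_transform",
    "peak_profile",
    "varpro_fit_detector",
    "aggregate_detectors",
    "compare_widths_to_afga",
    "MASS_TO_ELEMENT",
]

MASS_TO_ELEMENT = {1: "H", 12: "C", 16: "O", 27: "Al"}


@dataclass(frozen=True)
class DetectorGeometry:
    """Scattering angle (deg), flight paths (m), fixed final energy (meV)
    and a Gaussian resolution width in y-space (1/Angstrom)."""

    theta: float
    L0: float = 11.0
    L1: float = 0.7
    E1: float = 4897.0
    resolution_width: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 180.0:
            raise ValueError("theta must lie in (0, 180) degrees")
        if min(self.L0, self.L1, self.E1) <= 0:
            raise ValueError("L0, L1, E1 must be positive")


@dataclass
class NCSSpectrum:
    tof: np.ndarray          # microseconds
    counts: np.ndarray
    geometry: DetectorGeometry
    errors: Optional[np.ndarray] = None
    temperature: float = np.nan

    def __post_init__(self) -> None:
        self.tof = np.asarray(self.tof, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.tof) <= 0):
            raise ValueError("tof must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, float)


@dataclass
class NMDResult:
    """Aggregated per-mass momentum-distribution widths and intensities."""

    masses: list[float]
    widths: dict[float, float]
    width_errors: dict[float, float]
    relative_intensities: dict[float, float]
    intensity_errors: dict[float, float]
    converged: bool = True
    n_iterations: int = 0
    temperature: float = np.nan

    def __post_init__(self) -> None:
        for m, w in self.widths.items():
            if w <= 0:
                raise ValueError(f"non-positive width for mass {m}")
        tot = sum(self.relative_intensities.values())
        if self.relative_intensities and abs(tot - 1.0) > 1e-9:
            raise ValueError("relative intensities must sum to 1")


def _mass_ratio(mass: float) -> float:
    key = int(round(mass))
    if key in MASS_TO_ELEMENT:
        return MASS_RATIO[MASS_TO_ELEMENT[key]]
    return mass / 1.0086649


def recoil_incident_energy(theta: float, E1: float, A: float) -> float:
    """Incident energy (meV) satisfying free-recoil (y = 0) kinematics.

    Solves E0 - E1 = (1/A)(E0 + E1 - 2 sqrt(E0 E1) cos(theta)).  For A = 1
    the closed form is E0 = E1/cos^2(theta), which has no solution at
    theta >= 90 deg — hydrogen recoil is visible only in forward
    scattering.
    """
    if A <= 0:
        raise ValueError("mass ratio must be positive")
    c = np.cos(np.radians(theta))
    if abs(A - 1.0) < 1e-9:
        if c <= 0:
            raise ValueError(
                f"no hydrogen recoil solution at theta={theta} deg (needs theta < 90)")
        return E1 / c**2
    disc = c * c + A * A - 1.0
    if disc < 0:
        raise ValueError(f"no kinematic solution for A={A} at theta={theta}")
    r = (-c + np.sqrt(disc)) / (A - 1.0)
    if r <= 0:
        raise ValueError(f"unphysical kinematic root for A={A}, theta={theta}")
    return float(E1 * r * r)


def _velocity(E_mev):
    return NEUTRON_VELOCITY_CONST * np.sqrt(E_mev)


def tof_of(E0: float, geometry: DetectorGeometry) -> float:
    """Total time of flight (us) for incident energy E0 (meV)."""
    if np.any(np.asarray(E0) <= 0):
        raise ValueError("E0 must be positive")
    t0 = geometry.L0 / _velocity(E0) * 1e6
    t1 = geometry.L1 / _velocity(geometry.E1) * 1e6
    return t0 + t1


def energy_from_tof(t_us, geometry: DetectorGeometry):
    """Incident energy (meV) from total TOF (us); inverse of :func:`tof_of`."""
    t1 = geometry.L1 / _velocity(geometry.E1) * 1e6
    dt = np.asarray(t_us, float) - t1
    if np.any(dt <= 0):
        raise ValueError("TOF earlier than the final flight time")
    v0 = geometry.L0 / (dt * 1e-6)
    return (v0 / NEUTRON_VELOCITY_CONST) ** 2


def y_of_tof(t_us, geometry: DetectorGeometry, mass: float):
    """Longitudinal momentum variable y (1/Angstrom) for each TOF bin.

    y = (M/hbar q)(omega - hbar q^2/2M) with omega, q evaluated from the
    fixed-final-energy kinematics; the recoil peak sits at y = 0.
    """
    A = _mass_ratio(mass)
    E0 = np.asarray(energy_from_tof(t_us, geometry), float)
    E1 = geometry.E1
    omega = E0 - E1
    k0 = np.sqrt(E0 / HBAR2_OVER_2MN)
    k1 = np.sqrt(E1 / HBAR2_OVER_2MN)
    q = np.sqrt(k0**2 + k1**2 - 2.0 * k0 * k1 * np.cos(np.radians(geometry.theta)))
    return A * omega / (HBAR2_OVER_MN * q) - q / 2.0


def y_transform(spectrum: NCSSpectrum, mass: float):
    """Map a TOF spectrum into J(y) for one mass, Jacobian-corrected and
    normalized to unit area.  Returns (y, J) sorted by increasing y."""
    y = y_of_tof(spectrum.tof, spectrum.geometry, mass)
    dydt = np.gradient(y, spectrum.tof)
    J = spectrum.counts / np.abs(dydt)
    order = np.argsort(y)
    y, J = y[order], J[order]
    area = np.trapezoid(J, y)
    if area <= 0:
        raise ValueError("non-positive spectral area; cannot normalize J(y)")
    return y, J / area


def peak_profile(tof, geometry: DetectorGeometry, mass: float,
                 sigma_y: float, include_resolution: bool = True):
    """Unit-area recoil-peak profile in TOF for a Gaussian NMD of width
    sigma_y (detector resolution added in quadrature in y-space).

    The y-space Gaussian is mapped pointwise through the kinematic
    Jacobian |dy/dt|, so transforming the profile back to y recovers the
    Gaussian exactly; the integral over a TOF grid covering the peak is 1
    by construction.
    """
    sig = sigma_y
    if include_resolution:
        sig = np.sqrt(sigma_y**2 + geometry.resolution_width**2)
    t = np.asarray(tof, float)
    if t.ndim == 0 or t.size < 2:
        raise ValueError("peak_profile needs a TOF grid of >= 2 points")
    y = y_of_tof(t, geometry, mass)
    dydt = np.gradient(y, t)
    return np.exp(-0.5 * (y / sig) ** 2) / (sig * np.sqrt(2 * np.pi)) * np.abs(dydt)


def visible_masses(masses: Sequence[float], geometry: DetectorGeometry) -> list[float]:
    """Masses with a kinematic recoil solution at this detector (drops H
    at theta >= 90 deg)."""
    out = []
    for m in masses:
        try:
            recoil_incident_energy(geometry.theta, geometry.E1, _mass_ratio(m))
        except ValueError:
            continue
        out.append(m)
    return out


@dataclass
class DetectorFit:
    geometry: DetectorGeometry
    masses: list[float]
    widths: dict[float, float]
    width_errors: dict[float, float]
    intensities: dict[float, float]
    baseline: float
    chi2: float
    converged: bool


def solve_intensities(spectrum: NCSSpectrum, masses: Sequence[float],
                      widths: dict[float, float]) -> tuple[np.ndarray, float, float]:
    """Linear sub-problem: non-negative least-squares intensities (and a
    flat baseline) for fixed widths.  Returns (intensities, baseline, chi2)."""
    w = 1.0 / spectrum.errors if spectrum.errors is not None else np.ones_like(spectrum.counts)
    cols = [peak_profile(spectrum.tof, spectrum.geometry, m, widths[m]) for m in masses]
    cols.append(np.ones_like(spectrum.tof))
    design = np.column_stack(cols) * w[:, None]
    rhs = spectrum.counts * w
    coef, _ = nnls(design, rhs)
    resid = rhs - design @ coef
    return coef[:-1], float(coef[-1]), float(np.sum(resid**2))


def varpro_fit_detector(
    spectrum: NCSSpectrum,
    masses: Sequence[float],
    init_widths: dict[float, float],
    width_bounds: tuple[float, float] = (0.5, 60.0),
) -> DetectorFit:
    """Separable (variable-projection) fit of one detector spectrum.

    Peak centres are fixed by kinematics; for each trial width vector the
    intensities are the unique non-negative linear least-squares solution;
    the outer search runs over widths only.
    """
    vis = visible_masses(masses, spectrum.geometry)
    if not vis:
        raise ValueError("no fittable masses at this detector")
    centres = [tof_of(recoil_incident_energy(spectrum.geometry.theta,
                                             spectrum.geometry.E1, _mass_ratio(m)),
                      spectrum.geometry) for m in vis]
    if len(set(np.round(centres, 6))) < len(vis):
        raise ValueError("coincident recoil peaks: design matrix singular")

    wt = 1.0 / spectrum.errors if spectrum.errors is not None else np.ones_like(spectrum.counts)

    def residuals(logw):
        widths = dict(zip(vis, np.exp(logw)))
        intens, base, _ = solve_intensities(spectrum, vis, widths)
        model = np.full_like(spectrum.tof, base)
        for m, I in zip(vis, intens):
            model = model + I * peak_profile(spectrum.tof, spectrum.geometry, m, widths[m])
        return (spectrum.counts - model) * wt

    x0 = np.log([max(init_widths[m], width_bounds[0] * 1.01) for m in vis])
    lo = np.full(len(vis), np.log(width_bounds[0]))
    hi = np.full(len(vis), np.log(width_bounds[1]))
    sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                        method="trf", xtol=1e-10, ftol=1e-10, diff_step=1e-4)
    widths = dict(zip(vis, np.exp(sol.x)))
    intens, base, chi2 = solve_intensities(spectrum, vis, widths)

    # width covariance from the outer Jacobian (log-widths), delta-method
    dof = max(spectrum.tof.size - (2 * len(vis) + 1), 1)
    scale = chi2 / dof if spectrum.errors is None else 1.0
    try:
        cov_log = np.linalg.pinv(sol.jac.T @ sol.jac) * scale
        werr = {m: float(widths[m] * np.sqrt(max(cov_log[i, i], 0.0)))
                for i, m in enumerate(vis)}
    except np.linalg.LinAlgError:
        werr = {m: np.nan for m in vis}
    return DetectorFit(geometry=spectrum.geometry, masses=list(vis),
                       widths=widths, width_errors=werr,
                       intensities=dict(zip(vis, intens)), baseline=base,
                       chi2=chi2, converged=bool(sol.success))


def aggregate_detectors(
    spectra: Sequence[NCSSpectrum],
    masses: Sequence[float],
    init_widths: dict[float, float],
    n_iterations: int = 10,
    tol: float = 1e-4,
) -> NMDResult:
    """Self-consistent iterative aggregation of detector-by-detector fits.

    Each iteration fits every detector (variable projection), then updates
    the global widths as the inverse-variance-weighted average over
    detectors; iteration stops when the widths change by less than ``tol``
    (relative) or after ``n_iterations``.  Relative intensities are
    averaged per mass over the detectors where the mass is visible and
    renormalized to sum to 1.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 detectors")
    widths = dict(init_widths)
    fits: list[DetectorFit] = []
    converged = False
    it = 0
    for it in range(1, n_iterations + 1):
        fits = [varpro_fit_detector(sp, masses, widths) for sp in spectra]
        new_widths: dict[float, float] = {}
        for m in masses:
            vals, wts = [], []
            for f in fits:
                if m in f.widths:
                    err = f.width_errors.get(m, np.nan)
                    w = 1.0 / err**2 if np.isfinite(err) and err > 0 else 1.0
                    vals.append(f.widths[m])
                    wts.append(w)
            if vals:
                new_widths[m] = float(np.average(vals, weights=wts))
        rel_change = max(
            abs(new_widths[m] - widths.get(m, new_widths[m])) / new_widths[m]
            for m in new_widths
        )
        widths.update(new_widths)
        if rel_change < tol:
            converged = True
            break

    width_errs: dict[float, float] = {}
    rel_int: dict[float, float] = {}
    int_err: dict[float, float] = {}
    for m in masses:
        errs = [f.width_errors[m] for f in fits if m in f.width_errors
                and np.isfinite(f.width_errors[m]) and f.width_errors[m] > 0]
        if errs:
            width_errs[m] = float(1.0 / np.sqrt(np.sum(1.0 / np.asarray(errs) ** 2)))
        else:
            width_errs[m] = np.nan
        # average absolute peak intensities over the detectors where the
        # mass is kinematically visible, then normalize across masses; this
        # keeps forward-only (hydrogen) and all-detector masses comparable
        vals = [f.intensities[m] for f in fits if m in f.intensities]
        rel_int[m] = float(np.mean(vals)) if vals else 0.0
        int_err[m] = float(np.std(vals) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    tot = sum(rel_int.values())
    rel_int = {m: v / tot for m, v in rel_int.items()}
    int_err = {m: e / tot for m, e in int_err.items()}

    temp = float(np.nanmean([sp.temperature for sp in spectra]))
    return NMDResult(masses=list(masses), widths={m: widths[m] for m in widths},
                     width_errors=width_errs, relative_intensities=rel_int,
                     intensity_errors=int_err, converged=converged,
                     n_iterations=it, temperature=temp)


def compare_widths_to_afga(results: Sequence[NMDResult], model: AFGAModel):
    """Tabulate fitted hydrogen NMD width against the AFGA harmonic
    prediction per temperature: rows of (T, sigma_exp, sigma_model, delta)."""
    rows = []
    for res in results:
        if 1 not in res.widths and 1.0 not in res.widths:
            raise ValueError("no hydrogen width in NMD result")
        s_exp = res.widths.get(1, res.widths.get(1.0))
        s_mod = hydrogen_nmd_width(model, res.temperature)
        rows.append((res.temperature, s_exp, s_mod, s_exp - s_mod))
    return rows
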