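"""Synthetic-data generators for every pipeline input.

Each generator draws from the forward model the corresponding analysis
stage assumes, with known ground-truth parameters and seeded noise, so
that every downstream fit is testable by parameter recovery:

* FIDs from the two relaxation models at the standard acquisition grid
  (2048 points, 0.9 us dwell), additive Gaussian noise;
* Tg-vs-water datasets from the Gordon-Taylor equation;
* neutron transmission curves T(E) = exp(-n d sigma_tot(E)) from the AFGA
  cross-section model and a density schedule that drops sigmoidally from
  the glassy (1.3 g/cm^3) to the rubbery (1.1 g/cm^3) plateau across the
  transition;
* diffraction patterns = aluminium-container Bragg peaks (fcc,
  temperature-independent) + flat incoherent background proportional to
  the sample density;
* NCS TOF spectra as kinematically-placed Gaussian recoil peaks with
  intensities proportional to atom count x free cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import AL_LATTICE_A, AVOGADRO, MASS_RATIO, SIGMA_BOUND
from .afga import (
    AFGAModel,
    Stoichiometry,
    free_cross_section,
    total_sigma,
)
from .compton import (
    DetectorGeometry,
    NCSSpectrum,
    peak_profile,
    visible_masses,
    MASS_TO_ELEMENT,
)
from .gordon_taylor import GTParams, gt_tg
from .relaxometry import FIDSignal, RelaxParams, eval_model

__all__ = [
    "DensitySchedule",
    "AcquisitionSettings",
    "TransmissionCurve",
    "DiffractionPattern",
    "gen_fid",
    "gen_dsc_dataset",
    "density_at",
    "gen_transmission",
    "gen_diffraction",
    "gen_ncs_spectra",
    "al_bragg_dspacings",
    "DEFAULT_RELAX_TRUTH",
    "DEFAULT_SCHEDULE",
    "STUDY_TEMPERATURES",
]

#: temperature grid of the neutron measurement series, deg C
STUDY_TEMPERATURES = (-20.0, 0.0, 20.0, 40.0, 60.0, 80.0)

#: ground-truth FID parameters at 25 deg C: Abragam amplitude 0.13 of the
#: total signal; the remaining values are module defaults (documented in
#: docs/methods.md) chosen as typical low-moisture carbohydrate values —
#: a strongly dipolar-coupled semi-crystalline fraction (fast Abragam with
#: a resolved beat, b*T2s* = 8) distinct from the slower amorphous
#: Gaussian, which keeps the two solid components separable in a fit.
DEFAULT_RELAX_TRUTH = RelaxParams(
    Sg=0.50, T2g_star=20.0, Ss=0.13, T2s_star=16.0, b=0.5, L=0.37, T2L_star=400.0,
)


@dataclass(frozen=True)
class DensitySchedule:
    """Sigmoidal glass->rubber density drop vs temperature.

    rho(T) = rho_rubber + (rho_glass - rho_rubber)/(1 + exp((T - t_mid)/width)).
    Monotone non-increasing; endpoints are the glassy and rubbery plateau
    densities.
    """

    temperatures: tuple[float, ...] = STUDY_TEMPERATURES
    rho_glass: float = 1.3
    rho_rubber: float = 1.1
    t_mid: float = 50.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if not self.rho_glass > self.rho_rubber > 0:
            raise ValueError("need rho_glass > rho_rubber > 0")
        if self.width <= 0:
            raise ValueError("width must be positive")


DEFAULT_SCHEDULE = DensitySchedule()


def density_at(schedule: DensitySchedule, T: float):
    """Density (g/cm^3) of the schedule at temperature T (deg C)."""
    T = np.asarray(T, float)
    out = schedule.rho_rubber + (schedule.rho_glass - schedule.rho_rubber) / (
        1.0 + np.exp((T - schedule.t_mid) / schedule.width)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AcquisitionSettings:
    """FID acquisition grid and noise: 2048 points every 0.9 us by default."""

    n_points: int = 2048
    dwell: float = 0.9
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell


def gen_fid(params: RelaxParams, model_id: int, acq: AcquisitionSettings,
            temperature: float = np.nan) -> FIDSignal:
    """Noisy FID from model 1 or 2 on the acquisition grid; seed-reproducible."""
    if model_id == 1 and params.Sg > 0:
        raise ValueError("model 1 has no Gaussian component but Sg > 0")
    t = acq.times
    clean = eval_model(model_id, params, t)
    rng = np.random.default_rng(acq.seed)
    noise = rng.normal(0.0, acq.noise_sd, size=t.size) if acq.noise_sd > 0 else 0.0
    sigma = np.full(t.size, acq.noise_sd) if acq.noise_sd > 0 else None
    return FIDSignal(times=t, amplitudes=clean + noise, sigma=sigma,
                     temperature=temperature)


def gen_dsc_dataset(gt: GTParams, water_fractions: Sequence[float],
                    noise_sd: float, seed: int) -> list[tuple[float, float]]:
    """(Xw, Tg) pairs from the Gordon-Taylor model plus Gaussian noise on Tg."""
    xw = np.asarray(water_fractions, float)
    if np.any(xw < 0) or np.any(xw >= 1):
        raise ValueError("water fractions must lie in [0, 1)")
    tg = np.atleast_1d(gt_tg(xw, gt))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        tg = tg + rng.normal(0.0, noise_sd, size=xw.size)
    return list(zip(xw.tolist(), tg.tolist()))


@dataclass
class TransmissionCurve:
    """Energy-dependent transmission fraction with provenance metadata."""

    energies: np.ndarray        # eV
    transmission: np.ndarray    # fraction in (0, 1]
    temperature: float
    thickness: float            # cm
    errors: Optional[np.ndarray] = None
    clipped: bool = False

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, float)
        self.transmission = np.asarray(self.transmission, float)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.transmission <= 0):
            raise ValueError("transmission must be strictly positive")


def number_density(rho: float, molar_mass: float) -> float:
    """Formula units per cm^3 from mass density and formula-unit molar mass."""
    return rho * AVOGADRO / molar_mass


def gen_transmission(
    stoich: Stoichiometry,
    afga: AFGAModel,
    rho: float,
    thickness: float,
    E_grid: Sequence[float],
    noise_sd: float,
    seed: int,
    temperature: float = 20.0,
) -> TransmissionCurve:
    """T(E) = exp(-n_fu d sigma_tot(E, T)) + Gaussian noise, clipped to (0, 1].

    ``noise_sd`` is an absolute transmission-fraction standard deviation.
    Clipping of non-physical values after noise is flagged in metadata.
    """
    E = np.asarray(E_grid, float)
    if rho <= 0 or thickness <= 0:
        raise ValueError("rho and thickness must be positive")
    if np.any(E < 1e-3) or np.any(E > 1000.0):
        raise ValueError("energy grid must lie within [1e-3, 1000] eV")
    curve = total_sigma(E, afga, temperature)
    nd = number_density(rho, stoich.molar_mass) * thickness * 1e-24  # 1/barn
    clean = np.exp(-nd * curve.sigma_total)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0.0, noise_sd, size=E.size) if noise_sd > 0 else 0.0)
    clipped = bool(np.any(noisy <= 0) or np.any(noisy > 1))
    noisy = np.clip(noisy, 1e-12, 1.0)
    err = np.full(E.size, noise_sd) if noise_sd > 0 else None
    return TransmissionCurve(energies=E, transmission=noisy, temperature=temperature,
                             thickness=thickness, errors=err, clipped=clipped)


def al_bragg_dspacings(a: float = AL_LATTICE_A, d_min: float = 0.7) -> list[tuple[tuple[int, int, int], float]]:
    """Allowed fcc reflections (h,k,l all even or all odd) with d >= d_min."""
    seen = {}
    for h in range(0, 8):
        for k in range(0, 8):
            for l in range(0, 8):
                if h == k == l == 0:
                    continue
                parities = {h % 2, k % 2, l % 2}
                if len(parities) != 1:
                    continue
                s = h * h + k * k + l * l
                d = a / np.sqrt(s)
                if d < d_min:
                    continue
                if s not in seen:
                    seen[s] = (tuple(sorted((h, k, l), reverse=True)), d)
    return sorted(seen.values(), key=lambda x: -x[1])


@dataclass
class DiffractionPattern:
    d_spacings: np.ndarray   # Angstrom
    counts: np.ndarray
    temperature: float
    errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d_spacings = np.asarray(self.d_spacings, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


def gen_diffraction(
    rho: float,
    al_scale: float,
    bg_scale: float,
    d_grid: Sequence[float],
    noise_sd: float,
    seed: int,
    temperature: float = 20.0,
    al_lattice_a: float = AL_LATTICE_A,
    peak_width: float = 0.01,
) -> DiffractionPattern:
    """Aluminium-container Bragg peaks plus flat incoherent background.

    The Bragg template (Gaussian peaks at the allowed fcc d-spacings,
    intensity falling as d^2 as a crude structure/multiplicity proxy) is
    temperature-independent; the flat background is bg_scale * rho,
    proportional to the amorphous sample's number density.
    """
    d = np.asarray(d_grid, float)
    if np.any(d <= 0):
        raise ValueError("d-spacings must be positive")
    if al_scale < 0 or bg_scale < 0:
        raise ValueError("scales must be >= 0")
    pattern = np.full(d.size, bg_scale * rho)
    if al_scale > 0:
        for (_, d0) in al_bragg_dspacings(al_lattice_a, d_min=max(d.min() - 0.2, 0.5)):
            pattern = pattern + al_scale * (d0 / al_lattice_a) ** 2 * np.exp(
                -0.5 * ((d - d0) / peak_width) ** 2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        pattern = pattern + rng.normal(0.0, noise_sd, size=d.size)
    pattern = np.clip(pattern, 0.0, None)
    err = np.full(d.size, noise_sd) if noise_sd > 0 else None
    return DiffractionPattern(d_spacings=d, counts=pattern, temperature=temperature,
                              errors=err)


def gen_ncs_spectra(
    stoich: Stoichiometry,
    widths: dict[float, float],
    detectors: Sequence[DetectorGeometry],
    counts_scale: float = 1e4,
    baseline: float = 5.0,
    noise_scale: float = 0.0,
    seed: int = 0,
    temperature: float = 20.0,
    tof_grid: Optional[np.ndarray] = None,
) -> list[NCSSpectrum]:
    """Per-detector TOF spectra of kinematic recoil peaks.

    Peak integral intensity per mass is counts_scale x (atom count x free
    cross-section)/sum, i.e. proportional to stoichiometric abundance
    weighted by the free scattering cross-section.  The hydrogen peak is
    omitted at detectors where its recoil kinematics have no solution
    (theta >= 90 deg).  Noise is Gaussian with sqrt(counts) scaling
    (noise_scale multiplies sqrt(max(counts, 1))).
    """
    masses = sorted(widths)
    weights = {}
    for m in masses:
        el = MASS_TO_ELEMENT[int(round(m))]
        n = getattr(stoich, el)
        weights[m] = n * free_cross_section(SIGMA_BOUND[el], MASS_RATIO[el])
    total_w = sum(weights.values())
    rng = np.random.default_rng(seed)

    spectra = []
    for i, geom in enumerate(detectors):
        grid = (np.arange(60.0, 480.0, 0.5) if tof_grid is None
                else np.asarray(tof_grid, float))
        counts = np.full(grid.size, float(baseline))
        for m in visible_masses(masses, geom):
            I = counts_scale * weights[m] / total_w
            counts = counts + I * peak_profile(grid, geom, m, widths[m])
        err = None
        if noise_scale > 0:
            err = noise_scale * np.sqrt(np.maximum(counts, 1.0))
            counts = counts + rng.normal(0.0, 1.0, size=grid.size) * err
        spectra.append(NCSSpectrum(tof=grid, counts=counts, geometry=geom,
                                   errors=err, temperature=temperature))
    return spectra
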