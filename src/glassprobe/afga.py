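"""Average Functional Group Approximation (AFGA) forward model.

The total neutron scattering cross-section of a hydrogenous amorphous
sample is modelled as an additive ("incoherent") sum of independent
functional-group contributions — CH2, CH and OH of the anhydroglucose
monomer plus the OH pairs of sorbed water — each a Doppler-broadened
free-gas cross-section evaluated at a harmonic effective temperature
derived from the group's characteristic mode energies.  The construction
preserves the features the analysis relies on: additivity over groups, the
exact stoichiometry-weighted free-atom (impulse-approximation) plateau at
epithermal energies, and a thermally sensitive meV region.

The sample stoichiometry is C6H10O5 (H2O)_nu, a glucose polymer plus nu
water molecules per monomer, with nu derived from the moisture content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .constants import (
    ATOMIC_MASS,
    CELSIUS_ZERO,
    GLUCOSE_MONOMER_MASS,
    HBAR2_OVER_MN,
    K_B_MEV,
    MASS_RATIO,
    SIGMA_BOUND,
    WATER_MASS,
)
from .gordon_taylor import MoistureValue, moisture_convert

__all__ = [
    "Stoichiometry",
    "FunctionalGroup",
    "AFGAModel",
    "CrossSectionCurve",
    "build_stoichiometry",
    "free_cross_section",
    "effective_temperature",
    "group_sigma",
    "total_sigma",
    "window_integral",
    "nmd_width",
    "default_afga_model",
    "free_sigma_per_formula_unit",
]

# Representative organic-hydrogen mode energies (meV); each set carries one
# mode per momentum direction (weights sum to 3).  Values are generic
# stretch/bend/torsion scales for the group, configurable per model.
DEFAULT_GROUP_MODES = {
    "CH2": [(360.0, 1.0), (175.0, 1.0), (90.0, 1.0)],
    "CH": [(360.0, 1.0), (160.0, 1.0), (100.0, 1.0)],
    "OH": [(420.0, 1.0), (200.0, 1.0), (80.0, 1.0)],
    "water_OH": [(420.0, 1.0), (200.0, 1.0), (80.0, 1.0)],
}


@dataclass(frozen=True)
class Stoichiometry:
    """Element counts per C6H10O5(H2O)_nu formula unit."""

    H: float
    C: float
    O: float
    Al: float = 0.0
    water_per_glucose: float = 0.0

    def __post_init__(self) -> None:
        for el in ("H", "C", "O", "Al"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    @property
    def counts(self) -> dict[str, float]:
        d = {"H": self.H, "C": self.C, "O": self.O}
        if self.Al:
            d["Al"] = self.Al
        return d

    @property
    def molar_mass(self) -> float:
        return sum(n * ATOMIC_MASS[el] for el, n in self.counts.items())


@dataclass(frozen=True)
class FunctionalGroup:
    """A hydrogen-bearing group (or heavy atom) with its mode spectrum.

    ``modes`` is a list of (energy_meV, weight) pairs; weights sum to 3
    (one per momentum direction) for a full harmonic mode set.
    """

    name: str
    hydrogen_count: int
    modes: tuple[tuple[float, float], ...]
    element: str = "H"

    def __post_init__(self) -> None:
        for e, w in self.modes:
            if e <= 0:
                raise ValueError("mode energies must be positive")
            if w < 0:
                raise ValueError("mode weights must be non-negative")


@dataclass(frozen=True)
class AFGAModel:
    """Groups with per-formula-unit multiplicities plus heavy atoms."""

    groups: tuple[tuple[FunctionalGroup, float], ...]
    stoichiometry: Stoichiometry
    #: effective temperature (K) used for heavy atoms; None -> classical (T)
    heavy_modes: tuple[tuple[float, float], ...] = ((30.0, 3.0),)

    def __post_init__(self) -> None:
        n_h = sum(g.hydrogen_count * mult for g, mult in self.groups
                  if g.element == "H")
        if abs(n_h - self.stoichiometry.H) > 1e-6:
            raise ValueError(
                f"group hydrogen count {n_h} != stoichiometric {self.stoichiometry.H}")


@dataclass
class CrossSectionCurve:
    """Total cross-section per formula unit (barns) vs incident energy (eV)."""

    energies: np.ndarray
    sigma_total: np.ndarray
    temperature: float
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, float)
        self.sigma_total = np.asarray(self.sigma_total, float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, float)


def build_stoichiometry(moisture: MoistureValue, include_al: float = 0.0) -> Stoichiometry:
    """C6H10O5(H2O)_nu from a moisture content.

    nu = (g water per g dry matter) x M(C6H10O5)/M(H2O); wet-basis inputs
    are converted first.  Element counts: H = 10 + 2 nu, C = 6, O = 5 + nu.
    """
    dm = moisture_convert(moisture, "dry_matter").value
    nu = dm * GLUCOSE_MONOMER_MASS / WATER_MASS
    return Stoichiometry(H=10.0 + 2.0 * nu, C=6.0, O=5.0 + nu,
                         Al=include_al, water_per_glucose=nu)


def free_cross_section(sigma_bound: float, A: float) -> float:
    """Free-atom cross-section sigma_b * (A/(A+1))^2 for mass ratio A."""
    if A <= 0:
        raise ValueError("mass ratio must be positive")
    return sigma_bound * (A / (A + 1.0)) ** 2


def free_sigma_per_formula_unit(stoich: Stoichiometry) -> float:
    """Stoichiometry-weighted free cross-section, barns per formula unit."""
    return sum(
        n * free_cross_section(SIGMA_BOUND[el], MASS_RATIO[el])
        for el, n in stoich.counts.items()
    )


def effective_temperature(modes: Sequence[tuple[float, float]], T_kelvin: float) -> float:
    """Harmonic effective temperature, K.

    T* = <(hw/2kB) coth(hw/2kBT)> over modes (weighted mean).  Classical
    limit T* -> T for hw << kBT; zero-point limit T* -> hw/2kB for T -> 0.
    """
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive (K)")
    e = np.array([m[0] for m in modes], float)
    w = np.array([m[1] for m in modes], float)
    x = e / (2.0 * K_B_MEV * T_kelvin)
    tstar_modes = (e / (2.0 * K_B_MEV)) / np.tanh(x)
    return float(np.sum(w * tstar_modes) / np.sum(w))


def _free_gas_sigma(E_ev, sigma_free: float, A: float, tstar_kelvin: float):
    """Doppler-broadened free-gas total cross-section at effective temperature.

    sigma(E) = sigma_free * [(1 + 1/(2x^2)) erf(x) + exp(-x^2)/(x sqrt(pi))],
    x^2 = A E / (kB T*).  Tends to sigma_free for x >> 1 and to the 1/v law
    for x << 1.
    """
    E_mev = np.asarray(E_ev, float) * 1000.0
    x2 = A * E_mev / (K_B_MEV * tstar_kelvin)
    x = np.sqrt(x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sigma_free * ((1.0 + 0.5 / x2) * erf(x)
                            + np.exp(-x2) / (x * np.sqrt(np.pi)))
    return out


def group_sigma(E_ev, group: FunctionalGroup, T_celsius: float):
    """Cross-section (barns) of one group at incident energy E (eV), per
    formula-unit multiplicity of 1 (hydrogen_count hydrogens)."""
    E_ev = np.asarray(E_ev, float)
    if np.any(E_ev <= 0):
        raise ValueError("incident energy must be positive")
    el = group.element
    tstar = effective_temperature(group.modes, T_celsius + CELSIUS_ZERO)
    sfree = free_cross_section(SIGMA_BOUND[el], MASS_RATIO[el])
    out = group.hydrogen_count * _free_gas_sigma(E_ev, sfree, MASS_RATIO[el], tstar)
    return float(out) if out.ndim == 0 else out


def default_afga_model(stoich: Stoichiometry,
                       modes: dict | None = None) -> AFGAModel:
    """Glucose-polymer + water group decomposition.

    Per monomer: 1 CH2 (2 H), 5 CH (5 H: ring CH plus anomeric), 3 OH
    (3 H), and nu water_OH pairs (2 H each).  Total H = 10 + 2 nu, matching
    the stoichiometry by construction.
    """
    m = dict(DEFAULT_GROUP_MODES)
    if modes:
        m.update(modes)
    nu = stoich.water_per_glucose
    groups = (
        (FunctionalGroup("CH2", 2, tuple(m["CH2"])), 1.0),
        (FunctionalGroup("CH", 1, tuple(m["CH"])), 5.0),
        (FunctionalGroup("OH", 1, tuple(m["OH"])), 3.0),
        (FunctionalGroup("water_OH", 2, tuple(m["water_OH"])), nu),
    )
    return AFGAModel(groups=groups, stoichiometry=stoich)


def total_sigma(E_grid, model: AFGAModel, T_celsius: float) -> CrossSectionCurve:
    """Stoichiometry-weighted total cross-section curve, barns per formula unit.

    Hydrogen groups use their harmonic effective temperatures; heavy atoms
    (C, O, Al) use the low-energy lattice mode set of the model.  The
    epithermal limit is exactly the stoichiometric free-atom sum.
    """
    E = np.asarray(E_grid, float)
    sig = np.zeros_like(E)
    for g, mult in model.groups:
        sig = sig + mult * group_sigma(E, g, T_celsius)
    t_kelvin = T_celsius + CELSIUS_ZERO
    tstar_heavy = effective_temperature(model.heavy_modes, t_kelvin)
    for el in ("C", "O", "Al"):
        n = getattr(model.stoichiometry, el)
        if n > 0:
            sfree = free_cross_section(SIGMA_BOUND[el], MASS_RATIO[el])
            sig = sig + n * _free_gas_sigma(E, sfree, MASS_RATIO[el],
                                            max(tstar_heavy, t_kelvin))
    return CrossSectionCurve(energies=E, sigma_total=sig, temperature=T_celsius)


def window_integral(curve: CrossSectionCurve, lo_mev: float = 2.6,
                    hi_mev: float = 10.0) -> float:
    """Trapezoidal integral of sigma_total over [lo, hi] meV (barns*meV).

    The grid must cover the window; a warning-level check requires mean
    spacing below one tenth of the window width.
    """
    lo, hi = lo_mev * 1e-3, hi_mev * 1e-3  # eV
    E, S = curve.energies, curve.sigma_total
    if E[0] > lo or E[-1] < hi:
        raise ValueError("energy grid does not cover the integration window")
    sel = (E >= lo) & (E <= hi)
    Ew = np.concatenate(([lo], E[sel], [hi]))
    Sw = np.concatenate(([np.interp(lo, E, S)], S[sel], [np.interp(hi, E, S)]))
    Ew, idx = np.unique(Ew, return_index=True)
    Sw = Sw[idx]
    if np.diff(Ew).max() > (hi - lo) / 10.0:
        import warnings
        warnings.warn("energy grid coarser than window/10 inside the integral")
    return float(np.trapezoid(Sw, Ew) * 1000.0)  # barns * meV


def nmd_width(modes: Sequence[tuple[float, float]], T_celsius: float,
              mass_ratio: float) -> float:
    """Harmonic nuclear-momentum-distribution width sigma_y (1/Angstrom).

    sigma_y^2 = (1/3) sum_i w_i * (A hw_i / (2 hbar^2/m_n)) coth(hw_i/2kBT).
    In the classical limit this reduces to the Maxwell-Boltzmann width
    sigma_y^2 = A kB T / (hbar^2/m_n).
    """
    t_kelvin = T_celsius + CELSIUS_ZERO
    if t_kelvin <= 0:
        raise ValueError("temperature below absolute zero")
    e = np.array([m[0] for m in modes], float)
    w = np.array([m[1] for m in modes], float)
    coth = 1.0 / np.tanh(e / (2.0 * K_B_MEV * t_kelvin))
    sig2 = np.sum(w * mass_ratio * e * coth / (2.0 * HBAR2_OVER_MN)) / 3.0
    return float(np.sqrt(sig2))


def hydrogen_nmd_width(model: AFGAModel, T_celsius: float) -> float:
    """Hydrogen NMD width predicted by the AFGA model: hydrogen-weighted
    mean of sigma_y^2 over the hydrogen-bearing groups."""
    num, den = 0.0, 0.0
    for g, mult in model.groups:
        if g.element != "H" or mult == 0:
            continue
        nh = g.hydrogen_count * mult
        s = nmd_width(g.modes, T_celsius, MASS_RATIO["H"])
        num += nh * s**2
        den += nh
    if den == 0:
        raise ValueError("model has no hydrogen")
    return float(np.sqrt(num / den))
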