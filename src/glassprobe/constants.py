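"""Physical constants and nuclear data used across the package.

Neutron cross-sections are the standard tabulated bound values (barns);
mass ratios ``A`` are nuclide masses divided by the neutron mass, which is
the quantity entering free-atom kinematics and the free-gas cross-section.
Molar masses use standard atomic weights.
"""

# Atomic weights, g/mol
ATOMIC_MASS = {
    "H": 1.00794,
    "C": 12.0107,
    "O": 15.9994,
    "Al": 26.98154,
}

# Nuclide mass / neutron mass (p, 12C, 16O, 27Al over m_n = 1.0086649 u)
MASS_RATIO = {
    "H": 1.0072765 / 1.0086649,
    "C": 12.0 / 1.0086649,
    "O": 15.9949146 / 1.0086649,
    "Al": 26.9815385 / 1.0086649,
}

# Bound total scattering cross-sections, barns
SIGMA_BOUND = {
    "H": 82.02,
    "C": 5.551,
    "O": 4.232,
    "Al": 1.503,
}

#: Boltzmann constant, meV per kelvin
K_B_MEV = 0.08617333

#: hbar^2 / m_n, meV * Angstrom^2 (so hbar^2 k^2 / 2 m_n = 2.0717 k^2 meV)
HBAR2_OVER_MN = 4.1434
HBAR2_OVER_2MN = HBAR2_OVER_MN / 2.0

#: neutron speed in m/s for 1 meV kinetic energy: v = 437.39 * sqrt(E[meV])
NEUTRON_VELOCITY_CONST = 437.39

AVOGADRO = 6.02214076e23
BARN_CM2 = 1e-24

#: fcc aluminium lattice constant, Angstrom (standard value)
AL_LATTICE_A = 4.0495

#: anhydroglucose monomer C6H10O5 and water molar masses, g/mol
GLUCOSE_MONOMER_MASS = 162.14
WATER_MASS = 18.02

CELSIUS_ZERO = 273.15
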