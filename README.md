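# glassprobe

Multi-probe detection of the glass transition in a low-moisture
biopolymer — the kind of dry, water-plasticized starch system (e.g. dried
rice pasta) whose glassy-to-rubbery transition is notoriously
technique-dependent.  `glassprobe` implements, on a common synthetic-data
backbone, the full analysis chain such a concurrent NMR + neutron study
needs, so that every stage is testable by parameter recovery against known
ground truth:

* **Time-domain NMR relaxometry.** Free induction decays are decomposed
  into an Abragam component `Ss·exp(−(t/T2s*)²)·sin(bt)/(bt)` for
  strongly dipolar-coupled (semi-crystalline) protons, an optional
  Gaussian `Sg·exp(−(t/T2g*)²)` for the amorphous rigid fraction, and an
  exponential `L·exp(−t/T2L*)` for mobile protons.  Second moments
  `M2 = 2/T2s*² + b²/3` and amplitude fractions follow.
* **Bayesian model selection.** A Metropolis chain samples the likelihood
  `exp(−χ²/2)` of each candidate model, returning parameters as
  probability distributions and χ² distributions; models are compared by
  minimal χ² (ties go to fewer parameters).
* **Gordon–Taylor plasticization.** `Tg(Xw) = (Xs·Tgs + k·Xw·Tgw)/(Xs + k·Xw)`
  fitted by Levenberg–Marquardt with the pure-water `Tgw` fixed at
  −135 °C, plus moisture-basis and proximate-composition arithmetic.
* **Neutron densitometry.** The epithermal transmission plateau measures
  the scattering power `s = n·d·Σ_free`; the flat incoherent diffraction
  background (away from the aluminium-container Bragg peaks) is
  proportional to number density.  Both estimators are calibrated at the
  lowest temperature and bracket the density drop across the transition.
* **AFGA cross-sections.** The total neutron cross-section of
  C₆H₁₀O₅(H₂O)₁.₁ is an additive sum of functional-group contributions
  (CH₂, CH, OH, water OH), each a Doppler-broadened free-gas curve at a
  harmonic effective temperature, with the exact stoichiometry-weighted
  free-atom plateau and harmonic nuclear-momentum-distribution (NMD)
  width predictions.
* **Neutron Compton scattering.** Inverse-geometry recoil kinematics,
  y-scaling, and the partitioned variable-projection fit: peak centres
  fixed by kinematics, intensities solved as a non-negative linear
  least-squares subproblem, widths searched nonlinearly, aggregated
  detector-by-detector with inverse-variance iteration.

## Worked example

```bash
python examples/density_from_neutrons.py
```

```
T (degC)   rho_transmission   rho_diffraction   truth
    -20             1.3000            1.3000   1.3000
      0             1.2984            1.3008   1.3000
     20             1.2949            1.2998   1.2995
     40             1.2807            1.2760   1.2762
     60             1.1209            1.1246   1.1238
     80             1.1023            1.1009   1.1005
transition window (transmission): (40.0, 60.0) degC
transition window (diffraction):  (40.0, 60.0) degC
```

Synthetic transmission and diffraction series are generated from a
sigmoidal density schedule (1.3 → 1.1 g/cm³, midpoint 50 °C) with 0.5 %
noise; the two independent calibrated estimators recover the schedule to
a few 10⁻³ g/cm³ and both bracket the transition between the measured
temperatures 40 and 60 °C.  The other scripts in `examples/` demonstrate
FID fitting with χ²-MCMC model selection, the Gordon–Taylor fit, the AFGA
forward model, NCS width fitting, and the consolidated pipeline
(`glassprobe report` on the command line).

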