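"""Fit the two FID relaxation models and let the chi^2 MCMC choose.

Generates one noisy free induction decay of a low-moisture starch system
(two solid proton components plus a mobile exponential), fits both
candidate models by bounded least squares, then explores each chi^2
landscape with a Metropolis chain and compares minimal chi^2 values.
"""

from glassprobe.bayes import model_compare, run_mcmc
from glassprobe.pipeline import _mcmc_bounds
from glassprobe.relaxometry import fit_fid, solid_fractions
from glassprobe.synthetic import AcquisitionSettings, DEFAULT_RELAX_TRUTH, gen_fid

acq = AcquisitionSettings(noise_sd=0.005, seed=42)  # 0.5% of total amplitude
signal = gen_fid(DEFAULT_RELAX_TRUTH, 2, acq, temperature=25.0)

fit1 = fit_fid(signal, 1)  # Abragam + exponential
fit2 = fit_fid(signal, 2)  # Gaussian + Abragam + exponential
print(f"least-squares chi2:  model 1 = {fit1.chi2_min:.1f},  model 2 = {fit2.chi2_min:.1f}")

chain1 = run_mcmc(signal, 1, fit1.params, _mcmc_bounds(fit1.params, 1), steps=4000, seed=0)
chain2 = run_mcmc(signal, 2, fit2.params, _mcmc_bounds(fit2.params, 2), steps=4000, seed=1)
report = model_compare(chain1, chain2)
print(f"chain chi2_min:      model 1 = {report.chi2_min[1]:.1f},  model 2 = {report.chi2_min[2]:.1f}")
print(f"selected model:      {report.selected_model}")

ss, sg, liq = solid_fractions(fit2.params)
print(f"amplitude fractions: Abragam {ss:.3f}, Gaussian {sg:.3f}, mobile {liq:.3f}")
print("(the Abragam fraction tracks the semi-crystalline proton share; "
      "0.13 is the generating truth)")
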