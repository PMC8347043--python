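"""Bayesian chi-square landscape exploration and model selection.

A Metropolis Markov chain samples the likelihood exp(-chi^2/2) of a
relaxation model given a FID, with Gaussian proposals and rejection of
out-of-bounds moves.  Unlike point minimization this returns parameters as
probability distributions and the full chi^2 distribution of each model,
so competing models can be compared by their minimal (or most probable)
chi^2 rather than a single local optimum.  Proposal scales are adapted
during burn-in only, so the post-burn-in chain is a fixed-kernel
Metropolis sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .relaxometry import (
    FIDSignal,
    PARAM_NAMES,
    RelaxParams,
    chi_square,
    eval_model,
)

__all__ = ["Chain", "SelectionReport", "chi2", "run_mcmc", "model_compare", "marginal_pdf"]


def chi2(signal: FIDSignal, model_id: int, params: RelaxParams) -> float:
    """chi^2 = sum(((y_i - F(t_i))/sigma_i)^2), unit sigma if absent."""
    return chi_square(signal, model_id, params)


@dataclass
class Chain:
    """A Metropolis chain over model parameters with its chi^2 trace."""

    samples: np.ndarray          # (steps, n_params), post burn-in included
    chi2_values: np.ndarray
    acceptance_rate: float
    seed: int
    burn_in: int
    param_names: tuple[str, ...]
    model_id: int
    data_hash: str = ""

    def __post_init__(self) -> None:
        if np.any(self.chi2_values < 0):
            raise ValueError("chi2 values cannot be negative")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance rate must lie in [0, 1]")

    @property
    def chi2_min(self) -> float:
        return float(self.chi2_values.min())

    @property
    def best_params(self) -> np.ndarray:
        return self.samples[int(np.argmin(self.chi2_values))]

    def posterior(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    def chi2_mode(self, bins: int = 50) -> float:
        """Histogram mode of the post-burn-in chi^2 distribution."""
        c = self.chi2_values[self.burn_in:]
        hist, edges = np.histogram(c, bins=bins)
        i = int(np.argmax(hist))
        return float(0.5 * (edges[i] + edges[i + 1]))


def _hash_data(signal: FIDSignal) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(signal.times).tobytes())
    h.update(np.ascontiguousarray(signal.amplitudes).tobytes())
    return h.hexdigest()[:16]


def run_mcmc(
    signal: FIDSignal,
    model_id: int,
    init: RelaxParams,
    bounds: dict[str, tuple[float, float]],
    steps: int = 50_000,
    proposal_sd: Optional[dict[str, float]] = None,
    seed: int = 0,
    burn_in_frac: float = 0.2,
    chi2_fn: Optional[Callable[[np.ndarray], float]] = None,
) -> Chain:
    """Metropolis sampling of exp(-chi^2/2) with Gaussian proposals.

    Acceptance probability is min(1, exp(-delta_chi2/2)); proposals outside
    the per-parameter bounds are rejected outright.  Default proposal SD is
    2% of each parameter's bound range, scaled adaptively (toward ~30%
    acceptance) during burn-in only.  The chain is reproducible bit-for-bit
    from the seed.  ``chi2_fn`` overrides the FID chi^2 for generic
    problems (e.g. calibration on a linear model).
    """
    names = PARAM_NAMES[model_id]
    burn_in = int(steps * burn_in_frac)
    if steps <= burn_in:
        raise ValueError("steps must exceed burn-in")
    lo = np.array([bounds[n][0] for n in names], float)
    hi = np.array([bounds[n][1] for n in names], float)
    x = np.clip(init.as_array(model_id), lo, hi)

    if chi2_fn is None:
        def chi2_fn(theta):
            return chi_square(signal, model_id, RelaxParams.from_array(theta, model_id))

    sd = np.array(
        [proposal_sd[n] if proposal_sd and n in proposal_sd else 0.02 * (bounds[n][1] - bounds[n][0])
         for n in names], float)

    rng = np.random.default_rng(seed)
    n = len(names)
    samples = np.empty((steps, n))
    chi2s = np.empty(steps)
    c = chi2_fn(x)
    accepted = 0
    window_accept = 0
    for i in range(steps):
        prop = x + rng.normal(0.0, sd, size=n)
        if np.all(prop >= lo) & np.all(prop <= hi):
            c_prop = chi2_fn(prop)
            if c_prop <= c or rng.random() < np.exp(-(c_prop - c) / 2.0):
                x, c = prop, c_prop
                accepted += 1
                window_accept += 1
        samples[i] = x
        chi2s[i] = c
        # adapt proposal scale during burn-in only, every 100 steps,
        # steering toward ~30% acceptance; the post-burn-in kernel is fixed
        if i < burn_in and (i + 1) % 100 == 0:
            rate = window_accept / 100.0
            # a dead window means the scale is far too coarse; halve it
            sd *= 0.5 if rate == 0.0 else np.exp(rate - 0.3)
            window_accept = 0

    rate = accepted / steps
    if rate == 0.0:
        warnings.warn(
            "MCMC accepted no proposals; reduce proposal_sd (default 2% of "
            "bound range) or widen bounds")
    return Chain(samples=samples, chi2_values=chi2s, acceptance_rate=rate,
                 seed=seed, burn_in=burn_in, param_names=tuple(names),
                 model_id=model_id, data_hash=_hash_data(signal))


@dataclass
class SelectionReport:
    chi2_min: dict[int, float]
    chi2_mode: dict[int, float]
    selected_model: int
    n_params: dict[int, int]


def model_compare(chain_1: Chain, chain_2: Chain) -> SelectionReport:
    """Select between two models fitted to the same data.

    Smaller chi^2_min wins; exact ties go to the model with fewer
    parameters.  The chi^2 histogram mode is reported alongside.  Chains
    from different data are rejected.
    """
    if chain_1.data_hash and chain_2.data_hash and chain_1.data_hash != chain_2.data_hash:
        raise ValueError("chains were run on different data")
    chains = {chain_1.model_id: chain_1, chain_2.model_id: chain_2}
    cmin = {m: ch.chi2_min for m, ch in chains.items()}
    cmode = {m: ch.chi2_mode() for m, ch in chains.items()}
    npar = {m: len(ch.param_names) for m, ch in chains.items()}
    models = sorted(chains)
    a, b = models[0], models[-1]
    if cmin[a] == cmin[b]:
        selected = a if npar[a] <= npar[b] else b
    else:
        selected = a if cmin[a] < cmin[b] else b
    return SelectionReport(chi2_min=cmin, chi2_mode=cmode,
                           selected_model=selected, n_params=npar)


def marginal_pdf(chain: Chain, parameter: str, bins: int = 50):
    """Post-burn-in marginal histogram of one parameter.

    Returns (bin_edges, density) with the histogram normalized so that the
    probability mass (density x bin width) sums to 1.
    """
    if parameter not in chain.param_names:
        raise ValueError(f"unknown parameter {parameter!r}")
    post = chain.posterior()
    if post.shape[0] == 0:
        raise ValueError("empty post-burn-in chain")
    col = post[:, chain.param_names.index(parameter)]
    if np.ptp(col) == 0:
        edges = np.array([col[0] - 0.5, col[0] + 0.5])
        return edges, np.array([1.0])
    hist, edges = np.histogram(col, bins=bins, density=True)
    return edges, hist
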