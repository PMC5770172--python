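"""Tempered sequential Monte Carlo over the forward map.

Samples parameter vectors theta from the sequence of distributions
h(theta) proportional to p(M(theta))^gamma, gamma ramped from 0 (uniform over
the bounded search box) to 1, by iterating importance reweighting, systematic
resampling, and independence Metropolis-Hastings moves whose jumping
distribution is a Gaussian mixture fitted to the current (regularized)
particle locations.

The forward map is any callable mapping an (n, d) array of parameter vectors
to an (n, k) biomarker array plus a boolean validity mask; models that fail
to produce an acceptable AP carry density zero and can never be accepted once
gamma > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from sklearn.mixture import GaussianMixture

from .density import DensityEstimate

ForwardFn = Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray]]


class DegenerateEnsembleError(RuntimeError):
    def __init__(self, message, gamma=None):
        super().__init__(message)
        self.gamma = gamma


@dataclass
class ParticleEnsemble:
    """Weighted particles with cached forward outputs and log target values."""

    theta: np.ndarray        # (N, d)
    outputs: np.ndarray      # (N, k) cached biomarkers (transformed-space input)
    log_density: np.ndarray  # (N,) cached log p(M(theta)), -inf for invalid
    weights: np.ndarray      # (N,) nonnegative, sum to 1
    gamma: float = 0.0

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def ess(self) -> float:
        return 1.0 / float((self.weights ** 2).sum())

    def unique_fraction(self) -> float:
        return len(np.unique(self.theta, axis=0)) / self.n


@dataclass
class ProposalModel:
    """Gaussian-mixture independence proposal over theta-space."""

    gmm: GaussianMixture
    n_components: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # GaussianMixture.sample uses its own RandomState; route through rng
        # for a single seed stream.
        self.gmm.random_state = int(rng.integers(2 ** 31 - 1))
        X, _ = self.gmm.sample(n)
        return X

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        return self.gmm.score_samples(np.atleast_2d(X))


def _target_logdensity(Y: np.ndarray, valid: np.ndarray,
                       target: DensityEstimate) -> np.ndarray:
    """log p(M(theta)) for cached outputs; -inf where the model is invalid.

    Densities are evaluated in transformed biomarker space (no Jacobian):
    SMC only ever uses ratios of target values.
    """
    logp = np.full(Y.shape[0], -np.inf)
    if np.any(valid):
        Z = target.transform(Y[valid])
        logp[valid] = target.logpdf_transformed(Z)
    return logp


def initialize_particles(n: int, bounds: np.ndarray, seed,
                         forward: ForwardFn, target: DensityEstimate,
                         max_redraw_rounds: int = 200) -> ParticleEnsemble:
    """Uniform draws over the bounds, redrawing invalid forward outcomes.

    At gamma = 0 every particle is accepted by the tempered target, so dead
    (invalid-model) particles are explicitly redrawn here to keep the
    ensemble inside the support of every later tempered distribution.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be (d, 2)")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("each lower bound must be below its upper bound")
    if n < 2:
        raise ValueError("need at least 2 particles")
    rng = np.random.default_rng(seed)
    d = bounds.shape[0]
    theta = np.empty((n, d))
    outputs = None
    filled = 0
    for _ in range(max_redraw_rounds):
        need = n - filled
        if need == 0:
            break
        cand = rng.uniform(bounds[:, 0], bounds[:, 1], size=(need, d))
        Y, valid = forward(cand)
        if outputs is None:
            outputs = np.empty((n, Y.shape[1]))
        k = int(valid.sum())
        if k:
            theta[filled:filled + k] = cand[valid]
            outputs[filled:filled + k] = Y[valid]
            filled += k
    if filled < n:
        raise DegenerateEnsembleError(
            "could not draw enough valid models from the uniform prior",
            gamma=0.0)
    logp = _target_logdensity(outputs, np.ones(n, dtype=bool), target)
    return ParticleEnsemble(theta=theta, outputs=outputs, log_density=logp,
                            weights=np.full(n, 1.0 / n), gamma=0.0)


def temper_step(ens: ParticleEnsemble, ess_fraction: float = 0.5,
                tol: float = 1e-10) -> ParticleEnsemble:
    """Choose the gamma increment by bisection on the effective sample size.

    The increment delta reweights particles by p(M(theta))^delta; delta is
    chosen so the resulting ESS equals ``ess_fraction * N`` (capped so gamma
    never exceeds 1).
    """
    if ens.gamma >= 1.0:
        raise ValueError("gamma already at 1")
    logp = ens.log_density
    if np.all(np.isneginf(logp)):
        raise DegenerateEnsembleError("all particles have zero density",
                                      gamma=ens.gamma)
    target_ess = ess_fraction * ens.n
    finite = logp[np.isfinite(logp)]
    ref = finite.max()

    def weights_for(delta: float) -> np.ndarray:
        lw = np.log(ens.weights) + delta * (logp - ref)
        lw -= lw.max()
        w = np.exp(lw)
        return w / w.sum()

    def ess_at(delta: float) -> float:
        w = weights_for(delta)
        return 1.0 / float((w ** 2).sum())

    hi = 1.0 - ens.gamma
    if ess_at(hi) >= target_ess:
        delta = hi
    else:
        lo = 0.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if ess_at(mid) >= target_ess:
                lo = mid
            else:
                hi = mid
        delta = 0.5 * (lo + hi)
    return ParticleEnsemble(theta=ens.theta, outputs=ens.outputs,
                            log_density=ens.log_density,
                            weights=weights_for(delta),
                            gamma=min(ens.gamma + delta, 1.0))


def systematic_resample(weights: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: one uniform offset, N evenly spaced pointers.

    Particle i receives either floor(N w_i) or ceil(N w_i) copies.
    """
    n = len(weights)
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def resample(ens: ParticleEnsemble,
             rng: np.random.Generator) -> ParticleEnsemble:
    idx = systematic_resample(ens.weights, rng)
    return ParticleEnsemble(theta=ens.theta[idx].copy(),
                            outputs=ens.outputs[idx].copy(),
                            log_density=ens.log_density[idx].copy(),
                            weights=np.full(ens.n, 1.0 / ens.n),
                            gamma=ens.gamma)


def fit_proposal(ens: ParticleEnsemble, rng: np.random.Generator,
                 max_components: int = 5, jitter_fraction: float = 0.1,
                 reg_covar: float = 1e-6) -> ProposalModel:
    """Gaussian mixture fitted to regularized particle locations.

    Regularization: each location is jittered by 10% of the per-dimension
    ensemble standard deviation and a covariance floor is applied, so the
    mixture stays proper even when resampling has duplicated particles.
    The component count is chosen by BIC over 1..max_components.
    """
    X = ens.theta
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1e-8)
    Xj = X + rng.normal(scale=jitter_fraction * sd, size=X.shape)

    n_unique = len(np.unique(X, axis=0))
    upper = max(1, min(max_components, n_unique))
    best = None
    best_bic = np.inf
    for k in range(1, upper + 1):
        gmm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=reg_covar,
            random_state=int(rng.integers(2 ** 31 - 1)), n_init=1)
        try:
            gmm.fit(Xj)
        except ValueError:
            continue
        bic = gmm.bic(Xj)
        if bic < best_bic:
            best_bic = bic
            best = gmm
    if best is None:  # fall back to one broad Gaussian
        best = GaussianMixture(n_components=1, reg_covar=reg_covar,
                               random_state=0).fit(Xj)
    return ProposalModel(gmm=best, n_components=best.n_components)


def mh_accept_probability(p_new: float, p_old: float, gamma: float,
                          J_new: float, J_old: float) -> float:
    """Metropolis-Hastings acceptance for the independence proposal.

    min(1, (p_new/p_old)^gamma * J_old/J_new); zero when the proposed model
    is invalid (p_new = 0).
    """
    if p_old <= 0 or J_new <= 0:
        raise ValueError("p_old and J_new must be positive")
    if p_new <= 0:
        return 0.0
    return min(1.0, (p_new / p_old) ** gamma * (J_old / J_new))


def _mh_sweep(ens: ParticleEnsemble, proposal: ProposalModel,
              target: DensityEstimate, forward: ForwardFn,
              bounds: np.ndarray, rng: np.random.Generator) -> float:
    """One independence-MH update of every particle in place.

    Returns the realized acceptance rate.  Out-of-bounds proposals and
    invalid forward outcomes are rejected (zero tempered density).
    """
    n = ens.n
    cand = proposal.sample(n, rng)
    in_bounds = np.all((cand >= bounds[:, 0]) & (cand <= bounds[:, 1]), axis=1)
    logp_new = np.full(n, -np.inf)
    Y_new = np.zeros((n, ens.outputs.shape[1]))
    if np.any(in_bounds):
        Y, valid = forward(cand[in_bounds])
        Y_new[in_bounds] = Y
        lp = _target_logdensity(Y, valid, target)
        logp_new[in_bounds] = lp
    logJ_new = proposal.logpdf(cand)
    logJ_old = proposal.logpdf(ens.theta)
    # invalid proposals (zero density) are rejected outright, even at gamma=0
    tempered = np.where(np.isneginf(logp_new), -np.inf,
                        ens.gamma * (logp_new - ens.log_density))
    log_alpha = tempered + logJ_old - logJ_new
    accept = np.log(rng.uniform(size=n)) < log_alpha
    ens.theta[accept] = cand[accept]
    ens.outputs[accept] = Y_new[accept]
    ens.log_density[accept] = logp_new[accept]
    return float(accept.mean())


def mh_move(ens: ParticleEnsemble, proposal: ProposalModel,
            target: DensityEstimate, forward: ForwardFn, bounds: np.ndarray,
            rng: np.random.Generator, n_steps: Optional[int] = None,
            max_steps: int = 100) -> tuple[ParticleEnsemble, int, float]:
    """Adaptive independence-MH move phase.

    A pilot sweep estimates the acceptance rate p_acc, after which the total
    number of sweeps is ceil(ln 0.01 / ln(1 - p_acc)) so each particle moves
    at least once with probability >= 0.99.  Returns (ensemble, sweeps used,
    pilot acceptance rate).
    """
    bounds = np.asarray(bounds, dtype=float)
    acc = _mh_sweep(ens, proposal, target, forward, bounds, rng)
    if n_steps is None:
        if acc <= 0.0:
            raise DegenerateEnsembleError(
                "pilot MH sweep accepted no moves (proposal mismatch)",
                gamma=ens.gamma)
        if acc >= 1.0:
            n_steps = 1
        else:
            n_steps = int(np.ceil(np.log(0.01) / np.log(1.0 - acc)))
        n_steps = min(max(n_steps, 1), max_steps)
    for _ in range(n_steps - 1):
        _mh_sweep(ens, proposal, target, forward, bounds, rng)
    return ens, n_steps, acc


@dataclass
class SMCResult:
    theta: np.ndarray             # final unique particles (n, d)
    outputs: np.ndarray           # their cached biomarkers (n, k)
    gamma_schedule: list
    acceptance_rates: list
    unique_fraction: float
    ensemble: ParticleEnsemble = None


def smc_calibrate(target: DensityEstimate, forward: ForwardFn,
                  bounds, n_particles: int, seed,
                  ess_fraction: float = 0.5, max_components: int = 5,
                  max_iterations: int = 200) -> SMCResult:
    """Run the full tempered-SMC calibration, gamma: 0 -> 1.

    Returns the final particle set (duplicates removed) together with the
    cached biomarkers of each retained model and run diagnostics.
    """
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    ens = initialize_particles(n_particles, bounds,
                               rng.integers(2 ** 31 - 1), forward, target)
    gammas = [0.0]
    acc_rates = []
    for _ in range(max_iterations):
        if ens.gamma >= 1.0:
            break
        ens = temper_step(ens, ess_fraction=ess_fraction)
        gammas.append(ens.gamma)
        ens = resample(ens, rng)
        proposal = fit_proposal(ens, rng, max_components=max_components)
        ens, _, acc = mh_move(ens, proposal, target, forward, bounds, rng)
        acc_rates.append(acc)
    else:
        raise DegenerateEnsembleError(
            "tempering failed to reach gamma = 1", gamma=ens.gamma)
    _, idx = np.unique(ens.theta, axis=0, return_index=True)
    idx.sort()
    return SMCResult(theta=ens.theta[idx], outputs=ens.outputs[idx],
                     gamma_schedule=gammas, acceptance_rates=acc_rates,
                     unique_fraction=ens.unique_fraction(), ensemble=ens)
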