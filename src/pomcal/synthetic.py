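"""Synthetic biomarker data and cheap closed-form forward models.

The clinical dataset the calibration method was demonstrated on (seven AP
biomarkers for 469 atrial myocytes, sinus-rhythm and chronic-AF groups) is
not publicly deposited.  This module generates tables with the same
statistical structure -- correlated biomarkers, a strongly right-skewed
APD20, a bimodal APD50 in SR-like data (early-repolarizing cells versus
plateau cells), and APA nearly uncorrelated with dV/dt_max -- plus a family
of closed-form "toy" forward models cheap enough that the full SMC +
refinement pipeline runs end to end in seconds.

Generated values are anchored to plausible human atrial magnitudes; they are
fixture choices of this package, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .ap_model import BIOMARKER_NAMES
from .density import fit_density
from .refine import (PopulationOfModels, RefinementConfig, anneal_refine,
                     divergence)
from .smc import smc_calibrate

# Latent coordinates: z = (ln APD20, ln gap1, ln gap2, APA, RMP, V20,
# ln dVdtmax) with APD50 = APD20 + gap1 and APD90 = APD50 + gap2, so the
# APD ordering invariant holds by construction and APD20/dVdtmax are
# log-normal (right-skewed).
_CORR = np.array([
    # lnAPD20 lngap1 lngap2  APA    RMP    V20   lndVdt
    [1.00,   0.30,  0.00,  0.10,  0.00,  0.10,  0.15],
    [0.30,   1.00, -0.20,  0.00,  0.00,  0.40,  0.00],
    [0.00,  -0.20,  1.00,  0.00, -0.20,  0.10,  0.00],
    [0.10,   0.00,  0.00,  1.00, -0.30,  0.20,  0.05],
    [0.00,   0.00, -0.20, -0.30,  1.00,  0.00,  0.00],
    [0.10,   0.40,  0.10,  0.20,  0.00,  1.00,  0.00],
    [0.15,   0.00,  0.00,  0.05,  0.00,  0.00,  1.00],
])


@dataclass
class SyntheticSpec:
    """Mixture specification for one synthetic biomarker dataset."""

    n: int
    group_style: str                      # "SR" | "cAF"
    means: np.ndarray                     # (n_components, 7) latent means
    sds: np.ndarray                       # (n_components, 7) latent SDs
    weights: np.ndarray                   # mixture weights, sum to 1
    corr: np.ndarray = field(default_factory=lambda: _CORR.copy())
    seed: int = 0

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.linalg.eigvalsh(self.corr) <= 0):
            raise ValueError("latent correlation matrix is not positive-definite")


def sr_spec(n: int = 469, seed: int = 0) -> SyntheticSpec:
    """SR-like structure: bimodal APD50 (25% early-repolarizing cells with
    very small phase-1-to-phase-2 gaps), long plateaus, skewed APD20."""
    means = np.array([
        # lnAPD20    lngap1        lngap2        APA    RMP   V20  lndVdt
        [np.log(9), np.log(160), np.log(120), 105.0, -74.0, -4.0, np.log(210)],
        [np.log(7), np.log(18),  np.log(240),  105.0, -74.0, -20.0, np.log(210)],
    ])
    sds = np.array([
        [0.55, 0.30, 0.30, 12.0, 7.0, 11.0, 0.35],
        [0.55, 0.45, 0.25, 12.0, 7.0, 11.0, 0.35],
    ])
    return SyntheticSpec(n=n, group_style="SR", means=means, sds=sds,
                         weights=np.array([0.75, 0.25]), seed=seed)


def caf_spec(n: int = 469, seed: int = 0) -> SyntheticSpec:
    """cAF-like structure: unimodal, triangular APs (larger APD20, smaller
    APD50), shorter APD90, slightly depolarized RMP."""
    means = np.array([
        [np.log(25), np.log(45), np.log(125), 100.0, -78.0, -12.0,
         np.log(200)],
    ])
    sds = np.array([[0.45, 0.40, 0.30, 12.0, 7.0, 11.0, 0.35]])
    return SyntheticSpec(n=n, group_style="cAF", means=means, sds=sds,
                         weights=np.array([1.0]), seed=seed)


def _latent_to_biomarkers(Z: np.ndarray) -> np.ndarray:
    Y = np.empty_like(Z)
    apd20 = np.exp(Z[:, 0])
    apd50 = apd20 + np.exp(Z[:, 1])
    apd90 = apd50 + np.exp(Z[:, 2])
    Y[:, 0] = apd20
    Y[:, 1] = apd50
    Y[:, 2] = apd90
    Y[:, 3] = Z[:, 3]           # APA
    Y[:, 4] = Z[:, 4]           # RMP
    Y[:, 5] = Z[:, 5]           # V20
    Y[:, 6] = np.exp(Z[:, 6])   # dVdtmax
    return Y


def generate_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a biomarker table from the mixture; pure function of spec + seed.

    Rows violating the biomarker invariants (APA <= 0 or V20 above the AP
    peak, both far tails of the latent Gaussians) are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    chols = [np.linalg.cholesky(np.outer(s, s) * spec.corr)
             for s in spec.sds]
    rows = []
    while len(rows) < spec.n:
        need = spec.n - len(rows)
        comp = rng.choice(len(spec.weights), size=need, p=spec.weights)
        Z = np.empty((need, 7))
        for c in range(len(spec.weights)):
            m = comp == c
            if m.any():
                eps = rng.standard_normal((int(m.sum()), 7))
                Z[m] = spec.means[c] + eps @ chols[c].T
        Y = _latent_to_biomarkers(Z)
        ok = (Y[:, 3] > 0) & (Y[:, 6] > 0) & (Y[:, 5] <= Y[:, 4] + Y[:, 3])
        rows.extend(Y[ok])
    Y = np.asarray(rows[:spec.n])
    return pd.DataFrame(Y, columns=list(BIOMARKER_NAMES))


def generate(style: str, n: int = 469, seed: int = 0) -> pd.DataFrame:
    """Convenience wrapper: ``style`` is 'sr' or 'caf'."""
    s = style.lower()
    if s == "sr":
        return generate_dataset(sr_spec(n, seed))
    if s == "caf":
        return generate_dataset(caf_spec(n, seed))
    raise ValueError("style must be 'sr' or 'caf'")


@dataclass
class ToyForwardModel:
    """A closed-form forward map with known pushforward where available."""

    name: str
    dim: int
    out_dim: int
    bounds: np.ndarray
    fn: Callable[[np.ndarray], np.ndarray]
    pushforward: Optional[Callable[[np.ndarray], np.ndarray]] = None
    columns: tuple = ()

    def __call__(self, theta: np.ndarray):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        Y = self.fn(theta)
        return Y, np.ones(theta.shape[0], dtype=bool)


# Surrogate conductance -> biomarker directions: each output is a baseline
# magnitude modulated by saturating (tanh) responses to the centered
# parameters, mirroring the directions of the mechanistic model (repolarizing
# currents shorten APDs, the Na+ conductance drives both the upstroke
# velocity and the amplitude -- the built-in APA/dVdtmax correlation).
_SURROGATE_PARAMS = ("gNa", "gto", "gKur", "gKr", "gKs", "gK1", "gCaL",
                     "INaK", "INaCa", "Iup", "krel")
#                 gNa   gto   gKur  gKr   gKs   gK1   gCaL  INaK INaCa Iup krel
_W_APD20 = np.array([0.00, -0.30, -0.20, 0.00, 0.00, 0.00, 0.10, 0.0, 0.0, 0.0, 0.05])
_W_GAP1 = np.array([0.00, -0.10, -0.10, -0.10, -0.05, 0.00, 0.25, 0.0, 0.05, 0.0, 0.0])
_W_GAP2 = np.array([0.00, 0.00, 0.00, -0.20, -0.05, -0.30, 0.15, 0.05, 0.0, 0.0, 0.0])
_W_APA = np.array([0.08, 0.00, 0.00, 0.00, 0.00, 0.04, 0.02, 0.0, 0.0, 0.0, 0.0])
_W_DVDT = np.array([0.45, 0.00, 0.00, 0.00, 0.00, 0.02, 0.00, 0.0, 0.0, 0.0, 0.0])


def _surrogate_map(theta: np.ndarray) -> np.ndarray:
    u = np.tanh(theta - 1.0)
    apd20 = 10.0 * np.exp(u @ _W_APD20)
    gap1 = 140.0 * np.exp(u @ _W_GAP1)
    gap2 = 130.0 * np.exp(u @ _W_GAP2)
    apa = 105.0 * np.exp(u @ _W_APA)
    rmp = -74.0 - 8.0 * u[:, 5] + 1.5 * u[:, 7]
    v20 = -5.0 - 10.0 * u[:, 1] + 6.0 * u[:, 6]
    dvdt = 200.0 * np.exp(u @ _W_DVDT)
    return np.column_stack([apd20, apd20 + gap1, apd20 + gap1 + gap2,
                            apa, rmp, v20, dvdt])


def toy_models() -> dict[str, ToyForwardModel]:
    """Closed-form forward models for exercising the calibration engine."""
    unit = np.array([[0.0, 1.0]])
    models = {
        "identity": ToyForwardModel(
            name="identity", dim=1, out_dim=1, bounds=unit,
            fn=lambda th: th.copy(),
            pushforward=lambda y: np.where((y >= 0) & (y <= 1), 1.0, 0.0),
            columns=("y",)),
        "square": ToyForwardModel(
            name="square", dim=1, out_dim=1, bounds=unit,
            fn=lambda th: th ** 2,
            pushforward=lambda y: np.where(
                (y > 0) & (y <= 1), 0.5 / np.sqrt(np.maximum(y, 1e-300)), 0.0),
            columns=("y",)),
        "correlated2d": ToyForwardModel(
            name="correlated2d", dim=2, out_dim=2,
            bounds=np.array([[0.0, 1.0], [0.0, 1.0]]),
            fn=lambda th: np.column_stack(
                [th[:, 0], 0.7 * th[:, 0] + 0.3 * th[:, 1]]),
            columns=("y1", "y2")),
        "surrogate": ToyForwardModel(
            name="surrogate", dim=11, out_dim=7,
            bounds=np.tile([0.0, 2.0], (11, 1)),
            fn=_surrogate_map,
            columns=BIOMARKER_NAMES),
    }
    return models


PREDEFINED_SEEDS = tuple(range(1, 11))


@dataclass
class RecoveryReport:
    seed: int
    rho_refined: float
    rho_range: float
    refined_size: int
    range_size: int
    true_center: np.ndarray
    median_shift_pct: np.ndarray   # refined-POM median vs truth, per parameter


def end_to_end_recovery(seed: int, n_data: int = 150, n_particles: int = 256,
                        step_budget: int = 3000, bins: int = 32
                        ) -> RecoveryReport:
    """Full-pipeline exercise on the 11-parameter surrogate model.

    Draws a known parameter distribution, pushes it through the surrogate to
    make a synthetic data table, calibrates with SMC + annealing refinement,
    and compares the refined divergence against an equal-size
    range-calibrated (Latin hypercube) population on the same data.
    """
    from .analysis import RangeBox, lhs_candidates  # local: avoid cycle

    surrogate = toy_models()["surrogate"]
    rng = np.random.default_rng(seed)

    # ground truth: independent per-parameter Gaussians around a center
    # drawn once per seed, moderate spread, truncated to the bounds
    center = 1.0 + rng.uniform(-0.25, 0.25, size=11)
    sd = 0.25
    theta_true = rng.normal(center, sd, size=(n_data, 11))
    theta_true = np.clip(theta_true, surrogate.bounds[:, 0] + 1e-6,
                         surrogate.bounds[:, 1] - 1e-6)
    Y_true, _ = surrogate(theta_true)
    table = pd.DataFrame(Y_true, columns=list(BIOMARKER_NAMES))

    est = fit_density(table)
    res = smc_calibrate(est, surrogate, surrogate.bounds, n_particles,
                        seed=seed)
    pool = PopulationOfModels(theta=res.theta, biomarkers=res.outputs,
                              provenance={"method": "smc", "seed": seed})
    cfg = RefinementConfig(min_size=min(n_data, max(pool.size - 1, 1)),
                           step_budget=step_budget, bins=bins,
                           check_interval=500)
    ref = anneal_refine(pool, est, cfg, mode="rho", seed=seed)

    # equal-size range-calibrated population via Latin hypercube sampling
    box = RangeBox.from_table(table)
    cand = lhs_candidates(surrogate.bounds, replicates=4,
                          divisions=n_particles, rng=rng)
    Yc, valid = surrogate(cand)
    keep = valid & box.contains(Yc)
    idx = np.flatnonzero(keep)
    if len(idx) > ref.pom.size:
        idx = rng.choice(idx, size=ref.pom.size, replace=False)
    range_pom = PopulationOfModels(theta=cand[idx], biomarkers=Yc[idx],
                                   provenance={"method": "lhs-range"})

    _, rho_ref = divergence(ref.pom, est, mode="rho", bins=bins)
    _, rho_rng = divergence(range_pom, est, mode="rho", bins=bins)
    med = np.median(ref.pom.theta, axis=0)
    return RecoveryReport(seed=seed, rho_refined=rho_ref, rho_range=rho_rng,
                          refined_size=ref.pom.size, range_size=len(idx),
                          true_center=center,
                          median_shift_pct=100.0 * (med - center) / center)
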