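"""Subset refinement of a population of models (POM).

A calibrated POM is compared to the data through a matrix P of square-rooted
Jensen-Shannon divergences: diagonal entries are the divergences between the
marginal distributions of each biomarker (POM vs data), off-diagonal entries
between the pairwise bivariate distributions.  The scalar objective is the
spectral norm rho = ||P||_2.  A de-emphasized variant rho_hat zeroes the
off-diagonal row/column of one biomarker (dV/dt_max in the study) so that a
biomarker the model cannot reproduce does not dominate the fit.

Refinement selects the subpopulation minimizing rho by Metropolis-accepted
membership toggles at a fixed temperature T = 0.2: a uniformly random pool
member is proposed for removal (or reintroduction), accepted with probability
min(1, exp(-delta_rho / T)); every 1000 trials the state restarts from the
best subpopulation found if the current rho has drifted more than 1% above
it.  The subpopulation may never shrink below the number of data points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ap_model import BIOMARKER_NAMES, PARAMETER_NAMES
from .density import DensityEstimate, fit_density, optimal_bandwidth

JSD_MAX = float(np.sqrt(np.log(2.0)))
DVDTMAX_INDEX = BIOMARKER_NAMES.index("dVdtmax")


@dataclass
class PopulationOfModels:
    """Parameter vectors with their simulated biomarkers, plus provenance."""

    theta: np.ndarray                 # (n, d)
    biomarkers: np.ndarray            # (n, 7)
    parameter_names: tuple = PARAMETER_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.biomarkers = np.atleast_2d(
            np.asarray(self.biomarkers, dtype=float))
        if self.theta.shape[0] != self.biomarkers.shape[0]:
            raise ValueError("theta and biomarkers must have equal row counts")

    @property
    def size(self) -> int:
        return self.theta.shape[0]

    def subset(self, idx) -> "PopulationOfModels":
        return PopulationOfModels(theta=self.theta[idx],
                                  biomarkers=self.biomarkers[idx],
                                  parameter_names=self.parameter_names,
                                  provenance=dict(self.provenance))


@dataclass
class DivergenceMatrix:
    P: np.ndarray
    deemphasized_dim: Optional[int] = None

    def value(self, norm: str = "spectral") -> float:
        if norm == "spectral":
            return float(np.abs(np.linalg.eigvalsh(self.P)).max())
        if norm == "frobenius":
            return float(np.linalg.norm(self.P, "fro"))
        raise ValueError("norm must be 'spectral' or 'frobenius'")


@dataclass
class RefinementConfig:
    T: float = 0.2
    check_interval: int = 1000
    restart_threshold: float = 0.01
    min_size: Optional[int] = None      # default: number of data rows
    step_budget: int = 200_000
    bins: int = 128
    norm: str = "spectral"

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")
        if self.min_size is not None and self.min_size < 1:
            raise ValueError("min_size must be >= 1")


def jsd(p: np.ndarray, q: np.ndarray, cell_volume: float = 1.0) -> float:
    """Square-rooted Jensen-Shannon divergence between gridded densities.

    Both inputs must live on the same grid; each is Riemann-normalized before
    the divergence is computed, integrals are Riemann sums.  The value lies
    in [0, sqrt(ln 2)] (nats), 0 iff the gridded densities coincide.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must share a grid")
    ps = p.sum() * cell_volume
    qs = q.sum() * cell_volume
    if ps <= 0 or qs <= 0:
        raise ValueError("densities must have positive mass")
    p = p / ps
    q = q / qs
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * np.log(p / m), 0.0)
        kl_q = np.where(q > 0, q * np.log(q / m), 0.0)
    val = 0.5 * (kl_p.sum() + kl_q.sum()) * cell_volume
    return float(np.sqrt(max(val, 0.0)))


def _pom_bandwidth(Z: np.ndarray) -> np.ndarray:
    """Diagonal bandwidth for a POM output set (same rule as the data side)."""
    n, d = Z.shape
    var = Z.var(axis=0, ddof=1)
    if np.any(var <= 0):
        bad = int(np.argmin(var))
        raise ValueError(f"degenerate population: zero variance in "
                         f"dimension {bad}")
    return optimal_bandwidth(n, d) * var


class _DivergenceWorkspace:
    """Shared grids, data densities and per-member kernel rows.

    Everything lives in the transformed biomarker space of the data estimate.
    Because the bandwidth matrices are diagonal, any member's contribution to
    a bivariate grid is the outer product of its two univariate kernel rows,
    which makes membership toggles cheap: kernel-sum grids are updated by
    adding/subtracting one member's contribution.
    """

    def __init__(self, pom_Z: np.ndarray, data_est: DensityEstimate,
                 bins: int, pom_H: Optional[np.ndarray] = None):
        self.nb = data_est.dim
        self.bins = bins
        self.pairs = [(i, j) for i in range(self.nb)
                      for j in range(i + 1, self.nb)]
        self.H_pom = _pom_bandwidth(pom_Z) if pom_H is None else pom_H

        # shared grids: union range padded by 3 bandwidths on each side
        self.axes = []
        self.steps = np.empty(self.nb)
        for d in range(self.nb):
            sd = max(np.sqrt(data_est.H[d]), np.sqrt(self.H_pom[d]))
            lo = min(data_est.points[:, d].min(), pom_Z[:, d].min()) - 3 * sd
            hi = max(data_est.points[:, d].max(), pom_Z[:, d].max()) + 3 * sd
            ax = np.linspace(lo, hi, bins)
            self.axes.append(ax)
            self.steps[d] = ax[1] - ax[0]

        def kernel_rows(Z, H):
            # rows[d][m, :] = 1-D Gaussian kernel of member m on grid d
            rows = []
            for d in range(self.nb):
                u = (self.axes[d][None, :] - Z[:, d][:, None])
                rows.append(np.exp(-0.5 * u ** 2 / H[d])
                            / np.sqrt(2.0 * np.pi * H[d]))
            return rows

        data_rows = kernel_rows(data_est.points, data_est.H)
        n_data = data_est.n
        self.data_marg = [r.sum(axis=0) / n_data for r in data_rows]
        self.data_pair = {}
        for (i, j) in self.pairs:
            self.data_pair[(i, j)] = (data_rows[i].T @ data_rows[j]) / n_data

        self.rows = kernel_rows(pom_Z, self.H_pom)
        self.n_members = pom_Z.shape[0]

    def member_contrib(self, m: int):
        marg = [self.rows[d][m] for d in range(self.nb)]
        pair = {(i, j): np.outer(marg[i], marg[j]) for (i, j) in self.pairs}
        return marg, pair

    def sums_for(self, mask: np.ndarray):
        marg = [self.rows[d][mask].sum(axis=0) for d in range(self.nb)]
        pair = {(i, j): self.rows[i][mask].T @ self.rows[j][mask]
                for (i, j) in self.pairs}
        return marg, pair

    def rho(self, marg_sums, pair_sums, count: int,
            deemphasize: Optional[int] = None,
            norm: str = "spectral") -> tuple[DivergenceMatrix, float]:
        P = np.zeros((self.nb, self.nb))
        for d in range(self.nb):
            P[d, d] = jsd(self.data_marg[d], marg_sums[d] / count,
                          self.steps[d])
        for (i, j) in self.pairs:
            if deemphasize is not None and deemphasize in (i, j):
                continue
            v = jsd(self.data_pair[(i, j)], pair_sums[(i, j)] / count,
                    self.steps[i] * self.steps[j])
            P[i, j] = P[j, i] = v
        matrix = DivergenceMatrix(P, deemphasized_dim=deemphasize)
        return matrix, matrix.value(norm)


def divergence(pom: PopulationOfModels, data_est: DensityEstimate,
               mode: str = "rho", bins: int = 128, norm: str = "spectral",
               pom_bandwidth: Optional[np.ndarray] = None
               ) -> tuple[DivergenceMatrix, float]:
    """Divergence matrix P and scalar rho (or rho_hat) for a POM vs data.

    Both sides are estimated by Gaussian KDE on shared grids in the data
    estimate's transformed space; each side uses its own normal-reference
    bandwidth.  ``mode='rho_hat'`` zeroes the dV/dt_max off-diagonal entries
    before taking the norm (which can only decrease the spectral norm).
    """
    if pom.size < 2:
        raise ValueError("POM must contain at least 2 members")
    deemph = DVDTMAX_INDEX if mode == "rho_hat" else None
    if mode not in ("rho", "rho_hat"):
        raise ValueError("mode must be 'rho' or 'rho_hat'")
    Z = data_est.transform(pom.biomarkers)
    ws = _DivergenceWorkspace(Z, data_est, bins=bins, pom_H=pom_bandwidth)
    mask = np.ones(pom.size, dtype=bool)
    marg, pair = ws.sums_for(mask)
    return ws.rho(marg, pair, pom.size, deemphasize=deemph, norm=norm)


@dataclass
class RefinementResult:
    pom: PopulationOfModels
    rho_best: float
    rho_initial: float
    trace: np.ndarray          # columns: step, rho_current, rho_best
    membership: np.ndarray     # boolean mask into the input pool
    matrix: DivergenceMatrix


def anneal_refine(pool: PopulationOfModels, data_est: DensityEstimate,
                  cfg: RefinementConfig = RefinementConfig(),
                  mode: str = "rho", seed=0) -> RefinementResult:
    """Fixed-temperature Metropolis subset selection minimizing rho.

    Starting from the full pool, each trial toggles the membership of one
    uniformly chosen pool member and accepts with min(1, exp(-delta_rho/T));
    removals below the minimum size are rejected outright.  The POM-side
    kernel bandwidth is computed once from the full pool and held fixed
    across subsets so membership toggles stay incremental.  Returns the best
    subpopulation visited and the rho trace.
    """
    deemph = DVDTMAX_INDEX if mode == "rho_hat" else None
    if mode not in ("rho", "rho_hat"):
        raise ValueError("mode must be 'rho' or 'rho_hat'")
    min_size = cfg.min_size if cfg.min_size is not None else data_est.n
    rng = np.random.default_rng(seed)

    Z = data_est.transform(pool.biomarkers)
    ws = _DivergenceWorkspace(Z, data_est, bins=cfg.bins)
    n = pool.size

    mask = np.ones(n, dtype=bool)
    marg, pair = ws.sums_for(mask)
    count = n
    _, rho_cur = ws.rho(marg, pair, count, deemph, cfg.norm)
    rho_init = rho_cur

    best_mask = mask.copy()
    best_rho = rho_cur
    trace = [(0, rho_cur, best_rho)]
    if n <= min_size:
        matrix, _ = ws.rho(marg, pair, count, deemph, cfg.norm)
        return RefinementResult(pom=pool.subset(mask), rho_best=rho_cur,
                                rho_initial=rho_init,
                                trace=np.asarray(trace, dtype=float),
                                membership=mask, matrix=matrix)

    any_accept = False
    for step in range(1, cfg.step_budget + 1):
        m = int(rng.integers(n))
        removing = mask[m]
        if removing and count - 1 < min_size:
            trace.append((step, rho_cur, best_rho))
            continue
        c_marg, c_pair = ws.member_contrib(m)
        sgn = -1.0 if removing else 1.0
        t_marg = [marg[d] + sgn * c_marg[d] for d in range(ws.nb)]
        t_pair = {k: pair[k] + sgn * c_pair[k] for k in ws.pairs}
        t_count = count + (int(sgn))
        _, rho_new = ws.rho(t_marg, t_pair, t_count, deemph, cfg.norm)
        if rho_new <= rho_cur or rng.uniform() < np.exp(
                -(rho_new - rho_cur) / cfg.T):
            mask[m] = not removing
            marg, pair, count, rho_cur = t_marg, t_pair, t_count, rho_new
            any_accept = True
            if rho_cur < best_rho:
                best_rho = rho_cur
                best_mask = mask.copy()
        if step % cfg.check_interval == 0:
            if rho_cur > (1.0 + cfg.restart_threshold) * best_rho:
                mask = best_mask.copy()
                marg, pair = ws.sums_for(mask)
                count = int(mask.sum())
                rho_cur = best_rho
        trace.append((step, rho_cur, best_rho))

    if not any_accept:
        import warnings
        warnings.warn("annealing budget exhausted without an accepted move",
                      RuntimeWarning)
    final_marg, final_pair = ws.sums_for(best_mask)
    matrix, best_rho_check = ws.rho(final_marg, final_pair,
                                    int(best_mask.sum()), deemph, cfg.norm)
    refined = pool.subset(best_mask)
    refined.provenance.update({"refinement": mode, "T": cfg.T,
                               "rho": best_rho_check, "seed": seed})
    return RefinementResult(pom=refined, rho_best=best_rho_check,
                            rho_initial=rho_init,
                            trace=np.asarray(trace, dtype=float),
                            membership=best_mask, matrix=matrix)
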