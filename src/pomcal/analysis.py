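"""Downstream uses of calibrated populations of models.

Range calibration (the Latin-hypercube baseline the distributional method is
compared against), nonparametric comparison of parameter distributions
between two POMs, construction of a single "median" model from a POM, and
the current-block drug experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .ap_model import (BIOMARKER_NAMES, PARAMETER_NAMES, BiomarkerVector,
                       ParameterVector, Rejection, StimulusProtocol,
                       apply_drug_block, forward_map)
from .refine import PopulationOfModels

ELEVATED_RMP_THRESHOLD = -60.0  # mV; post-block resting potentials above
                                # this are flagged as unrealistically high


@dataclass(frozen=True)
class RangeBox:
    """Per-biomarker [min, max] intervals of a data table."""

    lo: np.ndarray
    hi: np.ndarray
    columns: tuple = BIOMARKER_NAMES

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   columns=BIOMARKER_NAMES) -> "RangeBox":
        Y = np.asarray(table[list(columns)], dtype=float)
        return cls(lo=Y.min(axis=0), hi=Y.max(axis=0), columns=tuple(columns))

    def contains(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return np.all((Y >= self.lo) & (Y <= self.hi), axis=1)


def lhs_candidates(bounds: np.ndarray, replicates: int, divisions: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Latin-hypercube candidates: ``replicates`` independent designs, each
    placing exactly one point per dimension stratum (``divisions`` strata,
    uniform within each stratum, independently permuted per dimension)."""
    bounds = np.asarray(bounds, dtype=float)
    if replicates < 1 or divisions < 1:
        raise ValueError("replicates and divisions must be >= 1")
    d = bounds.shape[0]
    out = np.empty((replicates * divisions, d))
    width = (bounds[:, 1] - bounds[:, 0]) / divisions
    for r in range(replicates):
        block = np.empty((divisions, d))
        for k in range(d):
            strata = rng.permutation(divisions)
            u = rng.uniform(size=divisions)
            block[:, k] = bounds[k, 0] + (strata + u) * width[k]
        out[r * divisions:(r + 1) * divisions] = block
    return out


def lhs_range_calibrate(data: pd.DataFrame, forward, bounds,
                        replicates: int = 10, divisions: int = 1000,
                        seed=0) -> PopulationOfModels:
    """Range calibration: accept LHS-sampled models whose every biomarker
    lies within the data's per-biomarker ranges.

    ``forward`` maps an (n, d) parameter array to (biomarkers, valid-mask),
    as in the SMC module.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    cand = lhs_candidates(bounds, replicates, divisions, rng)
    Y, valid = forward(cand)
    box = RangeBox.from_table(data)
    keep = valid & box.contains(Y)
    return PopulationOfModels(
        theta=cand[keep], biomarkers=Y[keep],
        provenance={"method": "lhs-range", "seed": seed,
                    "replicates": replicates, "divisions": divisions,
                    "candidates": cand.shape[0]})


def compare_parameter_distributions(pomA: PopulationOfModels,
                                    pomB: PopulationOfModels,
                                    sig_level: float = 0.001,
                                    nochange_level: float = 0.01
                                    ) -> pd.DataFrame:
    """Per-parameter median shift (% of pomA median) and Mann-Whitney U test.

    The shift is the ratio of medians (pomB over pomA) minus one, in percent.
    ``significant`` flags p below ``sig_level``; ``no_change`` flags p at or
    above ``nochange_level`` (reported "<->" in tabulated remodeling
    comparisons).  Identical samples are reported as p = 1.
    """
    if pomA.size == 0 or pomB.size == 0:
        raise ValueError("both POMs must be nonempty")
    if pomA.theta.shape[1] != pomB.theta.shape[1]:
        raise ValueError("POMs must share the parameter layout")
    names = pomA.parameter_names[:pomA.theta.shape[1]]
    rows = []
    for k, name in enumerate(names):
        a = pomA.theta[:, k]
        b = pomB.theta[:, k]
        med_a = np.median(a)
        med_b = np.median(b)
        shift = 100.0 * (med_b - med_a) / med_a if med_a != 0 else np.nan
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"parameter": name, "median_shift_pct": shift,
                     "p_value": p, "significant": p < sig_level,
                     "no_change": p >= nochange_level})
    return pd.DataFrame(rows)


def median_model(pom: PopulationOfModels):
    """Component-wise median of theta across the population.

    Returns a :class:`ParameterVector` for the mechanistic 11/12-parameter
    layout, otherwise the raw median array.
    """
    if pom.size == 0:
        raise ValueError("POM is empty")
    med = np.median(pom.theta, axis=0)
    if med.shape[0] in (11, 12):
        return ParameterVector.from_array(med)
    return med


def drug_block_experiment(pom: PopulationOfModels, current_name: str,
                          block_fraction: float,
                          protocol: StimulusProtocol = StimulusProtocol(),
                          forward_fn: Optional[Callable] = None
                          ) -> pd.DataFrame:
    """Pre/post biomarker pairs under a fractional current block.

    Each member is paced to steady state pre-block, then the blocked
    parameter set is re-paced with the full protocol.  Rows carry flags for
    members repolarizing to unrealistically high resting potentials
    (post-block RMP above -60 mV) and for paradoxical APD90 shortening.
    Post-block simulation failures are recorded per member, never fatal.

    ``forward_fn(theta: ParameterVector) -> BiomarkerVector | Rejection``
    defaults to the mechanistic forward map under ``protocol``.
    """
    if forward_fn is None:
        def forward_fn(theta):
            return forward_map(theta, protocol)
    rows = []
    for i in range(pom.size):
        theta = ParameterVector.from_array(pom.theta[i])
        pre = forward_fn(theta)
        post = forward_fn(apply_drug_block(theta, current_name,
                                           block_fraction))
        row = {"member": i}
        for tag, out in (("pre", pre), ("post", post)):
            if isinstance(out, Rejection):
                row[f"{tag}_failed"] = out.reason
                for n in BIOMARKER_NAMES:
                    row[f"{tag}_{n}"] = np.nan
            else:
                row[f"{tag}_failed"] = ""
                for n in BIOMARKER_NAMES:
                    row[f"{tag}_{n}"] = getattr(out, n)
        row["elevated_rmp"] = (row["post_RMP"] > ELEVATED_RMP_THRESHOLD
                               if np.isfinite(row["post_RMP"]) else False)
        row["apd90_decreased"] = (row["post_APD90"] < row["pre_APD90"]
                                  if np.isfinite(row["post_APD90"])
                                  and np.isfinite(row["pre_APD90"])
                                  else False)
        rows.append(row)
    return pd.DataFrame(rows)
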