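# Methods

This note documents the models, algorithms and numerical choices behind
`pomcal`, including the decisions made where the procedure being emulated is
underdetermined, and what the synthetic-data tests do and do not establish.

## Mechanistic model and forward map

The forward map is y = M(θ): simulate the Courtemanche–Ramirez–Nattel (CRN)
human atrial myocyte model — 21 coupled ODEs for membrane potential, twelve
Hodgkin–Huxley gates, intracellular Na⁺/K⁺/Ca²⁺ and two sarcoplasmic-
reticulum Ca²⁺ compartments — at parameter multipliers θ, and summarize the
final paced beat by seven biomarkers. The equations and published initial
conditions are transcribed from the original model publication (they are
standard and available in CellML form); the implementation is validated by
the resting-state consistency of the right-hand side (|dV/dt| < 5·10⁻⁴ mV/ms
at the published rest state under default conditions), solver-refinement
invariance of the biomarkers (< 1% under halved step size and 100× tighter
tolerances), and the deterministic reference values the calibration study
reports for this model (baseline RMP −85.7 mV, cAF-remodeled APD90 121 ms
and RMP −88.7 mV, stimulus ≈ 2× diastolic threshold).

**Experimental conditions.** T = 309.65 K, [Na⁺]ₒ = 149.42 mM,
[K⁺]ₒ = 4.5 mM, [Ca²⁺]ₒ = 1.8 mM; all other constants as published.

**Pacing protocol.** 2-ms, −2210-pA stimulus; pacing continues until every
state variable changes by ≤ 1% between consecutive beat ends
(|Δs|/(|s|+10⁻¹⁰) ≤ 0.01, with an absolute floor |Δs| ≤ 10⁻⁹ so near-zero
gates cannot stall the criterion), then 90 further beats; biomarkers come
from the final beat. The pacing frequency is not part of the emulated
protocol description; the default is 1 Hz (cycle length 1000 ms), exposed in
configuration. The steady-state search is capped at 1000 beats (warn and
continue); the baseline model satisfies the 1% criterion within a handful of
beats because the criterion is loose relative to the slow ionic drifts.

**Solver.** SciPy's LSODA (variable-order, stiffness-switching) with the
protocol's 1-ms cap on the step size, rtol 10⁻⁶ and per-state absolute
tolerances scaled to each state's magnitude (10⁻⁸ relative to scale). The
right-hand side is numba-compiled. Each beat is integrated in two segments
(stimulus on/off) so the discontinuity never crosses a solver step. dV/dt is
evaluated from the ODE right-hand side on dense output rather than by finite
differences, so dV/dt_max does not depend on the sampling grid.

**Biomarkers.** RMP is the potential immediately before the stimulus; APA
the peak above RMP; the activation time is the instant of dV/dt_max; APDx
runs from the activation time to the first crossing of peak − x%·APA
(linear interpolation between samples); V20 is the potential at activation
time + 0.2·APD90. APs are rejected, with a reason, if they (a) never exceed
−30 mV, (b) never repolarize to RMP + 0.1·APA, or (c) show a local maximum
above that level after repolarizing below it (spontaneous depolarization).
One additional guard: a trace whose *resting* potential already exceeds
−30 mV is rejected as non-excited — "exciting above −30 mV" is read as a
crossing from a polarized rest, without which a fully depolarized, currentless
membrane would pass the rules vacuously.

**Diastolic threshold.** Bisection (to ≤ 1 pA) of the 2-ms pulse magnitude
that drives the peak above −30 mV, starting from the model's published
resting state. Under the study's bath conditions the true resting potential
drifts several mV below the published rest; measuring the threshold from the
published rest state reproduces the protocol's "stimulus ≈ twice the
diastolic threshold" relation (2 × 1120 ≈ 2240 pA vs 2210 pA stated), while
a fully re-equilibrated rest raises it by ~20%. A `rest_time` parameter
exposes the alternative.

**cAF-remodeled baseline.** Only the quantified experimental remodeling
entries are applied (g_to ×0.3, g_Kur ×0.5, g_Ks ×2, g_K1 ×2, g_CaL ×0.3,
I_NaCa(max) ×1.4); currents reported as unchanged or with conflicting
evidence stay at 1.0.

## Biomarker density estimation

p(y) is a Gaussian KDE over the seven (transformed) biomarkers with diagonal
bandwidth H_ii = h_opt σ_i², h_opt = (4/(N(N_b+2)))^(2/(N_b+4)). Note the
exponent 2/(N_b+4): h_opt is a *squared* bandwidth factor, so H acts as the
kernel covariance and this is exactly the classical multivariate
normal-reference rule. A `bandwidth_convention="squared"` switch
(H_ii = h_opt²σ_i²) is provided for comparison.

Columns with sample skewness > 1 (and strictly positive values) are
natural-log transformed before estimation — on data with the structure of
the atrial study this selects APD20 (and typically dV/dt_max on the
synthetic tables, which are log-normal there by construction); the transform
set is overridable. During SMC the density is evaluated in transformed space
without the log-Jacobian, since only ratios enter the algorithm; reported
absolute densities include the Jacobian.

Marginal and pairwise densities are evaluated on regular grids of 128 bins
per dimension (configurable) covering the data range padded by 3 bandwidths;
because H is diagonal, marginalization is exact (the sub-KDE on the selected
coordinates).

## Tempered SMC

Target sequence h(θ) ∝ p(M(θ))^γ on the bounded search box (default
[0, 2]¹¹, i.e. ±100%; g_Na extensible to [0, 4] and an optional 12th
parameter scaling the I_Na h-gate time constant). Models that fail to
produce an acceptable AP have density zero; the γ = 0 initialization redraws
them so no dead particles enter the ensemble. Where the emulated procedure
leaves algorithmic details open, this package makes the standard choices
from the SMC literature:

- **γ increments** by bisection so the reweighted effective sample size
  equals N/2 (capped at γ = 1).
- **Systematic resampling** (copy counts within ⌊Nw⌋..⌈Nw⌉).
- **Proposal**: Gaussian mixture fitted to particle locations jittered by
  10% of the per-dimension ensemble SD, covariance floor 10⁻⁶, component
  count by BIC over 1..5; independence MH acceptance
  min(1, (p_new/p_old)^γ · J_old/J_new); out-of-bounds proposals rejected
  (the implicit uniform prior on the box).
- **Adaptive move count**: a pilot sweep estimates the acceptance rate
  p̂, then ⌈ln 0.01 / ln(1 − p̂)⌉ sweeps in total (≥ 99% probability each
  particle moves at least once), capped at 100.

The final particles are distributed ∝ p(M(θ)) over θ; this does **not** make
M(θ) distributed as p(y) (the map is neither invertible nor volume-
preserving), which is precisely why refinement follows. Tests assert the
pushforward property, not output-distribution equality.

## Divergence and refinement

ρ = ‖P‖₂ with P_ii = JSD(marginal i), P_ij = JSD(pair ij), where JSD is the
square-rooted Jensen–Shannon divergence (natural log; maximum √ln2) computed
by Riemann sums on shared grids. ‖·‖₂ is read as the spectral norm of the
symmetric matrix P; a Frobenius option exists (both norms can only decrease
when ρ̂ zeroes the dV/dt_max off-diagonals, so the ρ̂ ≤ ρ invariant holds
either way). Each side's KDE uses its own normal-reference bandwidth from
its own N and σ.

Annealing starts from the full pool and toggles uniformly chosen members
(removal or reintroduction), accepting with min(1, e^(−Δρ/T)), T = 0.2
fixed; every 1000 trials the state restarts from the best subpopulation if
the current ρ exceeds it by > 1%; removals below the minimum size (default:
the number of data rows) are rejected outright. Termination is a fixed trial
budget (default 200 000), as no stopping rule is part of the emulated
procedure. For incrementality the POM-side bandwidth is computed once from
the full pool and held fixed across subsets: with a diagonal H every
member's contribution to any marginal or pairwise grid is (an outer product
of) precomputed univariate kernel rows, so a membership toggle is a vector
update plus a JSD re-evaluation, and the incremental sums match from-scratch
recomputation to 10⁻¹⁰. The standalone `divergence()` entry point recomputes
the bandwidth from the population it is given.

## Downstream analyses

- **Range calibration**: `replicates` independent Latin-hypercube designs of
  `divisions` points (exactly one point per stratum per dimension, uniform
  within stratum), filtered by validity and the data's per-biomarker range
  box. The study-scale configuration is 10 replicates × 1000 divisions.
- **POM comparison**: per-parameter shift reported as the ratio of medians
  minus one (the tabulated "change in median current activity"); the
  alternative (median of ratios) is not used. Two-sided Mann–Whitney U via
  SciPy (exact for small samples, tie-corrected normal approximation for
  large); significance threshold 0.001, "no change" threshold 0.01, both
  configurable.
- **Median model**: component-wise median of θ.
- **Drug block**: scale one multiplier by (1 − block fraction), re-run the
  full protocol, report pre/post biomarker pairs with flags for post-block
  RMP > −60 mV (failure to repolarize to a realistic rest) and paradoxical
  APD90 shortening. The ±30% variability study needs no separate code path:
  set bounds to median-model θ ± 30%.

## Synthetic data and surrogates

The generator emulates the *structure* of the atrial biomarker data, not its
exact moments (which are not fully tabulated anywhere): a 7-D latent
Gaussian mixture over (ln APD20, ln(APD50−APD20), ln(APD90−APD50), APA, RMP,
V20, ln dV/dt_max), so APD ordering holds by construction, APD20 and
dV/dt_max are right-skewed, and the SR style's two components (25%
early-repolarizing cells with small APD50, 75% plateau cells) produce the
bimodal APD50. APA and dV/dt_max are assigned near-zero latent correlation
(|r| < 0.2 at n = 469). The cAF style is unimodal with larger APD20, smaller
APD50/APD90, and RMP ≈ −78 mV. Magnitudes are anchored to plausible human
atrial values; they are fixture choices. The generator does not model
measurement error, inter-patient clustering, or heavy-tailed outliers, so
passing tests establish algorithmic correctness on realistic structure, not
clinical reproduction.

Toy forward models: identity and square maps (analytic pushforwards),
a 2-D map with built-in output correlation, and an 11-parameter surrogate
whose outputs are baseline biomarker magnitudes modulated by saturating tanh
responses with mechanistically signed weights (repolarizing currents shorten
APDs; g_Na drives both dV/dt_max and APA — the built-in correlation the ρ̂
variant exists to de-emphasize). The surrogate evaluates in microseconds,
which is what makes 2000-particle SMC runs and the end-to-end recovery study
take seconds.

**End-to-end recovery** draws a known parameter distribution (center
1 ± 0.25 per component, SD 0.25, truncated to the box), builds a synthetic
data table through the surrogate (150 rows), runs SMC (256 particles) plus
refinement (3000 trials, 32 bins), and compares the refined ρ against an
equal-size LHS range-calibrated population. Problem sizes here, and in the
test suite generally, are scaled so the full suite completes in minutes; the
mechanics are identical at study scale (the study-shaped 2000-particle run
is exercised separately and retains > 95% unique particles).

## Known limitations

- Single-cell only; no tissue coupling, no alternative AP models, no
  intracellular Ca²⁺ biomarkers.
- The annealing objective holds the POM-side bandwidth fixed at the pool
  level (see above); refined ρ values reported by `divergence()` on the
  final subset use that subset's own bandwidth and can differ slightly.
- The KDE uses globally constant diagonal bandwidths; no boundary
  correction, so mass leaks past hard physical bounds (e.g. APD > 0) at the
  few-percent level for heavily skewed, untransformed columns.
- The Gaussian-copula density construction and variational-Bayes
  formulation of the calibration problem are intentionally out of scope.
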