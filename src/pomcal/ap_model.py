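"""Action-potential simulation and biomarker extraction.

The forward map at the heart of population-of-models calibration is
``y = M(theta)``: simulate the atrial AP model at conductance multipliers
``theta`` under a fixed pacing protocol, then summarize the final paced beat
by seven biomarkers (APD20, APD50, APD90, APA, RMP, V20, dV/dt_max).
Simulations that fail to excite, fail to repolarize, or show spontaneous
depolarizations are rejected, never summarized partially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from . import crn

BIOMARKER_NAMES = ("APD20", "APD50", "APD90", "APA", "RMP", "V20", "dVdtmax")
PARAMETER_NAMES = ("gNa", "gto", "gKur", "gKr", "gKs", "gK1", "gCaL",
                   "INaK_max", "INaCa_max", "Iup_max", "krel")

EXCITATION_THRESHOLD = -30.0  # mV; APs that never exceed this are discarded


@dataclass(frozen=True)
class ParameterVector:
    """Dimensionless multipliers on the CRN maximal current magnitudes.

    All entries scale the published baseline values; the all-ones vector is
    the unmodified model.  ``tau_h_scale`` optionally scales the I_Na h-gate
    time constant (1.0 leaves the published kinetics untouched).
    """

    gNa: float = 1.0
    gto: float = 1.0
    gKur: float = 1.0
    gKr: float = 1.0
    gKs: float = 1.0
    gK1: float = 1.0
    gCaL: float = 1.0
    INaK_max: float = 1.0
    INaCa_max: float = 1.0
    Iup_max: float = 1.0
    krel: float = 1.0
    tau_h_scale: float = 1.0

    def __post_init__(self):
        for name in PARAMETER_NAMES + ("tau_h_scale",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_array(self, include_tau_h: bool = False) -> np.ndarray:
        vals = [getattr(self, n) for n in PARAMETER_NAMES]
        if include_tau_h:
            vals.append(self.tau_h_scale)
        return np.array(vals)

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] not in (11, 12):
            raise ValueError("expected 11 or 12 parameter entries")
        kw = dict(zip(PARAMETER_NAMES, arr[:11]))
        if arr.shape[0] == 12:
            kw["tau_h_scale"] = arr[11]
        return cls(**kw)


# Experimentally reported cAF remodeling of the quantified currents
# (down-regulated I_to, I_Kur and I_CaL, up-regulated I_Ks and I_K1,
# increased Na+/Ca2+ exchange); currents without a quantified change
# are left at baseline.
CAF_REMODELING = {"gto": 0.3, "gKur": 0.5, "gKs": 2.0, "gK1": 2.0,
                  "gCaL": 0.3, "INaCa_max": 1.4}


def caf_adjusted_baseline() -> ParameterVector:
    """Baseline model with the experimentally observed cAF remodeling."""
    return ParameterVector(**CAF_REMODELING)


@dataclass(frozen=True)
class StimulusProtocol:
    """Pacing protocol and experimental conditions.

    Defaults follow the study conditions: a 2-ms, -2210-pA stimulus
    (about twice the diastolic threshold of the baseline model), pacing to
    steady state (<= 1% change in every state variable between beats) and
    then 90 further beats, at 309.65 K with the recorded bath concentrations.
    """

    amplitude: float = -2210.0      # pA, inward
    duration: float = 2.0           # ms
    cycle_length: float = 1000.0    # ms
    steady_state_tol: float = 0.01
    extra_beats: int = 90
    max_beats: int = 1000           # cap on the steady-state search
    temperature: float = crn.T_DEFAULT
    Na_o: float = crn.NA_O_DEFAULT
    K_o: float = crn.K_O_DEFAULT
    Ca_o: float = crn.CA_O_DEFAULT

    def __post_init__(self):
        if self.amplitude >= 0:
            raise ValueError("stimulus amplitude must be negative (inward)")
        if self.duration >= self.cycle_length:
            raise ValueError("stimulus duration must be < cycle length")
        if self.steady_state_tol <= 0:
            raise ValueError("steady_state_tol must be > 0")


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-integrator settings.

    A variable-order stiff method (LSODA) with a 1-ms cap on the step size;
    only the step-size cap is imposed by the emulated protocol, the
    tolerances are this package's own defaults.
    """

    max_step: float = 1.0
    rtol: float = 1e-6
    atol_scale: float = 1e-8  # per-state absolute tolerance multiplier
    method: str = "LSODA"

    def atol(self) -> np.ndarray:
        # States span ~10 orders of magnitude; scale tolerances to each
        # state's typical magnitude (potential ~100 mV, gates ~1, mM ~10).
        scales = np.ones(crn.N_STATES)
        scales[0] = 100.0      # V
        scales[16] = 10.0      # Na_i
        scales[17] = 100.0     # K_i
        scales[18] = 1e-3      # Ca_i
        scales[19] = 1.0       # Ca_up
        scales[20] = 1.0       # Ca_rel
        return self.atol_scale * scales


DEFAULT_SOLVER = SolverConfig()


@dataclass
class APTrace:
    """One paced beat: time (ms, stimulus onset at 0), potential (mV).

    ``dVdt`` holds the membrane-potential derivative evaluated from the ODE
    right-hand side at the sample times (V/s == mV/ms), removing any
    dependence of dV/dt_max on the sampling grid.
    """

    t: np.ndarray
    V: np.ndarray
    dVdt: Optional[np.ndarray] = None
    state_final: Optional[np.ndarray] = None
    activation_time: Optional[float] = None
    beats_to_steady_state: Optional[int] = None
    steady_state_reached: bool = True

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if len(self.t) != len(self.V):
            raise ValueError("t and V must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(dt > 1.0 + 1e-9):
            raise ValueError("sample spacing must be <= 1 ms")


@dataclass(frozen=True)
class BiomarkerVector:
    APD20: float
    APD50: float
    APD90: float
    APA: float
    RMP: float
    V20: float
    dVdtmax: float

    def __post_init__(self):
        if not (0 < self.APD20 <= self.APD50 <= self.APD90):
            raise ValueError("APD ordering violated")
        if self.APA <= 0 or self.dVdtmax <= 0:
            raise ValueError("APA and dVdtmax must be positive")
        if self.V20 > self.RMP + self.APA + 1e-9:
            raise ValueError("V20 cannot exceed the AP peak")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIOMARKER_NAMES])

    @classmethod
    def from_array(cls, arr) -> "BiomarkerVector":
        return cls(**dict(zip(BIOMARKER_NAMES, np.asarray(arr, dtype=float))))


@dataclass(frozen=True)
class Rejection:
    """Outcome of a discarded AP (or failed simulation)."""

    reason: str
    detail: str = ""


ForwardOutcome = Union[BiomarkerVector, Rejection]


class SimulationFailure(RuntimeError):
    def __init__(self, theta, message):
        super().__init__(message)
        self.theta = theta


def _integrate(y0, p, t_span, solver, dense=False, t_eval=None):
    sol = solve_ivp(
        crn.rhs, t_span, y0, method=solver.method, args=(p,),
        max_step=solver.max_step, rtol=solver.rtol, atol=solver.atol(),
        dense_output=dense, t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationFailure(None, f"stiff solver failed: {sol.message}")
    return sol


def _one_beat(y0, theta_arr, tau_h, protocol, solver, record=False):
    """Integrate one paced cycle; optionally return a sampled trace."""
    base = dict(tau_h_scale=tau_h, temperature=protocol.temperature,
                Na_o=protocol.Na_o, K_o=protocol.K_o, Ca_o=protocol.Ca_o)
    p_on = crn.pack_params(theta_arr, stim_current=protocol.amplitude, **base)
    p_off = crn.pack_params(theta_arr, stim_current=0.0, **base)

    sol_on = _integrate(y0, p_on, (0.0, protocol.duration), solver,
                        dense=record)
    sol_off = _integrate(sol_on.y[:, -1], p_off,
                         (protocol.duration, protocol.cycle_length), solver,
                         dense=record)
    y_end = sol_off.y[:, -1]
    if not record:
        return y_end, None

    # Dense sampling over the stimulus/upstroke window, 0.5 ms elsewhere.
    fine_end = min(protocol.duration + 20.0, protocol.cycle_length)
    t_fine = np.arange(0.0, fine_end, 0.02)
    t_coarse = np.arange(fine_end, protocol.cycle_length, 0.5)
    t = np.concatenate([t_fine, t_coarse, [protocol.cycle_length]])
    t = np.unique(t)

    Y = np.empty((crn.N_STATES, len(t)))
    on_mask = t <= protocol.duration
    Y[:, on_mask] = sol_on.sol(t[on_mask])
    Y[:, ~on_mask] = sol_off.sol(t[~on_mask])

    dV = np.empty(len(t))
    for i in range(len(t)):
        p = p_on if (t[i] < protocol.duration) else p_off
        dV[i] = crn.rhs(t[i], Y[:, i], p)[0]

    trace = APTrace(t=t, V=Y[0], dVdt=dV, state_final=y_end)
    return y_end, trace


def pace_to_steady_state(theta: ParameterVector,
                         protocol: StimulusProtocol = StimulusProtocol(),
                         solver: SolverConfig = DEFAULT_SOLVER,
                         initial_state: Optional[np.ndarray] = None
                         ) -> APTrace:
    """Pace until steady state, then ``extra_beats`` more; return final beat.

    Steady state means every state variable changes by at most
    ``steady_state_tol`` (relatively) between the ends of consecutive beats,
    with an absolute floor of 1e-9 for near-zero states.  If the criterion is
    not met within ``max_beats`` a warning is issued and pacing proceeds.
    """
    theta_arr = theta.to_array()
    y = crn.initial_state() if initial_state is None else np.array(initial_state)

    n_beats = None
    reached = False
    for beat in range(1, protocol.max_beats + 1):
        y_prev = y
        y, _ = _one_beat(y, theta_arr, theta.tau_h_scale, protocol, solver)
        delta = np.abs(y - y_prev)
        rel = delta / (np.abs(y_prev) + 1e-10)
        if np.all((rel <= protocol.steady_state_tol) | (delta <= 1e-9)):
            n_beats = beat
            reached = True
            break
    if not reached:
        warnings.warn(
            f"steady state not reached within {protocol.max_beats} beats; "
            "continuing with extra beats", RuntimeWarning)
        n_beats = protocol.max_beats

    for _ in range(max(protocol.extra_beats - 1, 0)):
        y, _ = _one_beat(y, theta_arr, theta.tau_h_scale, protocol, solver)
    # Record the last of the extra beats (or the next beat if extra_beats=0).
    y, trace = _one_beat(y, theta_arr, theta.tau_h_scale, protocol, solver,
                         record=True)
    trace.beats_to_steady_state = n_beats
    trace.steady_state_reached = reached
    return trace


def extract_biomarkers(trace: APTrace,
                       stim_duration: float = 2.0) -> ForwardOutcome:
    """Compute the seven AP biomarkers from one paced beat.

    RMP is the potential immediately before the stimulus (the first sample);
    APA the peak above RMP; dV/dt_max the maximum upstroke derivative;
    APDx runs from the activation time (instant of dV/dt_max) to the first
    crossing of peak - x% of APA, located by linear interpolation.  APs that
    never exceed -30 mV, never repolarize to RMP + 0.1 APA, or depolarize
    spontaneously after repolarization are rejected with a reason.
    """
    t, V = trace.t, trace.V
    rmp = V[0]
    if rmp >= EXCITATION_THRESHOLD:
        # excitation means crossing -30 mV from a polarized rest; a cell
        # already sitting above the threshold has no AP to measure
        return Rejection("no-excitation",
                         f"resting potential {rmp:.2f} mV is not below "
                         f"{EXCITATION_THRESHOLD} mV")
    peak_idx = int(np.argmax(V))
    peak = V[peak_idx]
    if peak <= EXCITATION_THRESHOLD:
        return Rejection("no-excitation",
                         f"peak {peak:.2f} mV never exceeded "
                         f"{EXCITATION_THRESHOLD} mV")
    apa = peak - rmp

    if trace.dVdt is not None:
        up = slice(0, peak_idx + 1)
        k = int(np.argmax(trace.dVdt[up]))
        dvdt_max = float(trace.dVdt[k])
        act_time = float(t[k])
    else:
        # Raw sampled trace: use per-interval slopes (exact for
        # piecewise-linear traces); activation at the interval start.
        slopes = np.diff(V) / np.diff(t)
        k = int(np.argmax(slopes[:max(peak_idx, 1)]))
        dvdt_max = float(slopes[k])
        act_time = float(t[k])
    if dvdt_max <= 0:
        return Rejection("no-excitation", "no depolarizing upstroke")

    def crossing_after(level, start_idx):
        """First downward crossing of `level` after start_idx (linear interp)."""
        for i in range(start_idx, len(t) - 1):
            if V[i] > level >= V[i + 1]:
                frac = (V[i] - level) / (V[i] - V[i + 1])
                return t[i] + frac * (t[i + 1] - t[i]), i + 1
        return None, None

    repol_level = rmp + 0.1 * apa  # == peak - 0.9 * APA
    t90, idx90 = crossing_after(repol_level, peak_idx)
    if t90 is None:
        return Rejection("no-repolarization",
                         f"never re-crossed RMP + 0.1 APA = {repol_level:.2f} mV")

    # Spontaneous depolarization: any local maximum back above the
    # repolarization level after the AP has repolarized below it.
    after = V[idx90:]
    if len(after) > 2:
        interior = after[1:-1]
        is_peak = (interior > after[:-2]) & (interior >= after[2:])
        if np.any(is_peak & (interior > repol_level)):
            return Rejection("spontaneous-depolarization",
                             "secondary peak above RMP + 0.1 APA")

    t20, _ = crossing_after(peak - 0.20 * apa, peak_idx)
    t50, _ = crossing_after(peak - 0.50 * apa, peak_idx)
    if t20 is None or t50 is None:
        return Rejection("no-repolarization", "incomplete repolarization")

    apd20 = t20 - act_time
    apd50 = t50 - act_time
    apd90 = t90 - act_time
    if apd20 <= 0:
        return Rejection("no-excitation", "non-positive APD20")
    v20 = float(np.interp(act_time + 0.2 * apd90, t, V))
    trace.activation_time = act_time
    return BiomarkerVector(APD20=apd20, APD50=apd50, APD90=apd90, APA=apa,
                           RMP=rmp, V20=v20, dVdtmax=dvdt_max)


def forward_map(theta: ParameterVector,
                protocol: StimulusProtocol = StimulusProtocol(),
                solver: SolverConfig = DEFAULT_SOLVER) -> ForwardOutcome:
    """The forward map M: theta -> biomarkers (or a rejection outcome).

    Deterministic: identical inputs under a fixed solver configuration yield
    identical biomarkers.  Solver failures and biomarker rejections are both
    reported as :class:`Rejection` (an invalid model, density zero downstream).
    """
    try:
        trace = pace_to_steady_state(theta, protocol, solver)
    except SimulationFailure as exc:
        return Rejection("simulation-failure", str(exc))
    return extract_biomarkers(trace, stim_duration=protocol.duration)


def diastolic_threshold(theta: ParameterVector,
                        protocol: StimulusProtocol = StimulusProtocol(),
                        solver: SolverConfig = DEFAULT_SOLVER,
                        resolution: float = 1.0,
                        ceiling: float = 20000.0,
                        rest_time: float = 0.0) -> float:
    """Minimum stimulus magnitude (pA) eliciting an AP from the rested model.

    The rested state is the model's published resting initial conditions;
    a positive ``rest_time`` additionally lets the model sit unstimulated
    for that many ms under the protocol's bath conditions first.  A single
    pulse of the protocol's duration is applied and the peak potential over
    the following window examined; the threshold is bisected to within
    ``resolution`` pA.
    """
    theta_arr = theta.to_array()
    base = dict(tau_h_scale=theta.tau_h_scale,
                temperature=protocol.temperature, Na_o=protocol.Na_o,
                K_o=protocol.K_o, Ca_o=protocol.Ca_o)
    y0 = crn.initial_state()
    if rest_time > 0:
        p_rest = crn.pack_params(theta_arr, stim_current=0.0, **base)
        y0 = _integrate(y0, p_rest, (0.0, rest_time), solver).y[:, -1]

    window = min(protocol.cycle_length, 400.0)

    def excites(magnitude: float) -> bool:
        p_on = crn.pack_params(theta_arr, stim_current=-magnitude, **base)
        p_off = crn.pack_params(theta_arr, stim_current=0.0, **base)
        sol_on = _integrate(y0, p_on, (0.0, protocol.duration), solver)
        t_eval = np.arange(protocol.duration, window, 0.5)
        sol_off = _integrate(sol_on.y[:, -1], p_off,
                             (protocol.duration, window), solver,
                             t_eval=t_eval)
        peak = max(sol_on.y[0].max(), sol_off.y[0].max())
        return peak > EXCITATION_THRESHOLD

    lo, hi = 0.0, 1000.0
    while not excites(hi):
        hi *= 2.0
        if hi > ceiling:
            raise SimulationFailure(theta, "model inexcitable within the "
                                           f"{ceiling} pA search ceiling")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if excites(mid):
            hi = mid
        else:
            lo = mid
    return hi


def batch_forward(protocol: StimulusProtocol = StimulusProtocol(),
                  solver: SolverConfig = DEFAULT_SOLVER,
                  include_tau_h: bool = False):
    """Vectorized adapter of the mechanistic forward map.

    Returns a callable mapping an (n, d) parameter array (d = 11, or 12 when
    ``include_tau_h``) to a biomarker array plus validity mask, the calling
    convention used by the SMC and range-calibration machinery.
    """
    def forward(theta: np.ndarray):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        Y = np.zeros((theta.shape[0], len(BIOMARKER_NAMES)))
        valid = np.zeros(theta.shape[0], dtype=bool)
        for i, row in enumerate(theta):
            out = forward_map(ParameterVector.from_array(row), protocol,
                              solver)
            if isinstance(out, BiomarkerVector):
                Y[i] = out.to_array()
                valid[i] = True
        return Y, valid

    return forward


def apply_drug_block(theta: ParameterVector, current_name: str,
                     block_fraction: float) -> ParameterVector:
    """Scale one current's multiplier by (1 - block_fraction)."""
    if current_name not in PARAMETER_NAMES:
        raise ValueError(f"unknown current {current_name!r}; expected one of "
                         f"{PARAMETER_NAMES}")
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block_fraction must lie in [0, 1]")
    if block_fraction == 0.0:
        return theta
    return replace(theta, **{current_name:
                             getattr(theta, current_name)
                             * (1.0 - block_fraction)})
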