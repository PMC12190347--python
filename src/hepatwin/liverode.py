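"""Mechanistic model of liver regeneration after partial hepatectomy.

Hepatocytes occupy three states — quiescent (Q), primed (P) and replicating
(R) — coupled to a cytokine/growth-factor cascade.  Removing a fraction f of
the liver raises the metabolic load per hepatocyte m = M/N (M constant
whole-body demand, N = Q+P+R), which drives TNF and growth-factor (GF)
production.  TNF degrades the extracellular matrix (ECM, via MMPs) and
induces IL-6; IL-6 activates STAT3 (JAK implicit), which transcribes SOCS3
(negative feedback on its own activation) and immediate-early (IE) genes.
IE signalling above its basal level primes quiescent cells; free GF drives
primed cells into replication; the ECM both sequesters GF and reverts primed
cells to quiescence; replicating cells divide (k_div) and return to
quiescence as the cascade subsides.  Liver volume is read out as
V = Q + h_P*P + h_R*R, with h_P, h_R >= 1 encoding hypertrophy of primed and
replicating cells.

State variables are dimensionless: cell populations are fractions of the
pre-resection total, and molecular species are normalized so the quiescent
basal level is 1.  Time is in hours.

Default rate constants are a calibration of this package, chosen so that
(i) the quiescent state is an exact stable fixed point, (ii) a 60% resection
recovers at least 90% of liver volume within 12 months, and (iii) peak
replication occurs between 1 and 10 days — the proliferative window of
liver regeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .grid import TimeGrid

STATE_FIELDS = ("Q", "P", "R", "TNF", "IL6", "STAT3", "SOCS3", "IE", "GF", "ECM")
STATE_DIM = len(STATE_FIELDS)


@dataclass
class LiverState:
    """Cell-population fractions and normalized molecular levels."""

    Q: float
    P: float
    R: float
    TNF: float
    IL6: float
    STAT3: float
    SOCS3: float
    IE: float
    GF: float
    ECM: float

    @property
    def N(self) -> float:
        return self.Q + self.P + self.R

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def state_vector(state: LiverState) -> np.ndarray:
    """Fixed-order vector (Q, P, R, TNF, IL6, STAT3, SOCS3, IE, GF, ECM)."""
    return np.array([getattr(state, f) for f in STATE_FIELDS], dtype=float)


def state_from_vector(vec: np.ndarray) -> LiverState:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (STATE_DIM,):
        raise ValueError(f"state vector must have length {STATE_DIM}")
    return LiverState(**dict(zip(STATE_FIELDS, vec.tolist())))


@dataclass(frozen=True)
class OdeParams:
    """Rate constants of the regeneration model (units 1/h where a rate).

    Molecular production (kappa) / decay (lam) pairs are set so every basal
    level is exactly 1 at metabolic load m = 1; ``ie_basal`` is the priming
    threshold — only the IE excess above it moves cells out of quiescence,
    which makes the quiescent state an exact fixed point.
    """

    # cytokine cascade
    kappa_T: float = 0.2      # TNF production per unit metabolic load
    lam_T: float = 0.2        # TNF decay
    kappa_I: float = 0.3      # IL-6 production per unit TNF
    lam_I: float = 0.3        # IL-6 decay
    kappa_S: float = 0.4      # STAT3 activation per unit IL-6
    lam_S: float = 0.2        # STAT3 decay
    gamma_SOCS: float = 1.0   # SOCS3 inhibition of STAT3 activation
    kappa_C: float = 0.05     # SOCS3 transcription per unit STAT3
    lam_C: float = 0.05       # SOCS3 decay
    kappa_E: float = 0.25     # IE transcription per unit STAT3
    lam_E: float = 0.25       # IE decay
    # growth factor / ECM
    kappa_G: float = 0.10     # GF production per unit metabolic load
    lam_G: float = 0.02       # free GF decay
    k_up: float = 0.08        # GF sequestration by ECM
    k_syn: float = 0.004      # ECM synthesis
    k_deg: float = 0.004      # ECM degradation per unit TNF (MMP activity)
    # cell-state transitions
    alpha0: float = 0.05      # Q->P priming per unit IE excess
    ie_basal: float = 1.0     # basal IE level; priming threshold
    beta0: float = 0.02       # P->R transition per unit free GF
    theta_R: float = 0.1      # R->Q requiescence
    theta_P: float = 0.05     # P->Q reversion per unit ECM
    k_div: float = 0.02       # replication growth rate
    delta_P: float = 0.001    # apoptosis of primed cells
    delta_R: float = 0.001    # apoptosis of replicating cells
    # readout / demand
    h_P: float = 1.5          # hypertrophy weight of primed cells
    h_R: float = 1.5          # hypertrophy weight of replicating cells
    M: float = 1.0            # whole-body metabolic demand

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class Trajectory:
    """Solution of the model on a time grid (hours)."""

    times: np.ndarray           # (T,)
    states: np.ndarray          # (T, STATE_DIM) in STATE_FIELDS order
    params: OdeParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def volume(self) -> np.ndarray:
        p = self.params
        return (self.component("Q") + p.h_P * self.component("P")
                + p.h_R * self.component("R"))

    @property
    def N(self) -> np.ndarray:
        return self.states[:, :3].sum(axis=1)

    def state_at(self, index: int) -> LiverState:
        return state_from_vector(self.states[index])


def rhs(y: np.ndarray, params: OdeParams) -> np.ndarray:
    """Time derivative of the state vector (STATE_FIELDS order)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs")
    p = params
    Q, P, R, TNF, IL6, STAT3, SOCS3, IE, GF, ECM = y
    N = Q + P + R
    m = p.M / N
    ie_excess = max(IE - p.ie_basal, 0.0)

    dTNF = p.kappa_T * m - p.lam_T * TNF
    dIL6 = p.kappa_I * TNF - p.lam_I * IL6
    dSTAT3 = p.kappa_S * IL6 / (1.0 + p.gamma_SOCS * SOCS3) - p.lam_S * STAT3
    dSOCS3 = p.kappa_C * STAT3 - p.lam_C * SOCS3
    dIE = p.kappa_E * STAT3 - p.lam_E * IE
    dGF = p.kappa_G * m - p.lam_G * GF - p.k_up * ECM * GF
    dECM = p.k_syn - p.k_deg * TNF * ECM
    dQ = -p.alpha0 * ie_excess * Q + p.theta_R * R + p.theta_P * ECM * P
    dP = (p.alpha0 * ie_excess * Q - p.beta0 * GF * P
          - p.theta_P * ECM * P - p.delta_P * P)
    dR = p.beta0 * GF * P + p.k_div * R - p.theta_R * R - p.delta_R * R
    return np.array([dQ, dP, dR, dTNF, dIL6, dSTAT3, dSOCS3, dIE, dGF, dECM])


def _basal_closed_form(params: OdeParams) -> np.ndarray:
    """Closed-form quiescent candidate with Q = 1, P = R = 0, m = 1."""
    p = params
    if p.lam_T <= 0 or p.lam_I <= 0 or p.lam_S <= 0 or p.lam_C <= 0 or p.lam_E <= 0:
        raise ValueError("decay rates must be positive for a finite fixed point")
    TNF = p.kappa_T * p.M / p.lam_T
    IL6 = p.kappa_I * TNF / p.lam_I
    # STAT3 solves lam_S * S * (1 + gamma * kappa_C/lam_C * S) = kappa_S * IL6
    a = p.lam_S * p.gamma_SOCS * p.kappa_C / p.lam_C
    b = p.lam_S
    c = -p.kappa_S * IL6
    STAT3 = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a) if a > 0 else -c / b
    SOCS3 = p.kappa_C * STAT3 / p.lam_C
    IE = p.kappa_E * STAT3 / p.lam_E
    if TNF <= 0:
        if p.k_syn > 0:
            raise ValueError("ECM has no finite fixed point with zero basal TNF")
        ECM = 0.0
    else:
        ECM = p.k_syn / (p.k_deg * TNF)
    GF = p.kappa_G * p.M / (p.lam_G + p.k_up * ECM)
    return np.array([1.0, 0.0, 0.0, TNF, IL6, STAT3, SOCS3, IE, GF, ECM])


def quiescent_steady_state(params: OdeParams, tol: float = 1e-8) -> LiverState:
    """Pre-resection fixed point (Q = 1, P = R = 0), polished by root finding.

    Raises if the closed-form candidate is not a genuine fixed point — e.g.
    when basal IE exceeds the priming threshold, so quiescence cannot hold.
    """
    guess = _basal_closed_form(params)
    if guess[STATE_FIELDS.index("IE")] > params.ie_basal + 1e-12:
        raise ValueError(
            "basal IE exceeds the priming threshold; no quiescent fixed point"
        )
    # polish molecular components with Q, P, R pinned
    mol = slice(3, STATE_DIM)

    def f(x: np.ndarray) -> np.ndarray:
        y = guess.copy()
        y[mol] = x
        return rhs(y, params)[mol]

    sol = root(f, guess[mol], method="hybr", tol=1e-13)
    fixed = guess.copy()
    fixed[mol] = sol.x
    resid = np.linalg.norm(rhs(fixed, params))
    if resid >= tol:
        raise ValueError(
            f"no quiescent fixed point found (residual {resid:.3e}); "
            f"params may be inconsistent"
        )
    return state_from_vector(fixed)


def apply_resection(state: LiverState, f: float) -> LiverState:
    """Remove fraction ``f`` of the liver: Q -> (1-f) Q, P = R = 0.

    Molecular levels are continuous across the resection instant; the
    metabolic load jumps implicitly through N.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("resected fraction must satisfy 0 <= f < 1")
    d = state.as_dict()
    d["Q"] = (1.0 - f) * d["Q"]
    d["P"] = 0.0
    d["R"] = 0.0
    return LiverState(**d)


def simulate(
    params: OdeParams,
    state0: LiverState,
    grid: TimeGrid | np.ndarray,
    *,
    t_start: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model to the requested hours (stiff-capable LSODA).

    ``grid`` is a :class:`TimeGrid` (post-resection hours are used) or an
    array of hours.  Integration starts at ``t_start`` (default: the first
    requested hour).  Small negative undershoots are clipped at 0; an
    undershoot beyond 1e-9 triggers a warning.
    """
    if isinstance(grid, TimeGrid):
        hours = grid.hours_array
    else:
        hours = np.asarray(grid, dtype=float)
    if hours.ndim != 1 or hours.size == 0:
        raise ValueError("grid must contain at least one time point")
    if np.any(np.diff(hours) <= 0) and hours.size > 1:
        raise ValueError("requested hours must be strictly increasing")
    y0 = state_vector(state0)
    if np.any(y0 < 0):
        raise ValueError("initial state has negative components")
    t0 = float(hours[0]) if t_start is None else float(t_start)
    if hours[0] < t0:
        raise ValueError("requested hours precede the integration start")

    eval_hours = hours[hours > t0]
    if eval_hours.size:
        sol = solve_ivp(
            lambda _, y: rhs(y, params),
            (t0, float(eval_hours[-1])),
            y0,
            method="LSODA",
            t_eval=eval_hours,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last = sol.t[-1] if sol.t.size else t0
            raise RuntimeError(
                f"integration failed at t = {last:.3g} h: {sol.message}"
            )
        integrated = sol.y.T
    else:
        integrated = np.empty((0, STATE_DIM))
    n_at_start = hours.size - eval_hours.size  # points requested at exactly t0
    states = np.vstack([np.tile(y0, (n_at_start, 1)), integrated])
    undershoot = -states.min()
    if undershoot > 1e-9:
        warnings.warn(
            f"state undershoot {undershoot:.2e} clipped to 0", stacklevel=2
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(hours, states, params)


def simulate_resection(
    params: OdeParams,
    f: float,
    grid: TimeGrid,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Full study trajectory: basal state at pre-resection samples, then the
    post-resection transient on the post-operative grid points."""
    basal = quiescent_steady_state(params)
    post_state = apply_resection(basal, f)
    hours = grid.hours_array
    post_idx = grid.postop_indices
    states = np.tile(state_vector(basal), (len(hours), 1))
    if len(post_idx):
        tr = simulate(
            params, post_state, hours[post_idx], t_start=0.0,
            rtol=rtol, atol=atol,
        )
        states[post_idx] = tr.states
    return Trajectory(hours, states, params)
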