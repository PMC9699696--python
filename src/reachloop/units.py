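"""Firing-rate unit models.

Four unit kinds appear in the circuit:

* sigmoidal units (most populations): tau_u * du/dt = sigma(I) - u with
  sigma a logistic function of the delayed, weighted input sum;
* noisy sigmoidal units: the same relaxation plus additive white noise
  (a Langevin equation, integrated with Euler-Maruyama);
* rectified-logarithm afferent units (population A):
  tau_a * da/dt = log([1 + I - T]_+) - a, clamped at zero so firing rates
  stay non-negative;
* the ACT/CHG pair implementing the exploration controller: ACT is a leaky
  integrator of the total error with an activity-dependent growth term and a
  fast reset commanded by CHG, a change detector whose synapses track the
  magnitude of the derivative of the prescribed sensory pattern.

All functions here are pure and operate on scalars or NumPy arrays; the
simulation engine reproduces the same expressions inside its compiled loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SigmoidalParams:
    tau_u: float = 0.02      # activity time constant [s]
    beta: float = 4.0        # sigmoid slope
    eta: float = 0.5         # sigmoid threshold
    sigma_noise: float = 0.0  # Langevin noise amplitude (0 -> deterministic)

    def __post_init__(self):
        if self.tau_u <= 0:
            raise ValueError("tau_u must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.sigma_noise < 0:
            raise ValueError("noise amplitude must be non-negative")


@dataclass
class LogAfferentParams:
    tau_a: float = 0.01      # [s]
    threshold: float = 0.0   # T in the rectified-log activation
    input_scale: float = 1.0

    def __post_init__(self):
        if self.tau_a <= 0:
            raise ValueError("tau_a must be positive")


@dataclass
class ACTParams:
    theta_act: float = 0.55   # error threshold on sigma(I)
    tau_act: float = 4.0      # growth time constant [s]
    gamma: float = 2.0        # rate-of-increase modulation weight
    tau_tilde: float = 1.0    # low-pass for the filtered input I~ [s]
    reset_rate: float = 40.0  # 1/s, fast decay while CHG is active
    chg_gate: float = 0.1     # CHG input level that triggers the reset
    beta: float = 6.0         # slope of ACT's own sigmoid
    eta: float = 0.4          # threshold of ACT's own sigmoid

    def __post_init__(self):
        if not 0 < self.theta_act < 1:
            raise ValueError("theta_act must lie in (0, 1)")


@dataclass
class AdaptationState:
    """Slow variables of one interneuron's adaptation current."""
    u_slow: float = 0.0
    i_adapt: float = 0.0


@dataclass
class AdaptationParams:
    tau_slow: float = 2.0        # [s], both for u_slow and the I_adapt decay
    act_threshold: float = 0.8   # ACT input level that triggers adaptation
    reset_below: float = 0.2     # I_adapt below this value allows a new trigger


# ---------------------------------------------------------------------------


def sigmoid(I, beta, eta):
    """Logistic rate function 1 / (1 + exp(beta * (I - eta))) ... increasing.

    Note the sign convention: the rate *increases* with I, i.e. the exponent
    is -beta (I - eta).
    """
    return 1.0 / (1.0 + np.exp(-beta * (np.asarray(I, float) - eta)))


def sigmoidal_unit_deriv(u, I, p: SigmoidalParams):
    """du/dt for a (noise-free) sigmoidal unit given its summed input I."""
    return (sigmoid(I, p.beta, p.eta) - u) / p.tau_u


def afferent_unit_deriv(a, I, p: LogAfferentParams):
    """da/dt for a rectified-log unit.  The activation log(1 + I - T) is
    clamped at zero so the steady state is never negative."""
    arg = 1.0 + p.input_scale * np.asarray(I, float) - p.threshold
    act = np.log(np.maximum(arg, 1.0))
    return (act - a) / p.tau_a


def act_dynamics(a, I, I_tilde, chg_input, p: ACTParams):
    """da/dt of the ACT exploration unit.

    While the CHG change-detector is active the unit resets fast; otherwise it
    decays when the (sigmoided) error is below threshold and grows toward 1
    when above, with growth boosted by a recent *increase* of the error
    (sigma(I) - sigma(I~), where I~ is the module-maintained low-pass of I).
    """
    s = sigmoid(I, p.beta, p.eta)
    if chg_input > p.chg_gate:
        return -p.reset_rate * a
    if s < p.theta_act:
        return a * (s - p.theta_act)
    sdot = s - sigmoid(I_tilde, p.beta, p.eta)
    return (s - p.theta_act) * (1.0 - a + p.gamma * sdot) / p.tau_act


def adaptation_update(state: AdaptationState, act_signal, u, dt,
                      p: AdaptationParams) -> AdaptationState:
    """One Euler step of the slow adaptation variables of a C (or M) unit.

    u_slow low-passes the unit's activity.  When the ACT signal is high and
    the previous adaptation has worn off, the inhibitory current jumps to
    u_slow**2 - the most active units receive the most inhibition, which
    shifts the dominant pattern and enlarges exploratory oscillations.
    """
    u_slow = state.u_slow + dt * (u - state.u_slow) / p.tau_slow
    if act_signal > p.act_threshold and state.i_adapt < p.reset_below:
        i_adapt = u_slow ** 2
    else:
        i_adapt = state.i_adapt - dt * state.i_adapt / p.tau_slow
    return AdaptationState(u_slow=u_slow, i_adapt=i_adapt)


def chg_weight_deriv(w, presyn_deriv, alpha, tau=0.02):
    """dw/dt of a CHG synapse: fast relaxation toward alpha * |ds/dt|.

    The change detector is written as an instantaneous assignment in the
    model description; a first-order relaxation with a fast time constant
    keeps the whole system an ODE while preserving the phasic response.
    """
    return (alpha * np.abs(presyn_deriv) - w) / tau
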