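"""Synaptic learning rules.

Two rules configure the loop:

* **Differential Hebbian rule** (motor-command edges, e.g. M->C and M->alpha,
  or SPA->M in the cortical-learning configuration).  The raw update
  correlates the *second* derivative of the presynaptic error signal with the
  lagged *first* derivative of the postsynaptic command,

      Delta = -(e''_j - <e''>) (c'_i(t - dt_lag) - <c'(t - dt_lag)>),

  so a command whose recent change preceded a deceleration of an error grows
  the corresponding weight.  Soft weight bounding (multiplication by the
  weight itself, so weights never cross zero) and multiplicative sum
  normalization toward per-row/per-column targets keep the matrix bounded:

      dw_ij/dt = alpha * w_ij * (Delta + lambda * (0.5 (zeta_sa + zeta_sb) - 1))

  with zeta_sa = w_sa / (outgoing sum of presynaptic unit j) and
  zeta_sb = w_sb / (incoming sum at postsynaptic unit i).  The sign of the
  normalization term is the stabilizing one: sums above target shrink the
  weights, sums below target grow them (see docs/methods.md on this choice).

* **Input-correlation rule** (afferent edges A->M, A->C).  dw/dt =
  alpha_IC * w * I_A * dI_PA/dt, where I_A is the unit's scaled afferent input
  and I_PA its error/command input; the weight group is then rescaled to a
  fixed sum and clipped elementwise.  Afferents that fire just before the
  error grows take over the group budget, which stabilizes the loop.

Derivatives of continuous signals are estimated by cascaded exponential
smoothers (see `DerivativeEstimator`): the difference of a fast and a slow
low-pass of x approximates x' times the difference of time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DiffHebbParams:
    alpha: float = 30.0       # learning rate
    lam: float = 30.0         # normalization strength (lambda)
    w_sa: float = 1.0         # target outgoing-sum per presynaptic unit
    w_sb: float = 1.0         # target incoming-sum per postsynaptic unit
    delta_t: float = 0.13     # causality lag [s] ~ sensorimotor loop latency
    drive_sign: float = 1.0   # sign of the Hebbian drive term (validation knob)
    tau_fast: float = 0.02    # derivative-smoother time constants [s]
    tau_mid: float = 0.04

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.w_sa <= 0 or self.w_sb <= 0:
            raise ValueError("sum targets must be positive")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


@dataclass
class InputCorrParams:
    alpha_ic: float = 10.0    # learning rate
    w_s: float = 1.0          # target group sum
    w_max: float = 0.5        # per-weight cap

    def __post_init__(self):
        if self.alpha_ic < 0:
            raise ValueError("alpha_ic must be non-negative")
        if not 0 < self.w_max <= self.w_s:
            raise ValueError("need 0 < w_max <= w_s")


class DerivativeEstimator:
    """First/second derivative estimates from cascaded exponential smoothers.

    For a signal with slowly varying derivative v, a low-pass y_tau lags the
    signal by tau * v, so (y_fast - y_mid) / (tau_mid - tau_fast) estimates v.
    Applying the same construction to the estimate yields the second
    derivative.  All states advance by explicit Euler, matching the engine.
    """

    def __init__(self, n, tau_fast=0.02, tau_mid=0.04):
        self.tau_fast = tau_fast
        self.tau_mid = tau_mid
        self.y_f = np.zeros(n)
        self.y_m = np.zeros(n)
        self.d_f = np.zeros(n)
        self.d_m = np.zeros(n)
        self._scale = 1.0 / (tau_mid - tau_fast)

    def reset(self, x):
        x = np.asarray(x, float)
        self.y_f[:] = x
        self.y_m[:] = x
        self.d_f[:] = 0.0
        self.d_m[:] = 0.0

    def update(self, x, dt):
        """Advance one step; returns (d1, d2) estimates."""
        x = np.asarray(x, float)
        self.y_f += dt * (x - self.y_f) / self.tau_fast
        self.y_m += dt * (x - self.y_m) / self.tau_mid
        d1 = (self.y_f - self.y_m) * self._scale
        self.d_f += dt * (d1 - self.d_f) / self.tau_fast
        self.d_m += dt * (d1 - self.d_m) / self.tau_mid
        d2 = (self.d_f - self.d_m) * self._scale
        return d1, d2


def diff_hebb_delta(e_ddot, c_dot_lagged, j, i):
    """Raw differential-Hebbian drive for the edge from presynaptic j to
    postsynaptic i, given population vectors of the derivative estimates."""
    e_ddot = np.asarray(e_ddot, float)
    c_dot_lagged = np.asarray(c_dot_lagged, float)
    return -(e_ddot[j] - e_ddot.mean()) * (c_dot_lagged[i] - c_dot_lagged.mean())


def diff_hebb_update(w, delta, out_sum, in_sum, p: DiffHebbParams):
    """dw/dt for one plastic edge.

    out_sum / in_sum are the current outgoing (presynaptic row) and incoming
    (postsynaptic column) weight sums of the edge's plastic group.
    """
    zeta_sa = p.w_sa / out_sum
    zeta_sb = p.w_sb / in_sum
    return p.alpha * w * (delta + p.lam * (0.5 * (zeta_sa + zeta_sb) - 1.0))


def input_corr_update(w, I_A, dI_PA_dt, dt, p: InputCorrParams):
    """One discrete update of an input-correlation weight group.

    Applies the Euler step of dw/dt = alpha_IC w I_A dI_PA/dt per weight
    (I_A entries are the per-edge presynaptic afferent activities), then
    rescales the group to sum w_s and clips at w_max.
    """
    w = np.asarray(w, float) + dt * p.alpha_ic * np.asarray(w, float) \
        * np.asarray(I_A, float) * dI_PA_dt
    s = w.sum()
    if s > 0:
        w = w * (p.w_s / s)
    return np.minimum(w, p.w_max)


def init_plastic_weights(rng, n_pre, n_post, row_sum, spread=0.5):
    """Positive uniform random weights scaled so every row sums to row_sum.

    Weights are drawn uniformly in [1 - spread, 1 + spread] before scaling,
    so all initial weights are strictly positive (soft bounding then keeps
    them so forever).
    """
    w = rng.uniform(1.0 - spread, 1.0 + spread, size=(n_pre, n_post))
    w *= row_sum / w.sum(axis=1, keepdims=True)
    return w
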