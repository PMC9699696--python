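"""Deterministic synthetic fixtures with known ground truth.

These let the analysis and plasticity modules be unit-tested without running
the simulator: cosine-tuned rate tables (known preferred directions), pure
planar rotations embedded in high dimension (known jPCA answer), additive
direction-field triples (gamma exactly zero), and scripted pre/post signal
pairs with a known causal lag for the learning rules.
"""

from __future__ import annotations

import numpy as np

from .protocols import center_out_targets
from .analysis import wrap_angle  # noqa: F401  (re-exported convenience)

FIXTURE_KINDS = ("cosine_tuned_rates", "rotational_traces",
                 "toy_direction_fields", "scripted_learning_signals")


def make_fixture(kind, seed=0, **kw):
    """Build one synthetic dataset; see the per-kind functions for fields."""
    if kind == "cosine_tuned_rates":
        return cosine_tuned_rates(seed=seed, **kw)
    if kind == "rotational_traces":
        return rotational_traces(seed=seed, **kw)
    if kind == "toy_direction_fields":
        return toy_direction_fields(seed=seed, **kw)
    if kind == "scripted_learning_signals":
        return scripted_learning_signals(seed=seed, **kw)
    raise ValueError(f"unknown fixture kind {kind!r}")


def cosine_tuned_rates(seed=0, pd_deg=(30.0,), n_targets=8, n_reps=6,
                       baseline=0.5, depth=0.3, noise=0.0):
    """Per-reach rates r = baseline + depth*cos(theta - pd) on a target ring.

    Returns dict with rates (n_reaches, n_units), labels, targets (on a
    10 cm ring around (0.3, 0.3)), center, and the generating pd_deg.
    """
    rng = np.random.default_rng(seed)
    center = np.array([0.3, 0.3])
    targets = center_out_targets(center, 0.10, n_targets)
    ang = np.arctan2(*(targets - center).T[::-1])
    labels = np.tile(np.arange(n_targets), n_reps)
    rng.shuffle(labels)
    pd = np.deg2rad(np.atleast_1d(pd_deg))
    rates = baseline + depth * np.cos(ang[labels][:, None] - pd[None, :])
    rates += noise * rng.standard_normal(rates.shape)
    return {"rates": rates, "labels": labels, "targets": targets,
            "center": center, "pd_deg": np.atleast_1d(pd_deg)}


def rotational_traces(seed=0, n_units=12, n_conditions=8, n_times=50,
                      dt=0.01, omega=2.0 * np.pi, noise=0.0):
    """Pure 2-D rotation embedded in `n_units` dims, per condition.

    Every condition follows the same angular velocity `omega` [rad/s] from a
    different phase/amplitude; the jPCA plane-1 variance fraction is 1 up to
    the added noise.  Returns (traces (J, T, I), dt, basis (I, 2)).
    """
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.standard_normal((n_units, 2)))[0]
    t = np.arange(n_times) * dt
    out = np.zeros((n_conditions, n_times, n_units))
    for j in range(n_conditions):
        amp = 1.0 + 0.5 * rng.random()
        ph = 2 * np.pi * rng.random()
        xy = np.column_stack([amp * np.cos(omega * t + ph),
                              amp * np.sin(omega * t + ph)])
        out[j] = xy @ basis.T
    out += noise * rng.standard_normal(out.shape)
    return {"traces": out, "dt": dt, "basis": basis, "omega": omega}


def toy_direction_fields(seed=0, n_grid=5, additive=True):
    """Three direction fields on a grid with D(a+b) = D(a) + D(b) exactly
    (when additive), so the gamma statistic is zero by construction."""
    from .protocols import DirectionField, field_grid
    rng = np.random.default_rng(seed)
    grid = field_grid((0.3, 0.3), 0.10, n_grid)

    def smooth_field(fp):
        v = fp - grid
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    va = smooth_field(np.array([0.38, 0.22]))
    vb = smooth_field(np.array([0.22, 0.38]))
    vab = va + vb if additive else smooth_field(np.array([0.30, 0.20]))
    fa = DirectionField(grid, va, (0,))
    fb = DirectionField(grid, vb, (1,))
    fab = DirectionField(grid, vab / np.linalg.norm(vab, axis=1, keepdims=True)
                         if additive else vab, (0, 1))
    return {(0,): fa, (1,): fb, (0, 1): fab}


def scripted_learning_signals(seed=0, n=20_000, dt=0.001, lag_steps=100,
                              coupling=-1.0, tau_e=0.2):
    """Pre/post signal pair with a known causal lag and sign.

    The postsynaptic command c (smoothed noise) drives the presynaptic
    error's *rate of change* after `lag_steps`:

        de/dt = coupling * c(t - lag) - e / tau_e

    so e'' contains coupling * c'(t - lag), and the differential-Hebbian
    drive -<e''(t) c'(t - lag)> equals -coupling * <c'^2> + O(1/tau_e):
    positive for coupling < 0 ("the command reduces the error"), and
    strongest when evaluated at the matching lag.
    """
    rng = np.random.default_rng(seed)
    c = np.zeros(n)
    e = np.zeros(n)
    x = 0.0
    for t in range(1, n):
        x += dt * (-x / 0.05) + 0.3 * np.sqrt(dt) * rng.standard_normal()
        c[t] = x
        drive = coupling * c[t - lag_steps] if t >= lag_steps else 0.0
        e[t] = e[t - 1] + dt * (drive - e[t - 1] / tau_e)
    return {"c": c, "e": e, "dt": dt, "lag_steps": lag_steps,
            "coupling": coupling}
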