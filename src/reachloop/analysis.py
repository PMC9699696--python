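"""Population analyses: preferred directions, rotational dynamics, and
direction-field linearity.

Conventions used throughout:

* a *preferred direction* (PD) vector is the gradient of a least-squares
  plane fitted to a unit's mean rates over target positions (equivalently,
  the projection onto the workspace of the downward normal of that plane);
* angles are radians internally, degrees in reported results;
* angle differences are minimal rotations in (-pi, pi].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


def wrap_angle(a):
    """Minimal rotation equivalent of an angle (radians, (-pi, pi])."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# preferred directions
# ---------------------------------------------------------------------------

def _target_means(rates, labels, n_targets):
    out = np.zeros((n_targets, rates.shape[1]))
    for k in range(n_targets):
        out[k] = rates[labels == k].mean(axis=0)
    return out


def pd_vectors(rates, labels, target_positions, center):
    """PD vectors from per-reach mean rates.

    rates : (n_reaches, n_units); labels : (n_reaches,) target index;
    target_positions : (n_targets, 2); center : (2,) hand rest position.
    Returns (n_units, 2): the fitted rate gradient per unit.
    """
    targets = np.asarray(target_positions, float) - np.asarray(center, float)
    n_targets = len(targets)
    M = _target_means(np.asarray(rates, float), np.asarray(labels), n_targets)
    X = np.column_stack([targets, np.ones(n_targets)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient target geometry for the plane fit")
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return coef[:2].T          # (n_units, 2)


def tuning_test(rates, labels, target_positions, center,
                n_shuffles=10_000, rng=None):
    """Bootstrap test of directional tuning.

    Shuffles the target identity of each reach, recomputes the PD length,
    and returns per-unit p-values: the fraction of shuffles whose PD length
    reaches the true one.  A unit is significantly tuned at the 99.9 %
    criterion when p < 0.001.
    """
    rng = np.random.default_rng(rng)
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    true_len = np.linalg.norm(
        pd_vectors(rates, labels, target_positions, center), axis=1)
    count = np.zeros(rates.shape[1])
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        ln = np.linalg.norm(
            pd_vectors(rates, perm, target_positions, center), axis=1)
        count += ln >= true_len
    return count / n_shuffles


def max_contraction_vectors(plant, targets, center=None):
    """Per-muscle 'direction of maximum contraction' over the target ring.

    v_i = sum_k [ (l_i0 - l_ik) / l_i0 ]_+ r_k, with l_i0 the muscle length
    at the center posture, l_ik at target k, and r_k the unit vector from
    the center to target k.
    """
    center = plant.hand_position(np.asarray(plant.arm.rest_q)) \
        if center is None else np.asarray(center, float)
    l0 = plant.geometry.muscle_lengths(plant.inverse_kinematics(center))
    v = np.zeros((6, 2))
    for tgt in np.asarray(targets, float):
        lk = plant.geometry.muscle_lengths(plant.inverse_kinematics(tgt))
        r = tgt - center
        r = r / np.linalg.norm(r)
        v += np.maximum((l0 - lk) / l0, 0.0)[:, None] * r[None, :]
    return v


def signed_error_weights(network):
    """(12, 6) map from per-muscle contraction errors to M units.

    Entry [j, i] is the net weight with which the "muscle i too long"
    error drives M unit j (the dual error side enters with opposite sign).
    """
    from . import network as net
    con = network.connections
    w = np.zeros((12, 6))
    for s, d, wt in zip(con.src, con.dst, con.weight):
        if net.SPA.start <= s < net.SPA.stop and net.M.start <= d < net.M.stop:
            i = s - net.SPA.start
            j = d - net.M.start
            if i < 6:
                w[j, i] += wt
            else:
                w[j, i - 6] -= wt
    return w


@dataclass
class PDPrediction:
    v_bars: np.ndarray         # (6, 2) per-muscle max-contraction vectors
    predicted: np.ndarray      # (12, 2) predicted PD per unit
    residuals_deg: np.ndarray  # minimal-rotation angle residuals
    r2: float


def predict_pd(pd_true, v_bars, weights):
    """Predict PD angles as weighted sums of muscle contraction directions.

    weights : (n_units, 6) signed error->unit map.  The coefficient of
    determination uses angle residuals scaled by each unit's relative PD
    norm (longer PD vectors are measured more reliably, so their residuals
    weigh more).
    """
    pd_true = np.asarray(pd_true, float)
    pred = np.asarray(weights, float) @ np.asarray(v_bars, float)
    th_t = np.arctan2(pd_true[:, 1], pd_true[:, 0])
    th_p = np.arctan2(pred[:, 1], pred[:, 0])
    eps = wrap_angle(th_t - th_p)
    r = np.linalg.norm(pd_true, axis=1)
    scale = r / r.mean() if r.mean() > 0 else np.ones_like(r)
    ss_res = np.sum((eps * scale) ** 2)
    ss_tot = np.sum((th_t - th_t.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    return PDPrediction(np.asarray(v_bars), pred, np.rad2deg(eps), float(r2))


def main_axis(pd):
    """Main axis of the PD distribution, degrees in [0, 180).

    Angles in the lower half-plane are reflected by +pi (axial data), then
    the axis is the direction of the length-weighted resultant.
    """
    pd = np.asarray(pd, float)
    r = np.linalg.norm(pd, axis=1)
    if np.all(r == 0):
        raise ValueError("all PD vectors are zero; main axis undefined")
    th = np.arctan2(pd[:, 1], pd[:, 0])
    th = np.where(th < 0, th + np.pi, th)
    ang = np.arctan2(np.sum(r * np.sin(th)), np.sum(r * np.cos(th)))
    return np.rad2deg(ang % np.pi)


def bimodality_test(angles, n_null=100_000, rng=None):
    """Axial (180-degree) Rayleigh test for a bimodal angle distribution.

    r = [ (sum cos 2phi)^2 + (sum sin 2phi)^2 ] / N; the null distribution
    is built from uniform angles on (0, pi).  Returns (r, p); significant
    bimodality at the 99.9 % criterion when p < 0.001.
    """
    rng = np.random.default_rng(rng)
    phi = np.asarray(angles, float)
    n = len(phi)

    def stat(a):
        return (np.cos(2 * a).sum(axis=-1) ** 2
                + np.sin(2 * a).sum(axis=-1) ** 2) / a.shape[-1]

    r = float(stat(phi))
    null = stat(rng.uniform(0, np.pi, size=(n_null, n)))
    p = float(np.mean(null >= r))
    return r, p


# ---------------------------------------------------------------------------
# rotational dynamics (jPCA)
# ---------------------------------------------------------------------------

@dataclass
class JPCAResult:
    m_hat: np.ndarray          # least-squares dynamics matrix (I, I)
    m_skew: np.ndarray
    basis: np.ndarray          # (I, 6) jPCA vectors, plane-major
    variance_fractions: np.ndarray   # per plane (3,)
    projections: np.ndarray    # (J, T-2, 2) trajectories in plane 1
    frequencies: np.ndarray    # |imag eigenvalue| per plane [rad/s]


def jpca(cond_traces, dt, n_planes=3):
    """Rotational-dynamics analysis of per-condition averaged traces.

    cond_traces : (J conditions, T times, I units), trial-averaged.  The
    cross-condition mean trace is removed per unit and time (normalization),
    the data and its central-difference derivative are stacked into
    X, Xdot (JT x I), and M_hat solves Xdot = X M by least squares.  The
    jPCA planes come from the complex-conjugate eigenvector pairs of the
    skew-symmetric part of M_hat, ordered by rotation frequency; no PCA
    preprocessing is applied.
    """
    A = np.asarray(cond_traces, float)
    J, T, I = A.shape
    A = A - A.mean(axis=0, keepdims=True)    # normalized per condition
    # central differences; trim the endpoints
    Xd = (A[:, 2:, :] - A[:, :-2, :]) / (2 * dt)
    X = A[:, 1:-1, :]
    Xf = X.reshape(J * (T - 2), I)
    Xdf = Xd.reshape(J * (T - 2), I)
    gram_rank = np.linalg.matrix_rank(Xf)
    if gram_rank < I:
        log.warning("X rank %d < %d units; least squares uses the "
                    "pseudoinverse (ridge-like minimum-norm solution)",
                    gram_rank, I)
    m_hat, *_ = np.linalg.lstsq(Xf, Xdf, rcond=None)
    m_skew = 0.5 * (m_hat - m_hat.T)

    lam, vec = np.linalg.eig(m_skew)
    order = np.argsort(-np.abs(lam.imag))
    basis = np.zeros((I, 2 * n_planes))
    freqs = np.zeros(n_planes)
    used = set()
    plane = 0
    for idx in order:
        if plane >= n_planes:
            break
        if idx in used or abs(lam[idx].imag) < 1e-15:
            continue
        conj = np.argmin(np.abs(lam - lam[idx].conjugate()))
        used.update((idx, conj))
        v = vec[:, idx]
        b1, b2 = v.real, v.imag
        b1 = b1 / np.linalg.norm(b1)
        b2 = b2 - b1 * (b1 @ b2)
        b2 = b2 / np.linalg.norm(b2)
        basis[:, 2 * plane] = b1
        basis[:, 2 * plane + 1] = b2
        freqs[plane] = abs(lam[idx].imag)
        plane += 1

    tot = np.sum(Xf ** 2)
    var = np.array([np.sum((Xf @ basis[:, 2 * p:2 * p + 2]) ** 2) / tot
                    for p in range(n_planes)])
    # report planes in order of captured variance (plane 1 = strongest
    # rotational component of the data, the quantity the analysis tracks)
    order2 = np.argsort(-var)
    var = var[order2]
    freqs = freqs[order2]
    basis = basis[:, np.concatenate([[2 * p, 2 * p + 1] for p in order2])]
    proj = np.einsum("jti,ik->jtk", X, basis[:, :2])
    return JPCAResult(m_hat, m_skew, basis, var, proj, freqs)


# ---------------------------------------------------------------------------
# direction-field linearity
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma_pairs: dict          # (a, b) -> mean angle difference [deg]
    gamma_mean: float          # mean over site pairs [deg]
    null_mean: float           # mismatched-pair null mean [deg]
    null_samples: np.ndarray
    p_value: float


def field_angle_difference(field_joint, field_a, field_b):
    """Mean |minimal angle| between D(a+b) and the vector sum D(a)+D(b)."""
    if field_joint.grid.shape != field_a.grid.shape or \
            not np.allclose(field_joint.grid, field_a.grid) or \
            not np.allclose(field_joint.grid, field_b.grid):
        raise ValueError("direction fields are on mismatched grids")
    vsum = field_a.vectors + field_b.vectors
    a_sum = np.arctan2(vsum[:, 1], vsum[:, 0])
    diff = wrap_angle(field_joint.angles() - a_sum)
    return float(np.rad2deg(np.mean(np.abs(diff))))


def gamma_linearity(fields, n_shuffles=400, rng=None):
    """Linearity of direction-field summation over all site pairs.

    `fields` maps site tuples to DirectionField: () for rest, (i,) single
    sites, (i, j) joint stimulation.  gamma_mean is the average angle
    difference between each joint field and its own summed single fields;
    the null reassigns each joint field to the summed fields of a different,
    randomly chosen pair (400 reassignments), and linearity is significant
    at the 99 % criterion when gamma_mean is below the 1st percentile of
    the null means.
    """
    rng = np.random.default_rng(rng)
    pairs = sorted(k for k in fields if len(k) == 2)
    gp = {}
    for (a, b) in pairs:
        gp[(a, b)] = field_angle_difference(fields[(a, b)], fields[(a,)],
                                            fields[(b,)])
    gmean = float(np.mean(list(gp.values())))

    null = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        vals = []
        for (a, b) in pairs:
            while True:
                c, d = pairs[rng.integers(len(pairs))]
                if (c, d) != (a, b):
                    break
            vals.append(field_angle_difference(fields[(a, b)], fields[(c,)],
                                               fields[(d,)]))
        null[s] = np.mean(vals)
    p = float(np.mean(null <= gmean))
    return GammaResult(gp, gmean, float(null.mean()), null, p)


# ---------------------------------------------------------------------------
# reach metrics
# ---------------------------------------------------------------------------

def reach_metrics(trace, reach_slices, targets, threshold=0.10):
    """Per-reach time-averaged error, speed profile, and success flag."""
    t = trace.time - trace.time[0]
    hand = trace.hand
    speed = trace.hand_speed
    out = []
    for k, t_on, t_off in reach_slices:
        m = (t >= t_on) & (t < t_off)
        err = float(np.linalg.norm(hand[m] - np.asarray(targets[k]),
                                   axis=1).mean())
        out.append({"target": int(k), "error": err,
                    "speed": speed[m], "success": err < threshold})
    return out
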