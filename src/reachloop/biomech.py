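"""Two-link planar arm with six Hill-type muscles and proprioceptors.

The arm is a compound double pendulum (uniform 1-kg cylinders, no gravity,
viscous joint friction) actuated by six straight-line muscles: a biarticular
flexor/extensor pair and monoarticular flexor/extensor pairs at the shoulder
and elbow.  Each muscle carries a muscle spindle (one static and one dynamic
nuclear-bag fiber driving the Ia and II afferents) and a Golgi tendon organ
(Ib afferent).

Muscle indexing and antagonist pairs (0,3), (1,4), (2,5)::

    0  biarticular flexor  (biceps)      3  biarticular extensor (triceps)
    1  shoulder flexor                   4  shoulder extensor
    2  elbow flexor                      5  elbow extensor

All viscoelastic constants are per-muscle configurable; defaults were tuned so
that the closed-loop rest posture (hand at (0.3, 0.3) m, elbow at (0.3, 0))
is a stable equilibrium and full drive produces a few N.m of joint torque.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels


@dataclass
class ArmParams:
    """Rigid-body parameters of the two-link arm."""
    m1: float = 1.0          # upper-arm mass [kg]
    m2: float = 1.0          # forearm mass [kg]
    L1: float = 0.3          # shoulder->elbow length [m]
    L2: float = 0.3          # elbow->hand length [m]
    viscosity: float = 3.0   # joint viscous friction [N.m.s/rad]
    rest_q: tuple = (0.0, np.pi / 2)  # rest joint angles -> hand (0.3, 0.3)

    def __post_init__(self):
        if min(self.m1, self.m2, self.L1, self.L2, self.viscosity) <= 0:
            raise ValueError("arm masses, lengths and friction must be positive")


@dataclass
class MuscleParams:
    """Hill-type muscle constants, one value per muscle (broadcast if scalar)."""
    k_se: float = 200.0      # series stiffness [N/m]
    k_pe: float = 60.0       # parallel stiffness [N/m]
    b: float = 20.0          # parallel damping [N.s/m]
    gain: float = 60.0       # input gain g [N per unit drive]

    def arrays(self):
        return tuple(np.full(6, v, dtype=float)
                     for v in (self.k_se, self.k_pe, self.b, self.gain))


@dataclass
class SpindleParams:
    """Static/dynamic bag-fiber constants and Ia/II output mixing."""
    k_se_s: float = 200.0
    k_pe_s: float = 100.0
    b_s: float = 10.0
    k_se_d: float = 200.0
    k_pe_d: float = 100.0
    b_d: float = 100.0       # high damping -> velocity sensitivity of Ia
    l0_s: float = 0.45       # bag rest length / muscle rest length
    l0_d: float = 0.45
    g_ia: float = 30.0
    f_s_ia: float = 0.5      # fraction of Ia from the static bag serial element
    g_ii: float = 30.0
    f_s_ii: float = 0.3


@dataclass
class GTOParams:
    """Golgi tendon organ (Ib afferent)."""
    g_ib: float = 0.4
    t0: float = 10.0         # tension scale [N]
    tau_ib: float = 0.03     # output filter [s]


# default muscle endpoints: (frame, x, y) proximal then distal.
# frame 0 = torso/world, 1 = upper arm (x along shoulder->elbow), 2 = forearm.
_DEFAULT_PATHS = [
    ((0, -0.02, 0.04), (2, 0.04, 0.02)),     # 0 biarticular flexor
    ((0, -0.02, 0.04), (1, 0.12, 0.02)),     # 1 shoulder flexor
    ((1, 0.15, 0.02), (2, 0.03, 0.015)),     # 2 elbow flexor
    ((0, -0.02, -0.04), (2, -0.03, -0.01)),  # 3 biarticular extensor (olecranon)
    ((0, -0.02, -0.04), (1, 0.12, -0.02)),   # 4 shoulder extensor
    ((1, 0.15, -0.02), (2, -0.03, -0.005)),  # 5 elbow extensor
]


@dataclass
class Geometry:
    """Muscle attachment points and the length/moment-arm map.

    The attachment points define each muscle's rest length and rest moment
    arms through the straight chord between them.  The simulated path is a
    joint-capsule *pulley*: the moment arms stay at their rest-chord values
    over the whole workspace, so a muscle's action never reverses sign (a
    straight chord crosses the joint center at extreme postures).
    """
    paths: list = field(default_factory=lambda: [p for p in _DEFAULT_PATHS])
    L1: float = 0.3
    rest_q: tuple = (0.0, np.pi / 2)

    def __post_init__(self):
        self.pframe = np.array([[p[0][0], p[1][0]] for p in self.paths],
                               dtype=np.int64)
        self.pxy = np.array([[[p[0][1], p[0][2]], [p[1][1], p[1][2]]]
                             for p in self.paths], dtype=float)
        self.qrest = np.asarray(self.rest_q, dtype=float)
        self.ml_rest, self.darm = _kernels.chord_geometry(
            self.qrest[0], self.qrest[1], self.pframe, self.pxy, self.L1)
        self.ml_rest = np.ascontiguousarray(self.ml_rest)
        self.darm = np.ascontiguousarray(self.darm)

    def muscle_lengths(self, q, qd=None):
        """Muscle lengths (and velocities, if qd given) at joint angles q."""
        lengths, dldq = _kernels.muscle_geometry(
            float(q[0]), float(q[1]), self.ml_rest, self.darm, self.qrest)
        if np.any(lengths <= 0):
            raise ValueError("singular muscle geometry: non-positive length")
        if qd is None:
            return lengths
        xdot = dldq @ np.asarray(qd, dtype=float)
        return lengths, xdot

    def chord_lengths(self, q):
        """Straight-line attachment-to-attachment distances (diagnostic)."""
        lengths, _ = _kernels.chord_geometry(
            float(q[0]), float(q[1]), self.pframe, self.pxy, self.L1)
        return lengths

    def moment_arms(self, q):
        """dL/dq rows; torque from tension T_m is -T_m * dldq[m]."""
        _, dldq = _kernels.muscle_geometry(
            float(q[0]), float(q[1]), self.ml_rest, self.darm, self.qrest)
        return dldq


class PlanarArm:
    """The assembled plant: rigid links + muscles + spindles + GTOs.

    Exposes the plant state as the 28-vector documented in `_kernels` and
    wraps the compiled dynamics.  `calibrate_rest` must run before simulating
    (the constructor does it) so that all tensions vanish at the rest posture.
    """

    def __init__(self, arm: ArmParams | None = None,
                 muscles: MuscleParams | None = None,
                 spindles: SpindleParams | None = None,
                 gto: GTOParams | None = None,
                 geometry: Geometry | None = None):
        self.arm = arm or ArmParams()
        self.muscles = muscles or MuscleParams()
        self.spindles = spindles or SpindleParams()
        self.gto = gto or GTOParams()
        self.geometry = geometry or Geometry(L1=self.arm.L1)
        self.calibrate_rest()

    # -- calibration --------------------------------------------------------
    def calibrate_rest(self):
        """Set muscle and bag rest lengths from the rest posture.

        After calibration the unforced plant has zero tension, hence zero
        acceleration, at the rest posture: a fixed point by construction.
        """
        q0 = np.asarray(self.arm.rest_q, dtype=float)
        rest = self.geometry.muscle_lengths(q0)
        if np.any(rest <= 0):
            raise ValueError("degenerate muscle geometry at the rest posture")
        self.rest_lengths = rest
        sp = self.spindles
        self.rest_s = sp.l0_s * rest
        self.rest_d = sp.l0_d * rest
        self._pack()

    def _pack(self):
        mp = self.muscles
        sp = self.spindles
        kse, kpe, bdm, gain = mp.arrays()
        full6 = lambda v: np.full(6, v, dtype=float)
        self._args = (
            self.geometry.ml_rest, self.geometry.darm, self.geometry.qrest,
            self.arm.L1, self.arm.L2, self.arm.m1, self.arm.m2,
            self.arm.viscosity,
            kse, kpe, bdm, gain, self.rest_lengths.copy(),
            full6(sp.k_se_s), full6(sp.k_pe_s), full6(sp.b_s), self.rest_s.copy(),
            full6(sp.k_se_d), full6(sp.k_pe_d), full6(sp.b_d), self.rest_d.copy(),
            full6(self.gto.g_ib), full6(self.gto.t0), full6(self.gto.tau_ib),
        )
        self._aff_args = (
            self.geometry.ml_rest, self.geometry.darm, self.geometry.qrest,
            full6(sp.k_se_s), full6(sp.b_s), full6(sp.k_se_d), full6(sp.k_pe_s),
            full6(sp.g_ia), full6(sp.f_s_ia), full6(sp.g_ii), full6(sp.f_s_ii),
        )

    # -- state helpers ------------------------------------------------------
    def initial_state(self, q=None):
        """Plant state at rest (or at posture q) with steady bag tensions."""
        y = np.zeros(_kernels.NY)
        y[0:2] = self.arm.rest_q if q is None else q
        lengths = self.geometry.muscle_lengths(y[0:2])
        sp = self.spindles
        # steady-state intrafusal tensions at this (static) posture
        y[10:16] = (sp.k_se_s * sp.k_pe_s / (sp.k_se_s + sp.k_pe_s)) \
            * (lengths - self.rest_s)
        y[16:22] = (sp.k_se_d * sp.k_pe_d / (sp.k_se_d + sp.k_pe_d)) \
            * (lengths - self.rest_d)
        return y

    def rhs(self, y, drive):
        return _kernels.plant_rhs(np.asarray(y, float),
                                  np.asarray(drive, float), *self._args)

    def advance(self, y, dt, drive, rtol=1e-5, atol=1e-7):
        y = _kernels.plant_advance(np.asarray(y, float), dt,
                                   np.asarray(drive, float), rtol, atol,
                                   *self._args)
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FloatingPointError(
                f"non-finite plant state component {bad} after advance")
        return y

    def afferents(self, y):
        """(Ia, Ib, II) six-vectors for the current plant state."""
        return _kernels.afferent_outputs(np.asarray(y, float), *self._aff_args)

    # -- kinematics ---------------------------------------------------------
    def hand_position(self, q):
        q1, q2 = q
        return np.array([
            self.arm.L1 * np.cos(q1) + self.arm.L2 * np.cos(q1 + q2),
            self.arm.L1 * np.sin(q1) + self.arm.L2 * np.sin(q1 + q2)])

    def inverse_kinematics(self, hand_xy):
        """Joint angles placing the hand at hand_xy (elbow-down branch, as at
        rest where the elbow sits at (0.3, 0) below the hand)."""
        x, y = hand_xy
        L1, L2 = self.arm.L1, self.arm.L2
        d2 = x * x + y * y
        c2 = (d2 - L1 * L1 - L2 * L2) / (2 * L1 * L2)
        if not -1.0 <= c2 <= 1.0:
            raise ValueError(f"target {hand_xy} out of reach")
        q2 = np.arccos(c2)          # positive branch, matches rest q2 = +pi/2
        k1 = L1 + L2 * c2
        k2 = L2 * np.sin(q2)
        q1 = np.arctan2(y, x) - np.arctan2(k2, k1)
        return np.array([q1, q2])

    def energy(self, y):
        """Kinetic energy of the links (used by dissipation tests)."""
        q2, qd = y[1], y[2:4]
        L1, L2 = self.arm.L1, self.arm.L2
        m1, m2 = self.arm.m1, self.arm.m2
        lc1, lc2 = L1 / 2, L2 / 2
        I1, I2 = m1 * L1 ** 2 / 12, m2 * L2 ** 2 / 12
        c2 = np.cos(q2)
        M11 = m1 * lc1 ** 2 + I1 + m2 * (L1 ** 2 + lc2 ** 2 + 2 * L1 * lc2 * c2) + I2
        M12 = m2 * (lc2 ** 2 + L1 * lc2 * c2) + I2
        M22 = m2 * lc2 ** 2 + I2
        return 0.5 * (M11 * qd[0] ** 2 + 2 * M12 * qd[0] * qd[1] + M22 * qd[1] ** 2)

    def elastic_energy(self, y):
        """Potential energy stored in the parallel elastic elements.

        The series+parallel Hill element is not conservative, so the energy
        audit in tests uses kinetic + parallel-elastic energy with tensions at
        steady state (slow movements).
        """
        lengths = self.geometry.muscle_lengths(y[0:2])
        mp = self.muscles
        keff = mp.k_se * mp.k_pe / (mp.k_se + mp.k_pe)
        dx = lengths - self.rest_lengths
        return float(0.5 * np.sum(keff * dx ** 2))

    def steady_tension(self, drive, q=None):
        """Closed-form steady-state muscle tension at fixed posture."""
        q = np.asarray(self.arm.rest_q if q is None else q, float)
        lengths = self.geometry.muscle_lengths(q)
        mp = self.muscles
        dx = lengths - self.rest_lengths
        return mp.k_se * (mp.gain * np.asarray(drive, float) + mp.k_pe * dx) \
            / (mp.k_se + mp.k_pe)

    def steady_afferents(self, q):
        """(Ia, Ib, II) at a static posture, from the closed forms."""
        y = self.initial_state(q=q)
        # GTO filter state at its own fixed point
        T = self.steady_tension(np.zeros(6), q)
        Tp = np.maximum(T, 0.0)
        y[4:10] = T
        y[22:28] = self.gto.g_ib * np.log(Tp / self.gto.t0 + 1.0)
        return self.afferents(y)
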