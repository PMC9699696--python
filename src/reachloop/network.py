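"""The 74-unit sensorimotor circuit and its wiring policy.

Populations (unit index ranges)::

    SP   0-5    prescribed somatosensory pattern (clamped sources)
    SA   6-11   somatosensory cortex, driven by the II afferents
    SPA  12-23  dual error representation: unit i carries the "muscle i is
                too long" error max(sA_i - sP_i, 0)-like drive, unit 6+i the
                opposite sign; the two are mutually inhibitory
    M    24-35  motor cortex; M_i is driven one-to-one by SPA_i (so M_0..5
                command contraction of their muscle, M_6..11 are their duals)
    A    36-53  afferent relay: Ia_0..5 (36-41), Ib_0..5 (42-47),
                II_0..5 (48-53), rectified-log units
    CE   54-59  spinal excitatory interneurons (one per muscle)
    CI   60-65  spinal inhibitory interneurons
    AL   66-71  alpha motoneurons (drive the muscles)
    ACT  72     exploration controller (leaky integrator of total error)
    CHG  73     change detector for the prescribed pattern

Three configurations share this topology and differ only in which edges are
plastic: ``spinal_learning`` (M->CE/CI and M->alpha differential-Hebbian,
A->M / A->C input-correlation), ``cortical_learning`` (SPA->M differential-
Hebbian, A edges input-correlation), and ``static`` (no plasticity; weights
hand-set by the policy below, which approximates the learned solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomech import PlanarArm

# population slices
SP = slice(0, 6)
SA = slice(6, 12)
SPA = slice(12, 24)
M = slice(24, 36)
A = slice(36, 54)
A_IA = slice(36, 42)
A_IB = slice(42, 48)
A_II = slice(48, 54)
CE = slice(54, 60)
CI = slice(60, 66)
AL = slice(66, 72)
ACT = 72
CHG = 73
N_UNITS = 74

CONFIGURATIONS = ("spinal_learning", "cortical_learning", "static")

# unit kind codes (shared with the engine kernel)
KIND_CLAMPED = 0
KIND_SIGMOID = 1
KIND_NOISY = 2
KIND_LOG = 3
KIND_ACT = 4

# plasticity rule codes
RULE_STATIC = 0
RULE_DIFF_HEBB = 1
RULE_INPUT_CORR = 2
RULE_CHG = 3
RULE_GATE = 4          # CHG -> ACT reset gate (not summed into ACT's input)


@dataclass
class AgonistMap:
    """Antagonist / partial-agonist relations between the six muscles.

    Muscles i and i+3 are full antagonists.  The biarticular muscles are
    partial agonists of the monoarticular muscles acting in their direction.
    """
    antagonist: tuple = (3, 4, 5, 0, 1, 2)
    partial_agonists: tuple = ((1, 2), (0,), (0,), (4, 5), (3,), (3,))

    def __post_init__(self):
        for i, a in enumerate(self.antagonist):
            if a == i:
                raise ValueError("a muscle cannot be its own antagonist")
            if self.antagonist[a] != i:
                raise ValueError("antagonism must be symmetric")


@dataclass
class NetworkParams:
    """All synaptic weights, unit constants, and delays.

    None of these numbers are published for the original circuit; they are
    this package's defaults, tuned so the static configuration holds the rest
    posture and reaches (see docs/methods.md).
    """
    # unit time constants [s]
    tau_sa: float = 0.02
    tau_spa: float = 0.02
    tau_m: float = 0.02
    tau_c: float = 0.02
    tau_a: float = 0.01

    # sigmoid slopes; beta_m / beta_sa form the loop-gain knob
    beta_sa: float = 6.0
    beta_spa: float = 4.0
    beta_m: float = 1.5
    beta_c: float = 4.0
    beta_al: float = 4.0
    # rest-state baseline activities; thresholds are calibrated so the rest
    # posture is a fixed point with these values (C inhibition dominating)
    base_spa: float = 0.15
    base_m: float = 0.2
    base_ce: float = 0.25
    base_ci: float = 0.35
    base_al: float = 0.15

    # afferent relay
    a_input_scale: float = 1.0
    a_threshold: float = 0.0

    # weights
    w_a_sa: float = 1.0        # II -> SA one-to-one
    w_sa_spa: float = 3.0      # SA/SP -> SPA (opposite signs)
    w_spa_mut: float = 1.0     # mutual inhibition within a dual pair
    w_spa_m: float = 2.0       # SPA -> M one-to-one
    w_m_c: float = 0.6         # M -> CE / CI principal weight
    w_m_al: float = 0.5        # M -> alpha principal weight
    partial_factor: float = 0.5
    w_ce_ci: float = 0.8       # CE -> CI within a trio
    w_ci_ce: float = 1.0       # CI -> CE (inhibitory)
    w_ce_al: float = 1.0
    w_ci_al: float = 1.5       # CI -> alpha (inhibitory)
    w_ce_ce_ag: float = 0.3    # CE -> CE of partial agonists
    w_ce_ci_ant: float = 0.3   # CE -> CI of antagonists
    w_ib_c: float = 0.3        # Ib policy weight into C / dual M
    ia_factor: float = 0.8     # Ia weights = ia_factor * Ib weights
    w_spa_act: float = 0.12    # SPA -> ACT (x12 units ~ input in [0, 1.44])
    w_chg_act: float = 1.0
    alpha_chg: float = 20.0    # CHG synapse gain on |dSP/dt|
    tau_chg: float = 0.02

    # noise and adaptation (exploration)
    noise_sigma: float = 0.3
    g_adapt: float = 1.5       # weight of -I_adapt in C (or M) inputs

    # transmission delays [s]
    delay_local: float = 0.005
    delay_long: float = 0.010

    # initial-weight spread for plastic groups
    init_spread: float = 0.5
    ic_baseline: float = 0.05  # floor weight so input-correlation can grow edges


@dataclass
class ConnectionTable:
    """Flat edge list: the single source of truth for the topology."""
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    rule: np.ndarray

    def __len__(self):
        return len(self.src)

    def to_frame(self) -> pd.DataFrame:
        rule_names = {RULE_STATIC: "static", RULE_DIFF_HEBB: "diff_hebb",
                      RULE_INPUT_CORR: "input_corr", RULE_CHG: "chg",
                      RULE_GATE: "gate"}
        return pd.DataFrame({
            "src": self.src, "dst": self.dst, "weight": self.weight,
            "delay": self.delay,
            "rule": [rule_names[r] for r in self.rule]})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


class Network:
    """Units + connections for one configuration, ready for the engine."""

    def __init__(self, configuration: str, params: NetworkParams,
                 plant: PlanarArm, agonists: AgonistMap, seed: int = 0):
        if configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {configuration!r}")
        self.configuration = configuration
        self.params = params
        self.plant = plant
        self.agonists = agonists
        self.seed = seed
        self._build()

    # ------------------------------------------------------------------
    def _build(self):
        p = self.params
        rng = np.random.default_rng(self.seed)

        # --- unit arrays ------------------------------------------------
        kind = np.full(N_UNITS, KIND_SIGMOID, dtype=np.int64)
        tau = np.full(N_UNITS, p.tau_m)
        beta = np.full(N_UNITS, 4.0)
        eta = np.full(N_UNITS, 0.5)
        noise = np.zeros(N_UNITS)

        kind[SP] = KIND_CLAMPED
        kind[A] = KIND_LOG
        kind[ACT] = KIND_ACT

        tau[SA] = p.tau_sa
        tau[SPA] = p.tau_spa
        tau[M] = p.tau_m
        tau[A] = p.tau_a
        tau[CE] = tau[CI] = tau[AL] = p.tau_c

        beta[SA] = p.beta_sa
        beta[SPA] = p.beta_spa
        beta[M] = p.beta_m
        beta[CE] = beta[CI] = p.beta_c
        beta[AL] = p.beta_al
        beta[CHG] = 6.0
        eta[CHG] = 0.5   # baseline ~0.05, below the ACT reset gate (0.1)

        # A units: threshold/scale of the rectified-log activation
        self.a_scale = np.full(18, p.a_input_scale)
        self.a_threshold = np.full(18, p.a_threshold)

        # calibrate SA thresholds so SA sits mid-range at the rest posture
        q0 = np.asarray(self.plant.arm.rest_q, float)
        _, _, ii0 = self.plant.steady_afferents(q0)
        a_rest = np.maximum(
            np.log(np.maximum(1.0 + self.a_scale[12:] * ii0
                              - self.a_threshold[12:], 1.0)), 0.0)
        eta[SA] = p.w_a_sa * a_rest

        # exploration noise: C interneurons (spinal/static) or M (cortical)
        if self.configuration == "cortical_learning":
            noise[M] = p.noise_sigma
            kind[M] = KIND_NOISY
            self.adapt_units = np.arange(M.start, M.stop)
        else:
            noise[CE.start:CI.stop] = p.noise_sigma
            kind[CE.start:CI.stop] = KIND_NOISY
            self.adapt_units = np.arange(CE.start, CI.stop)

        self.kind, self.tau, self.beta, self.eta, self.noise = \
            kind, tau, beta, eta, noise

        # --- edges -------------------------------------------------------
        src, dst, wgt, dly, rul = [], [], [], [], []

        def add(s, d, w, delay, rule=RULE_STATIC):
            src.append(s); dst.append(d); wgt.append(w)
            dly.append(delay); rul.append(rule)

        ant = self.agonists.antagonist
        pag = self.agonists.partial_agonists
        loc, lng = p.delay_local, p.delay_long

        # II -> SA one-to-one (spino-cortical)
        for i in range(6):
            add(A_II.start + i, SA.start + i, p.w_a_sa, lng)

        # SA/SP -> SPA dual pairs; SA excites units 0-5, SP the duals
        for i in range(6):
            add(SA.start + i, SPA.start + i, p.w_sa_spa, loc)
            add(SP.start + i, SPA.start + i, -p.w_sa_spa, loc)
            add(SA.start + i, SPA.start + 6 + i, -p.w_sa_spa, loc)
            add(SP.start + i, SPA.start + 6 + i, p.w_sa_spa, loc)
            # mutual inhibition within the pair
            add(SPA.start + i, SPA.start + 6 + i, -p.w_spa_mut, loc)
            add(SPA.start + 6 + i, SPA.start + i, -p.w_spa_mut, loc)

        # SPA -> M
        if self.configuration == "cortical_learning":
            # all-to-all plastic (differential Hebbian)
            from .plasticity import init_plastic_weights
            w0 = init_plastic_weights(rng, 12, 12, row_sum=p.w_spa_m,
                                      spread=p.init_spread)
            for j in range(12):
                for i in range(12):
                    add(SPA.start + j, M.start + i, w0[j, i], loc,
                        RULE_DIFF_HEBB)
        else:
            for i in range(12):
                add(SPA.start + i, M.start + i, p.w_spa_m, loc)

        # M -> C and M -> alpha
        if self.configuration == "spinal_learning":
            from .plasticity import init_plastic_weights
            w0 = init_plastic_weights(rng, 12, 12, row_sum=2.0 * p.w_m_c,
                                      spread=p.init_spread)
            for j in range(12):
                for i in range(6):
                    add(M.start + j, CE.start + i, w0[j, i], lng,
                        RULE_DIFF_HEBB)
                    add(M.start + j, CI.start + i, w0[j, 6 + i], lng,
                        RULE_DIFF_HEBB)
            wa = init_plastic_weights(rng, 12, 6, row_sum=p.w_m_al,
                                      spread=p.init_spread)
            for j in range(12):
                for i in range(6):
                    add(M.start + j, AL.start + i, wa[j, i], lng,
                        RULE_DIFF_HEBB)
        else:
            for i, w_ce, w_al, w_ci in self._policy_m_rows():
                for j, w in w_ce:
                    add(M.start + i, CE.start + j, w, lng)
                for j, w in w_al:
                    add(M.start + i, AL.start + j, w, lng)
                for j, w in w_ci:
                    add(M.start + i, CI.start + j, w, lng)

        # A (Ia, Ib) -> C and M: input-correlation edges, policy-initialized
        ic_rule = RULE_STATIC if self.configuration == "static" \
            else RULE_INPUT_CORR
        for s, d, w in self._policy_afferent_edges():
            add(s, d, w, lng if d >= M.start and d < M.stop else loc, ic_rule)

        # C internal wiring
        for i in range(6):
            add(CE.start + i, CI.start + i, p.w_ce_ci, loc)
            add(CI.start + i, CE.start + i, -p.w_ci_ce, loc)
            add(CE.start + i, AL.start + i, p.w_ce_al, loc)
            add(CI.start + i, AL.start + i, -p.w_ci_al, loc)
            for j in pag[i]:
                add(CE.start + i, CE.start + j, p.w_ce_ce_ag, loc)
            add(CE.start + i, CI.start + ant[i], p.w_ce_ci_ant, loc)

        # exploration controller
        for i in range(12):
            add(SPA.start + i, ACT, p.w_spa_act, loc)
        for i in range(6):
            add(SP.start + i, CHG, 0.0, loc, RULE_CHG)
        add(CHG, ACT, p.w_chg_act, loc, RULE_GATE)

        self.connections = ConnectionTable(
            src=np.array(src, dtype=np.int64),
            dst=np.array(dst, dtype=np.int64),
            weight=np.array(wgt, dtype=float),
            delay=np.array(dly, dtype=float),
            rule=np.array(rul, dtype=np.int64))

        if np.any(self.connections.delay <= 0):
            raise ValueError("every connection must have a positive delay")

        self._calibrate_thresholds(a_rest_all=self._rest_a_activities())

    # ------------------------------------------------------------------
    def _rest_a_activities(self):
        """A-unit activities (Ia, Ib, II) at the rest posture."""
        q0 = np.asarray(self.plant.arm.rest_q, float)
        ia, ib, ii = self.plant.steady_afferents(q0)
        aff = np.concatenate([ia, ib, ii])
        arg = 1.0 + self.a_scale * aff - self.a_threshold
        return np.maximum(np.log(np.maximum(arg, 1.0)), 0.0)

    def _calibrate_thresholds(self, a_rest_all):
        """Choose sigmoid thresholds so the rest posture is a network fixed
        point with the configured baseline activities.

        With SP clamped to the rest pattern, every unit's input at the
        baselines is computed from the connection table, and the threshold
        is set so the sigmoid output equals the unit's target baseline
        (eta = I - logit(base) / beta).  This is the hand-tuning that makes
        the static weights approximate the optimal feedback solution.
        """
        p = self.params
        base = np.zeros(N_UNITS)
        base[SP] = 0.5
        base[SA] = 0.5
        base[SPA] = p.base_spa
        base[M] = p.base_m
        base[A] = a_rest_all
        base[CE] = p.base_ce
        base[CI] = p.base_ci
        base[AL] = p.base_al
        base[ACT] = 0.0
        base[CHG] = 0.0

        con = self.connections
        I = np.zeros(N_UNITS)
        for s, d, w, r in zip(con.src, con.dst, con.weight, con.rule):
            if r != RULE_GATE:
                I[d] += w * base[s]

        logit = lambda x: np.log(x / (1.0 - x))
        for sl, b in ((SPA, p.base_spa), (M, p.base_m), (CE, p.base_ce),
                      (CI, p.base_ci), (AL, p.base_al)):
            self.eta[sl] = I[sl] - logit(b) / self.beta[sl]
        self.rest_baseline = base

    # ------------------------------------------------------------------
    def _policy_m_rows(self):
        """Static-weight policy for the M -> C / alpha projections.

        M_i (i < 6) commands contraction of muscle i: it excites CE_i and
        alpha_i, the CI of muscle i's antagonist, and (weaker) the CE/alpha
        of muscle i's partial agonists.  The dual unit M_{6+i} applies the
        same pattern to the antagonist.  Only excitatory weights are used.
        """
        p = self.params
        ant = self.agonists.antagonist
        pag = self.agonists.partial_agonists
        rows = []
        for u in range(12):
            mus = u % 6 if u < 6 else ant[u - 6]
            ce = [(mus, p.w_m_c)]
            al = [(mus, p.w_m_al)]
            ci = [(ant[mus], p.w_m_c)]
            for g in pag[mus]:
                ce.append((g, p.partial_factor * p.w_m_c))
                al.append((g, p.partial_factor * p.w_m_al))
            rows.append((u, ce, al, ci))
        return rows

    def _policy_afferent_edges(self):
        """Policy for Ia/Ib -> C and -> M edges.

        Tension or stretch of muscle i predicts growing error for its
        antagonist, so Ib_i excites CI_i, the CE/alpha of i's antagonist,
        and the M unit commanding relaxation of muscle i (the dual M_{6+i}).
        Ia edges repeat the pattern with slightly smaller weights.
        """
        p = self.params
        ant = self.agonists.antagonist
        edges = []
        for i in range(6):
            for base, w in ((A_IB.start, p.w_ib_c),
                            (A_IA.start, p.ia_factor * p.w_ib_c)):
                edges.append((base + i, CI.start + i, w))
                edges.append((base + i, CE.start + ant[i], w))
                edges.append((base + i, AL.start + ant[i], w))
                edges.append((base + i, M.start + 6 + i, w))
        return edges

    # ------------------------------------------------------------------
    def rest_sp_pattern(self):
        """SA activity at the rest posture (the SP pattern that encodes it)."""
        from .protocols import target_to_sp
        return target_to_sp(np.asarray(self.plant.arm.rest_q), self, self.plant)

    def dual_error_drive(self, e):
        """Input drive of a dual SPA pair for a signed length error e
        (positive e = muscle longer than desired).  Contract-side unit gets
        +w*e, its dual -w*e; used by tests of the dual-representation
        contract."""
        w = self.params.w_sa_spa / self.params.beta_sa  # per unit of SA drive
        return w * max(e, 0.0), w * max(-e, 0.0)


def default_params(configuration: str) -> NetworkParams:
    """Per-configuration defaults.  The static network runs at a slightly
    higher loop gain (slope of the M units), close enough to the onset of
    oscillations that endpoint oscillation is visible."""
    p = NetworkParams()
    if configuration == "static":
        p.beta_m = 2.0
    return p


def build(configuration: str, params: NetworkParams | None = None,
          plant: PlanarArm | None = None,
          agonists: AgonistMap | None = None, seed: int = 0) -> Network:
    """Construct the circuit for one of the three configurations."""
    return Network(configuration,
                   params or default_params(configuration),
                   plant or PlanarArm(),
                   agonists or AgonistMap(),
                   seed=seed)
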