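"""Closed-loop simulation engine.

The neural units advance by forward Euler (Euler-Maruyama where noisy) at a
fixed step, reading their inputs from per-connection delay lines; the plant
advances over each neural step with an adaptive Dormand-Prince 5(4)
integrator while the motoneuron drives are held constant (operator
splitting).  Plasticity is integrated with the same Euler step, using
derivative estimates from cascaded exponential smoothers of the activity
history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels, network as net
from .plasticity import DiffHebbParams, InputCorrParams
from .trace import ReachTrace
from .units import ACTParams, AdaptationParams

log = logging.getLogger(__name__)


@dataclass
class IntegratorConfig:
    dt: float = 0.001          # neural Euler step [s]
    plant_rtol: float = 1e-5
    plant_atol: float = 1e-7
    seed: int = 0
    sensory_delay: float = 0.005   # plant -> A relay [s]
    motor_delay: float = 0.005     # alpha -> muscle [s]
    record_every: float = 0.01     # trace cadence [s]

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class DelayBuffer:
    """Read-only view of the engine's activity history ring."""

    def __init__(self, buf, misc, dt):
        self._buf = buf
        self._misc = misc
        self._dt = dt

    def read(self, unit, lag=0.0):
        """Activity of `unit` a time `lag` seconds ago (quantized to dt)."""
        H = self._buf.shape[1]
        steps = int(round(lag / self._dt))
        if steps < 0 or steps >= H:
            raise ValueError(f"lag {lag} outside the buffer horizon")
        return self._buf[unit, (self._misc[0] - steps) % H]


class SimState:
    """Live view of the simulation state (time, activities, plant, weights)."""

    def __init__(self, engine):
        self._e = engine

    @property
    def time(self):
        return self._e.misc[1] * self._e.cfg.dt

    @property
    def activities(self):
        return self._e.act

    @property
    def plant(self):
        return self._e.y

    @property
    def weights(self):
        return self._e.ew

    @property
    def buffer(self):
        return DelayBuffer(self._e.buf, self._e.misc, self._e.cfg.dt)


class Engine:
    """Binds a `Network` + `PlanarArm` to the compiled integration loop."""

    def __init__(self, network: net.Network, cfg: IntegratorConfig | None = None,
                 dh: DiffHebbParams | None = None,
                 dh_alpha: DiffHebbParams | None = None,
                 ic: InputCorrParams | None = None,
                 act_params: ACTParams | None = None,
                 adapt_params: AdaptationParams | None = None):
        self.network = network
        self.plant = network.plant
        self.cfg = cfg or IntegratorConfig()
        self.dh = dh or DiffHebbParams()
        self.dh_alpha = dh_alpha or DiffHebbParams(w_sa=0.5)
        self.ic = ic or InputCorrParams()
        self.act_params = act_params or ACTParams()
        self.adapt_params = adapt_params or AdaptationParams()
        self._nrun = 0
        self._assemble()
        self.reset()

    # ------------------------------------------------------------------
    def _assemble(self):
        cfg = self.cfg
        nw = self.network
        con = nw.connections
        dt = cfg.dt

        self.kind = nw.kind.copy()
        self.tau = nw.tau.copy()
        self.beta = nw.beta.copy()
        self.eta = nw.eta.copy()
        self.noise = nw.noise.copy()
        ap = self.act_params
        self.beta[net.ACT] = ap.beta
        self.eta[net.ACT] = ap.eta

        self.esrc = con.src.copy()
        self.edst = con.dst.copy()
        self.ew0 = con.weight.copy()
        self.erule = con.rule.copy()
        self.edly = np.maximum(np.round(con.delay / dt).astype(np.int64), 1)
        if np.any(con.delay < dt):
            raise ValueError("dt must not exceed the minimum transmission delay")

        # differential-Hebbian groups: (pre slice, post slice, params)
        groups = []
        if nw.configuration == "spinal_learning":
            groups = [(net.M, slice(net.CE.start, net.CI.stop), self.dh),
                      (net.M, net.AL, self.dh_alpha)]
        elif nw.configuration == "cortical_learning":
            groups = [(net.SPA, net.M, self.dh)]
        self.egroup = np.full(len(con), -1, dtype=np.int64)
        gpar = {k: [] for k in ("alpha", "lam", "wsa", "wsb", "lag", "sgn")}
        for g, (pre, post, p) in enumerate(groups):
            mask = (self.erule == net.RULE_DIFF_HEBB) \
                & (self.esrc >= pre.start) & (self.esrc < pre.stop) \
                & (self.edst >= post.start) & (self.edst < post.stop)
            self.egroup[mask] = g
            # sum targets taken from the initial weights (rows are built to a
            # common sum; column target is the mean initial incoming sum)
            rows = np.zeros(net.N_UNITS)
            cols = np.zeros(net.N_UNITS)
            np.add.at(rows, self.esrc[mask], self.ew0[mask])
            np.add.at(cols, self.edst[mask], self.ew0[mask])
            gpar["alpha"].append(p.alpha)
            gpar["lam"].append(p.lam)
            gpar["wsa"].append(rows[pre].max() if rows[pre].max() > 0 else p.w_sa)
            gpar["wsb"].append(cols[post].max() if cols[post].max() > 0 else p.w_sb)
            gpar["lag"].append(max(int(round(p.delta_t / dt)), 1))
            gpar["sgn"].append(p.drive_sign)
        self.g_alpha = np.array(gpar["alpha"], dtype=float)
        self.g_lam = np.array(gpar["lam"], dtype=float)
        self.g_wsa = np.array(gpar["wsa"], dtype=float)
        self.g_wsb = np.array(gpar["wsb"], dtype=float)
        self.g_lag = np.array(gpar["lag"], dtype=np.int64)
        self.g_sign = np.array(gpar["sgn"], dtype=float)
        self.g_pre0 = np.array([g[0].start for g in groups], dtype=np.int64)
        self.g_pre1 = np.array([g[0].stop for g in groups], dtype=np.int64)
        self.g_post0 = np.array([g[1].start for g in groups], dtype=np.int64)
        self.g_post1 = np.array([g[1].stop for g in groups], dtype=np.int64)

        # input-correlation targets: preserve each unit's initial afferent sum
        self.ic_target = np.zeros(net.N_UNITS)
        icm = self.erule == net.RULE_INPUT_CORR
        np.add.at(self.ic_target, self.edst[icm], self.ew0[icm])

        # "PA-class" edges: error/command inputs whose derivative gates the
        # input-correlation rule (M->C for spinal units, SPA->M for M units)
        self.epa = (((self.esrc >= net.M.start) & (self.esrc < net.M.stop)
                     & (self.edst >= net.CE.start) & (self.edst < net.AL.stop))
                    | ((self.esrc >= net.SPA.start) & (self.esrc < net.SPA.stop)
                       & (self.edst >= net.M.start) & (self.edst < net.M.stop))
                    ).astype(np.int64)

        self.sens_steps = max(int(round(cfg.sensory_delay / dt)), 1)
        self.motor_steps = max(int(round(cfg.motor_delay / dt)), 1)
        self.H = int(max(self.edly.max(), self.sens_steps, self.motor_steps,
                         self.g_lag.max() if len(self.g_lag) else 1)) + 2

        self.adapt_mask = np.zeros(net.N_UNITS, dtype=np.int64)
        self.adapt_mask[nw.adapt_units] = 1

    # ------------------------------------------------------------------
    def reset(self, q=None, sp=None):
        """Reset to a static posture (default: rest) with zeroed history."""
        nw = self.network
        self.ew = self.ew0.copy()
        self.y = self.plant.initial_state(q=q)
        T = self.plant.steady_tension(np.zeros(6), self.y[0:2])
        self.y[4:10] = np.maximum(T, 0.0)
        self.y[22:28] = self.plant.gto.g_ib * np.log(
            np.maximum(T, 0) / self.plant.gto.t0 + 1.0)
        ia, ib, ii = self.plant.afferents(self.y)
        aff = np.concatenate([ia, ib, ii])

        self.act = nw.rest_baseline.copy()
        # afferent relay at its fixed point
        arg = 1.0 + nw.a_scale * aff - nw.a_threshold
        self.act[net.A] = np.maximum(np.log(np.maximum(arg, 1.0)), 0.0)
        sa = 1.0 / (1.0 + np.exp(-self.beta[net.SA]
                                 * (nw.params.w_a_sa * self.act[net.A_II]
                                    - self.eta[net.SA])))
        self.act[net.SA] = sa
        self.act[net.SP] = sa if sp is None else np.asarray(sp, float)
        self.act[net.ACT] = 0.0
        self.act[net.CHG] = 0.0

        self.buf = np.repeat(self.act[:, None], self.H, axis=1)
        self.dbuf = np.zeros((net.N_UNITS, self.H))
        self.aff_buf = np.repeat(aff[:, None], self.H, axis=1)
        self.yf = self.act.copy()
        self.ym = self.act.copy()
        self.df = np.zeros(net.N_UNITS)
        self.dm = np.zeros(net.N_UNITS)
        self.ipa_f = np.zeros(net.N_UNITS)
        self.ipa_m = np.zeros(net.N_UNITS)
        self.u_slow = np.zeros(net.N_UNITS)
        self.i_adapt = np.zeros(net.N_UNITS)
        self.scal = np.zeros(1)
        self.misc = np.zeros(5, dtype=np.int64)
        self.active = np.ones(net.N_UNITS, dtype=np.int64)
        self.state = SimState(self)
        return self.state

    def isolate_spinal(self):
        """Silence every population except the spinal circuit (CE, CI, alpha).

        Used by the stimulation protocols: the remaining units' activities
        are clamped at zero and their edges carry no signal.
        """
        self.active[:] = 0
        self.active[net.CE.start:net.AL.stop] = 1
        self.act[self.active == 0] = 0.0
        self.buf[self.active == 0, :] = 0.0
        self.noise[:] = 0.0

    def set_noise(self, on: bool):
        scale = 1.0 if on else 0.0
        self.noise = self.network.noise * scale

    def freeze_plasticity(self):
        """Turn every learning rule off (weights keep their current values)."""
        self.g_alpha = np.zeros_like(self.g_alpha)
        self._ic_off = True

    # ------------------------------------------------------------------
    def run(self, duration, schedule=None, stim=None, noise=None,
            record_every=None, weight_record_every=0.0,
            freeze_plant_for=0.0, plant_on=True) -> ReachTrace:
        """Integrate for `duration` seconds; returns the recorded trace.

        schedule : optional TargetSchedule (onset-relative to this call)
        stim     : optional 74-vector of constant external input
        freeze_plant_for : hold the plant static for the first part [s]
        """
        cfg = self.cfg
        dt = cfg.dt
        steps = int(round(duration / dt))
        if abs(steps * dt - duration) > 1e-9:
            log.warning("duration snapped to %d steps of %g s", steps, dt)
        rec_every = record_every if record_every is not None else cfg.record_every
        rsteps = max(int(round(rec_every / dt)), 1)
        wsteps = int(round(weight_record_every / dt)) if weight_record_every else 0

        if schedule is not None and len(schedule) > 0:
            t0 = self.misc[1]
            on = np.round(np.asarray(schedule.onsets) / dt).astype(np.int64)
            if np.any(np.abs(on * dt - np.asarray(schedule.onsets)) > 1e-9):
                log.info("schedule onsets snapped to the %g s grid", dt)
            sched_step = t0 + on
            sched_sp = np.asarray(schedule.sp_patterns, dtype=float)
            sched_tgt = np.asarray(schedule.hand_targets, dtype=float)
        else:
            sched_step = np.zeros(0, dtype=np.int64)
            sched_sp = np.zeros((0, 6))
            sched_tgt = np.zeros((0, 2))

        nrec = steps // rsteps + 1
        rec_t = np.zeros(nrec)
        rec_act = np.zeros((nrec, net.N_UNITS))
        rec_y = np.zeros((nrec, _kernels.NY))
        rec_tgt = np.zeros((nrec, 2))
        nwrec = (steps // wsteps) if wsteps else 0
        rec_w = np.zeros((max(nwrec, 1), len(self.ew)))

        # a fresh schedule starts from its first entry
        if len(sched_step):
            self.misc[2] = 0

        # row 0 = state at call start
        rec_t[0] = self.misc[1] * dt
        rec_act[0] = self.act
        rec_y[0] = self.y
        rec_tgt[0] = sched_tgt[0] if len(sched_tgt) else 0.0
        self.misc[3] = 1
        self.misc[4] = 0

        stim_vec = np.zeros(net.N_UNITS) if stim is None else \
            np.asarray(stim, dtype=float)
        noise_vec = self.noise if noise is None else \
            np.where(np.asarray(noise), self.network.noise, 0.0)

        seed = (self.cfg.seed * 9973 + self._nrun * 101 + 17) % (2 ** 31)
        self._nrun += 1
        ap, dp = self.act_params, self.adapt_params
        alpha_ic = 0.0 if getattr(self, "_ic_off", False) else self.ic.alpha_ic

        status = _kernels.run_core(
            steps, dt, 1, seed,
            self.kind, self.tau, self.beta, self.eta, noise_vec, self.active,
            self.network.a_scale, self.network.a_threshold,
            self.esrc, self.edst, self.ew, self.edly, self.erule,
            self.egroup, self.epa,
            self.g_alpha, self.g_lam, self.g_wsa, self.g_wsb, self.g_lag,
            self.g_sign, self.g_pre0, self.g_pre1, self.g_post0, self.g_post1,
            alpha_ic, self.ic.w_max, self.ic_target,
            self.network.params.alpha_chg, self.network.params.tau_chg,
            ap.theta_act, ap.tau_act, ap.gamma, ap.tau_tilde,
            ap.reset_rate, ap.chg_gate,
            self.adapt_mask, dp.tau_slow, dp.act_threshold, dp.reset_below,
            self.network.params.g_adapt,
            self.yf, self.ym, self.df, self.dm, self.ipa_f, self.ipa_m,
            self.dh.tau_fast, self.dh.tau_mid,
            self.act, self.buf, self.dbuf, self.aff_buf, self.misc,
            self.u_slow, self.i_adapt, self.scal,
            self.y, 1 if plant_on else 0,
            self.misc[1] + int(round(freeze_plant_for / dt)),
            self.sens_steps, self.motor_steps, cfg.plant_rtol, cfg.plant_atol,
            *self.plant._args,
            *self.plant._aff_args[7:11],
            stim_vec, sched_step, sched_sp, sched_tgt,
            rsteps, rec_t, rec_act, rec_y, rec_tgt,
            wsteps, rec_w)
        if status != 0:
            u = status - 1
            raise FloatingPointError(
                f"non-finite activity in unit {u} at t="
                f"{self.misc[1] * dt:.3f} s")

        nr = self.misc[3]
        nwr = self.misc[4]
        wt = None
        w = None
        if wsteps:
            w = rec_w[:nwr]
            wt = (np.arange(1, nwr + 1) * wsteps * dt
                  + rec_t[0])
        return ReachTrace(
            time=rec_t[:nr], activities=rec_act[:nr], plant=rec_y[:nr],
            target=rec_tgt[:nr], weights=w, weight_time=wt,
            meta={"L1": self.plant.arm.L1, "L2": self.plant.arm.L2,
                  "configuration": self.network.configuration,
                  "seed": int(self.cfg.seed), "dt": dt})

    def step(self):
        """Advance a single neural time step (diagnostic convenience)."""
        self.run(self.cfg.dt, record_every=self.cfg.dt)
        return self.state
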