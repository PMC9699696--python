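"""Experiment protocols: training, center-out reaching, PD drift, mass
change, and isolated spinal stimulation.

A reach is commanded purely in sensory space: the prescribed pattern SP is
set to the somatosensory activity the arm *would* produce at the target
posture, and the loop moves the arm until perceived matches prescribed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .engine import Engine, IntegratorConfig
from .trace import ReachTrace

log = logging.getLogger(__name__)

# random-target sampling ranges (radians) and workspace limits
SHOULDER_RANGE = (np.deg2rad(-20.0), np.deg2rad(110.0))
ELBOW_RANGE = (np.deg2rad(10.0), np.deg2rad(150.0))


@dataclass
class TargetSchedule:
    """Onset-sorted target presentations for one engine run."""
    onsets: list = field(default_factory=list)        # seconds, run-relative
    sp_patterns: list = field(default_factory=list)   # 6-vectors
    hand_targets: list = field(default_factory=list)  # hand xy per target
    joint_targets: list = field(default_factory=list)

    def add(self, onset, sp, hand_xy, q=None):
        if self.onsets and onset <= self.onsets[-1]:
            raise ValueError("schedule onsets must be strictly increasing")
        self.onsets.append(float(onset))
        self.sp_patterns.append(np.asarray(sp, float))
        self.hand_targets.append(np.asarray(hand_xy, float))
        self.joint_targets.append(None if q is None else np.asarray(q, float))

    def __len__(self):
        return len(self.onsets)


def target_to_sp(target, network: net.Network, plant=None):
    """SP pattern (6 SA steady-state values) encoding a target posture.

    `target` is either a pair of joint angles (radians) or, if it lies in
    the arm workspace as a hand position, an (x, y) hand coordinate.  Joint
    angles are detected by shape of use: pass hand coordinates through
    `hand=` style tuples of length 2 -- both are length 2, so the rule is:
    values are interpreted as joint angles.  Use `sp_for_hand` for hand
    coordinates.
    """
    plant = plant or network.plant
    q = np.asarray(target, dtype=float)
    lengths = plant.geometry.muscle_lengths(q)
    if np.any(lengths <= 0):
        raise ValueError(f"unreachable/degenerate target posture {q}")
    _, _, ii = plant.steady_afferents(q)
    a = np.maximum(np.log(np.maximum(
        1.0 + network.a_scale[12:] * ii - network.a_threshold[12:], 1.0)), 0.0)
    I = network.params.w_a_sa * a
    return 1.0 / (1.0 + np.exp(-network.beta[net.SA] * (I - network.eta[net.SA])))


def sp_for_hand(hand_xy, network: net.Network, plant=None):
    """SP pattern for a hand-space target (elbow-down inverse kinematics)."""
    plant = plant or network.plant
    q = plant.inverse_kinematics(hand_xy)
    return target_to_sp(q, network, plant), q


def sample_joint_targets(n, rng, plant, min_radius=0.12, max_radius=0.55):
    """Random joint-angle targets, uniform over the sampling box, rejecting
    postures whose hand leaves a workspace annulus around the shoulder."""
    out = []
    while len(out) < n:
        q = np.array([rng.uniform(*SHOULDER_RANGE), rng.uniform(*ELBOW_RANGE)])
        r = np.linalg.norm(plant.hand_position(q))
        if min_radius <= r <= max_radius:
            out.append(q)
    return out


# ---------------------------------------------------------------------------


@dataclass
class TrainingResult:
    trace: ReachTrace
    per_presentation_error: np.ndarray   # time-averaged distance [m]
    failed_before_success: int
    final_error: float                   # mean over last 4 presentations [m]
    success: bool

    def summary(self):
        return {"per_presentation_error_cm":
                (100 * self.per_presentation_error).round(2).tolist(),
                "failed_before_success": int(self.failed_before_success),
                "final_error_cm": 100 * self.final_error,
                "success": bool(self.success)}


def training_phase(engine: Engine, n_presentations=16, presentation=40.0,
                   threshold=0.10, settle=2.0, record_every=0.02,
                   weight_record_every=0.0) -> TrainingResult:
    """Free movement under noise + exploration through random SP targets.

    Targets are sampled uniformly in joint-angle space, one every
    `presentation` seconds.  Success = time-averaged hand-target distance
    below `threshold` (10 cm) over the last four presentations.
    """
    nw = engine.network
    rng = np.random.default_rng((engine.cfg.seed * 7919 + 11) % 2 ** 31)
    engine.set_noise(True)

    # settle at rest with SP = rest pattern before the first target
    rest_sp = target_to_sp(np.asarray(nw.plant.arm.rest_q), nw)
    engine.reset(sp=rest_sp)
    engine.run(settle, record_every=record_every)

    sched = TargetSchedule()
    targets = sample_joint_targets(n_presentations, rng, nw.plant)
    for k, q in enumerate(targets):
        sched.add(k * presentation, target_to_sp(q, nw),
                  nw.plant.hand_position(q), q=q)
    trace = engine.run(n_presentations * presentation, schedule=sched,
                       record_every=record_every,
                       weight_record_every=weight_record_every)

    errs = per_presentation_errors(trace, sched, presentation)
    below = errs < threshold
    failed = int(np.argmax(below)) if below.any() else n_presentations
    final = float(errs[-4:].mean())
    return TrainingResult(trace, errs, failed, final, final < threshold)


def per_presentation_errors(trace: ReachTrace, sched: TargetSchedule,
                            presentation: float):
    """Time-averaged hand-target distance within each presentation."""
    t = trace.time - trace.time[0]
    hand = trace.hand
    errs = []
    for k in range(len(sched)):
        m = (t >= sched.onsets[k]) & (t < sched.onsets[k] + presentation)
        d = np.linalg.norm(hand[m] - np.asarray(sched.hand_targets[k]), axis=1)
        errs.append(d.mean())
    return np.array(errs)


# ---------------------------------------------------------------------------


@dataclass
class CenterOutResult:
    trace: ReachTrace
    schedule: TargetSchedule
    reach_slices: list                 # (target index, t_on, t_off) per reach
    mean_error: float                  # time-averaged distance, peripheral [m]
    targets: np.ndarray                # (n_targets, 2) hand positions

    def summary(self):
        return {"mean_error_cm": 100 * self.mean_error,
                "n_reaches": len(self.reach_slices)}


def center_out_targets(center, radius=0.10, n=8):
    ang = 2 * np.pi * np.arange(n) / n
    return np.asarray(center) + radius * np.column_stack(
        [np.cos(ang), np.sin(ang)])


def center_out(engine: Engine, n_reps=6, n_targets=8, reach_duration=5.0,
               radius=0.10, record_every=0.01, settle=2.0,
               rng=None) -> CenterOutResult:
    """Standard center-out task around the hand rest position.

    Peripheral targets sit on a `radius` circle around the rest hand
    position; each appears `n_reps` times in random order, every peripheral
    reach preceded by a reach back to the center.  Unit noise is off.
    """
    nw = engine.network
    plant = nw.plant
    if rng is None:
        rng = np.random.default_rng((engine.cfg.seed * 104729 + 7) % 2 ** 31)
    engine.set_noise(False)

    center = plant.hand_position(np.asarray(plant.arm.rest_q))
    targets = center_out_targets(center, radius, n_targets)
    order = np.concatenate([rng.permutation(n_targets) for _ in range(n_reps)])

    rest_sp = target_to_sp(np.asarray(plant.arm.rest_q), nw)
    engine.run(settle, record_every=record_every)

    sched = TargetSchedule()
    slices = []
    t = 0.0
    for k in order:
        sched.add(t, rest_sp, center, q=np.asarray(plant.arm.rest_q))
        t += reach_duration
        sp, q = sp_for_hand(targets[k], nw, plant)
        sched.add(t, sp, targets[k], q=q)
        slices.append((int(k), t, t + reach_duration))
        t += reach_duration
    trace = engine.run(t, schedule=sched, record_every=record_every)

    t_rel = trace.time - trace.time[0]
    hand = trace.hand
    errs = []
    for k, t_on, t_off in slices:
        m = (t_rel >= t_on) & (t_rel < t_off)
        errs.append(np.linalg.norm(hand[m] - targets[k], axis=1).mean())
    return CenterOutResult(trace, sched, slices, float(np.mean(errs)), targets)


def reach_rate_table(result: CenterOutResult, window=(0.0, 4.0),
                     population="M"):
    """Mean unit rates per reach for tuning analyses.

    Returns (rates (n_reaches, n_units), target_index (n_reaches,)):
    activity averaged over `window` (seconds after reach onset).  The 4-s
    default starts at target onset so it covers the transit phase, where
    the length errors -- and hence the directional signal -- live; in the
    gravity-free plant, holding a reached posture needs no net drive.
    """
    t_rel = result.trace.time - result.trace.time[0]
    acts = result.trace.pop(population)
    rows = []
    labels = []
    for k, t_on, t_off in result.reach_slices:
        m = (t_rel >= t_on + window[0]) & (t_rel < t_on + window[1])
        rows.append(acts[m].mean(axis=0))
        labels.append(k)
    return np.asarray(rows), np.asarray(labels)


def condition_traces(result: CenterOutResult, t_start=0.05, t_stop=0.55,
                     population="M"):
    """Per-condition trial-averaged traces for rotational-dynamics analysis.

    Returns array (n_targets, n_times, n_units): activity from `t_start` to
    `t_stop` seconds after target onset, averaged over repetitions.
    """
    t_rel = result.trace.time - result.trace.time[0]
    acts = result.trace.pop(population)
    n_targets = len(result.targets)
    dt = np.median(np.diff(t_rel))
    nt = int(round((t_stop - t_start) / dt))
    out = np.zeros((n_targets, nt, acts.shape[1]))
    cnt = np.zeros(n_targets)
    for k, t_on, t_off in result.reach_slices:
        i0 = int(round((t_on + t_start) / dt))
        out[k] += acts[i0:i0 + nt]
        cnt[k] += 1
    return out / cnt[:, None, None]


# ---------------------------------------------------------------------------


def pd_drift_protocol(engine: Engine, n_reaches=40, n_targets=10,
                      reach_duration=5.0, radius=0.10, record_every=0.01):
    """Additional center-out reaching on a denser target ring to probe drift
    of the preferred directions under continuous learning (noise off)."""
    from .analysis import pd_vectors
    nw = engine.network
    rng = np.random.default_rng((engine.cfg.seed * 31 + 5) % 2 ** 31)

    def run_block(n_t, n_reach):
        plant = nw.plant
        center = plant.hand_position(np.asarray(plant.arm.rest_q))
        targets = center_out_targets(center, radius, n_t)
        order = rng.permutation(np.concatenate(
            [np.arange(n_t)] * int(np.ceil(n_reach / n_t))))[:n_reach]
        rest_sp = target_to_sp(np.asarray(plant.arm.rest_q), nw)
        sched = TargetSchedule()
        slices = []
        t = 0.0
        for k in order:
            sched.add(t, rest_sp, center)
            t += reach_duration
            sp, q = sp_for_hand(targets[k], nw, plant)
            sched.add(t, sp, targets[k], q=q)
            slices.append((int(k), t, t + reach_duration))
            t += reach_duration
        trace = engine.run(t, schedule=sched, record_every=record_every)
        res = CenterOutResult(trace, sched, slices, np.nan, targets)
        errs = []
        t_rel = trace.time - trace.time[0]
        hand = trace.hand
        for k, t_on, t_off in slices:
            m = (t_rel >= t_on) & (t_rel < t_off)
            errs.append(np.linalg.norm(hand[m] - targets[k], axis=1).mean())
        res.mean_error = float(np.mean(errs))
        return res

    engine.set_noise(False)
    before = run_block(8, 48)
    rates_b, lab_b = reach_rate_table(before)
    pd_before = pd_vectors(rates_b, lab_b, before.targets,
                           before.targets.mean(axis=0))
    after = run_block(n_targets, n_reaches)
    rates_a, lab_a = reach_rate_table(after)
    pd_after = pd_vectors(rates_a, lab_a, after.targets,
                          after.targets.mean(axis=0))
    db = np.rad2deg(np.abs(_wrap(np.arctan2(pd_after[:, 1], pd_after[:, 0])
                                 - np.arctan2(pd_before[:, 1], pd_before[:, 0]))))
    return {"pd_before": pd_before, "pd_after": pd_after,
            "pd_change_deg": db, "mean_error": after.mean_error,
            "result_before": before, "result_after": after}


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def mass_change_protocol(engine: Engine, masses=(0.8, 1.2), n_reps=6):
    """Center-out reaching at altered link masses (the rest posture is
    unaffected: there is no gravity)."""
    out = {}
    for mass in masses:
        engine.plant.arm.m1 = engine.plant.arm.m2 = float(mass)
        engine.plant._pack()   # run() reads plant args freshly each call
        res = center_out(engine, n_reps=n_reps)
        out[mass] = res
    return out


# ---------------------------------------------------------------------------


@dataclass
class DirectionField:
    """Initial hand-movement directions on a grid, per stimulation site(s)."""
    grid: np.ndarray          # (n_points, 2) hand positions
    vectors: np.ndarray       # (n_points, 2) unit vectors
    sites: tuple              # stimulated muscle trios

    def angles(self):
        return np.arctan2(self.vectors[:, 1], self.vectors[:, 0])

    def fixed_point(self):
        """Grid point with the smallest mean inward-flow residual: the point
        toward which the field converges (coarse estimate)."""
        score = np.zeros(len(self.grid))
        for i, p in enumerate(self.grid):
            d = p - self.grid
            nrm = np.linalg.norm(d, axis=1)
            ok = nrm > 1e-9
            score[i] = np.mean(np.sum(self.vectors[ok] * d[ok]
                                      / nrm[ok, None], axis=1))
        return self.grid[np.argmax(score)]


def field_grid(center, half_width=0.10, n=5):
    xs = np.linspace(center[0] - half_width, center[0] + half_width, n)
    ys = np.linspace(center[1] - half_width, center[1] + half_width, n)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def spinal_stimulation(engine: Engine, sites, grid=None, amplitude=0.3,
                       hold=0.4, window=0.15) -> DirectionField:
    """Direction field from stimulating spinal E-I pairs in the isolated C.

    All populations except C are silenced.  For each grid hand position the
    arm is held static while the stimulated circuit settles (`hold` s), then
    released; the field vector is the direction of the average hand velocity
    over the first `window` s after release.  Grid points outside the
    workspace are skipped with a log entry.
    """
    nw = engine.network
    plant = nw.plant
    if grid is None:
        grid = field_grid(plant.hand_position(np.asarray(plant.arm.rest_q)))
    stim = np.zeros(net.N_UNITS)
    for s in sites:
        stim[net.CE.start + s] = amplitude
        stim[net.CI.start + s] = amplitude

    vecs = []
    pts = []
    for p in grid:
        try:
            q = plant.inverse_kinematics(p)
        except ValueError:
            log.info("grid point %s outside the workspace, skipped", p)
            continue
        engine.reset(q=q)
        engine.isolate_spinal()
        engine.run(hold, stim=stim, freeze_plant_for=hold,
                   record_every=engine.cfg.dt * 10)
        tr = engine.run(window, stim=stim, record_every=engine.cfg.dt)
        v = tr.hand[-1] - tr.hand[0]
        nv = np.linalg.norm(v)
        vecs.append(v / nv if nv > 1e-12 else np.zeros(2))
        pts.append(p)
    return DirectionField(np.asarray(pts), np.asarray(vecs), tuple(sites))


def all_direction_fields(make_engine, amplitude=0.3, grid=None,
                         include_pairs=True):
    """Direction fields for all 6 single sites, all 15 pairs, and rest.

    `make_engine` is a zero-argument factory returning a fresh engine (the
    isolated-C run mutates engine state)."""
    fields = {}
    eng = make_engine()
    singles = [(i,) for i in range(6)]
    pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)] \
        if include_pairs else []
    for sites in [()] + singles + pairs:
        fields[sites] = spinal_stimulation(eng, sites, grid=grid,
                                           amplitude=amplitude)
    return fields
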