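"""Trial execution, pair evaluation, treatments and counterfactual probes.

One trial lasts 100 time steps.  Within a step the order of events is:
the sender senses (sine/cosine of its position plus the food floor sensor)
and updates its network, producing this step's emitted amplitude; the
perceived amplitude is computed from this step's positions and emission
(nest-gated); the receiver senses (sine/cosine plus perceived amplitude) and
updates its network; finally both agents move.  Logged positions are the
positions the agents occupied *during* the step, before moving.

Performance of a trial is 0.01 per time step the receiver spends on the
food-bearing site during the last 20 steps (t = 81..100), so at most 0.2 per
trial and 1.0 over the five trials of an evaluation.

Because the sender receives no input from (or about) the receiver, its
trajectory and emission are autonomous given the food site.  The
receiver-side probes (mean-amplitude replay, onset shift) therefore replay
the sender's logged positions and emissions exactly, and only re-simulate
the receiver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ctrnn
from .world import WorldSpec, default_world, food_sensor, normalize_angle

#: Perceived amplitude above this threshold counts as signal onset.  Sigmoid
#: outputs are never exactly zero, so a small positive threshold is needed;
#: 0.05 is a documented sensitivity alternative.
ONSET_THRESHOLD = 1e-6

SCORED_STEPS = slice(80, 100)  # t = 81..100 (1-based) of a 100-step trial

MODES = ("communication", "no_communication", "constrained_sender")
PROBES = ("none", "fixed_amplitude", "mean_amplitude_replay", "onset_shift", "duration_lock")


@dataclass(frozen=True)
class Treatment:
    """Experimental condition of a trial or evolutionary run.

    ``mode`` applies during evolution: free communication, perceived signal
    clamped to zero, or sender motion fixed (full speed, counterclockwise;
    signal output still network-controlled).  ``probe`` names a post-hoc
    manipulation applied to evolved agents at evaluation time only.
    """

    mode: str = "communication"
    probe: str = "none"
    fixed_amplitude: float | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown treatment mode {self.mode!r}")
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}")
        if self.probe == "fixed_amplitude":
            if self.fixed_amplitude is None or not 0.0 <= self.fixed_amplitude <= 1.0:
                raise ValueError("fixed_amplitude probe needs an amplitude in [0, 1]")


@dataclass
class TrialLog:
    """Per-step record of one 100-step trial."""

    food_site: int
    sender_pos: np.ndarray
    receiver_pos: np.ndarray
    emitted: np.ndarray
    perceived: np.ndarray
    food: np.ndarray

    def __len__(self):
        return len(self.sender_pos)

    def on_food(self, world: WorldSpec) -> np.ndarray:
        """Boolean per-step indicator: receiver inside the food-bearing arc."""
        return np.asarray(world.sites[self.food_site].contains(self.receiver_pos))


@dataclass
class PairPerformance:
    """Per-trial performance p_T (each in [0, 0.2]) and their sum (in [0, 1])."""

    per_trial: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_trial.sum())


def trial_performance(log: TrialLog, world: WorldSpec) -> float:
    """p_T = 0.01 x (number of scored steps t=81..100 the receiver is on food)."""
    if len(log) != world.trial_steps:
        raise ValueError("incomplete trial log")
    return 0.01 * int(log.on_food(world)[SCORED_STEPS].sum())


def sensor_vector(role, position, third_input):
    """Three sensory inputs: sin and cos of own position, plus the role's
    extra channel (food floor sensor for senders, perceived amplitude for
    receivers)."""
    return np.array([np.sin(position), np.cos(position), third_input])


def trial_logs_to_dataframe(logs, world: WorldSpec | None = None):
    """Tidy per-step table for a set of trial logs.

    Columns: trial, step (1-based), sender_pos, receiver_pos, emitted,
    perceived, food_site, on_food.  Write with ``.to_csv(path, index=False)``.
    """
    import pandas as pd

    world = world or default_world()
    frames = []
    for trial, log in enumerate(logs):
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial,
                    "step": np.arange(1, len(log) + 1),
                    "sender_pos": log.sender_pos,
                    "receiver_pos": log.receiver_pos,
                    "emitted": log.emitted,
                    "perceived": log.perceived,
                    "food_site": log.food_site,
                    "on_food": log.on_food(world),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_trial(
    sender: ctrnn.Genome,
    receiver: ctrnn.Genome,
    food_site: int,
    world: WorldSpec | None = None,
    treatment: Treatment | None = None,
    *,
    integration: str = ctrnn.DEFAULT_INTEGRATION,
    sender_start: float = 0.0,
    receiver_start: float = 0.0,
    sender_replay: tuple[np.ndarray, np.ndarray] | None = None,
    perceived_amplitude: np.ndarray | None = None,
    perceived_shift: int = 0,
    duration_lock: bool = False,
) -> TrialLog:
    """Simulate one trial and return its full log.

    Both agents start at position 0 by default with freshly initialized
    networks (internal states zero).  Keyword hooks implement the probes:

    * ``sender_replay=(positions, emitted)`` replaces the live sender with a
      logged trajectory and emission stream (exact, because senders are
      autonomous).
    * ``perceived_amplitude`` replaces the emitted stream used for the
      receiver's perception (still nest-gated by sender and receiver
      positions) — the mean-amplitude replay.
    * ``perceived_shift`` delays the receiver's perception timeline by a
      whole number of steps: at step t the receiver perceives what the
      sender-side stream carried at step t - shift (zero before onset).
    * ``duration_lock`` freezes the sender's motion upon its first re-entry
      into the nest (the initial residence at the start position does not
      arm the lock, since both agents begin inside the nest).
    """
    world = world or default_world()
    treatment = treatment or Treatment()
    if not 0 <= food_site < len(world.sites):
        raise IndexError(f"invalid foraging-site index {food_site}")
    n_steps = world.trial_steps

    if sender_replay is not None:
        replay_pos, replay_emit = (np.asarray(a, dtype=float) for a in sender_replay)
        if len(replay_pos) != n_steps or len(replay_emit) != n_steps:
            raise ValueError("sender replay streams must cover the whole trial")
    else:
        replay_pos = replay_emit = None
        sp = ctrnn.decode_genome(sender)
        s_state = ctrnn.init_state(sp)
    if perceived_shift < 0:
        raise ValueError("perceived_shift is a delay and must be >= 0")

    rp = ctrnn.decode_genome(receiver)
    r_state = ctrnn.init_state(rp)

    pos_s = float(normalize_angle(sender_start))
    pos_r = float(normalize_angle(receiver_start))

    log_s = np.empty(n_steps)
    log_r = np.empty(n_steps)
    log_e = np.empty(n_steps)
    log_p = np.empty(n_steps)
    log_f = np.empty(n_steps)

    # signal stream as produced sender-side (pre-shift), for the shift probe
    stream_emit = np.zeros(n_steps)
    stream_in_nest = np.zeros(n_steps, dtype=bool)

    lock_armed = False  # sender has left the nest at least once
    lock_frozen = False

    for t in range(n_steps):
        if replay_pos is not None:
            pos_s = float(replay_pos[t])
        food = float(food_sensor(pos_s, food_site, world))

        if replay_pos is not None:
            emitted = float(replay_emit[t])
            speed_s, dir_s = 0.0, 1.0  # position comes from the replay stream
        else:
            s_state = ctrnn.ctrnn_step(
                sp, s_state, sensor_vector("sender", pos_s, food), integration
            )
            out = s_state.y[-sp.n_outputs :]
            emitted = float(out[2])
            speed_s, dir_s = ctrnn.motor_command(out[0], out[1], world.max_speed)

        if treatment.probe == "fixed_amplitude":
            emitted = float(treatment.fixed_amplitude)

        sender_in_nest = bool(world.nest.contains(pos_s))
        receiver_in_nest = bool(world.nest.contains(pos_r))

        stream_emit[t] = emitted if perceived_amplitude is None else float(perceived_amplitude[t])
        stream_in_nest[t] = sender_in_nest

        u = t - perceived_shift
        if u >= 0 and stream_in_nest[u] and receiver_in_nest:
            perceived = float(stream_emit[u])
        else:
            perceived = 0.0
        if treatment.mode == "no_communication":
            perceived = 0.0

        r_state = ctrnn.ctrnn_step(
            rp, r_state, sensor_vector("receiver", pos_r, perceived), integration
        )
        r_out = r_state.y[-rp.n_outputs :]
        speed_r, dir_r = ctrnn.motor_command(r_out[0], r_out[1], world.max_speed)

        log_s[t] = pos_s
        log_r[t] = pos_r
        log_e[t] = emitted
        log_p[t] = perceived
        log_f[t] = food

        # movement overrides
        if treatment.mode == "constrained_sender":
            speed_s, dir_s = world.max_speed, 1.0
        if duration_lock:
            if not sender_in_nest:
                lock_armed = True
            elif lock_armed:
                lock_frozen = True
            if lock_frozen:
                speed_s = 0.0

        if replay_pos is None:
            pos_s = float(normalize_angle(pos_s + dir_s * speed_s))
        pos_r = float(normalize_angle(pos_r + dir_r * speed_r))

    return TrialLog(
        food_site=food_site,
        sender_pos=log_s,
        receiver_pos=log_r,
        emitted=log_e,
        perceived=log_p,
        food=log_f,
    )


def run_pair(
    sender: ctrnn.Genome,
    receiver: ctrnn.Genome,
    food_order,
    world: WorldSpec | None = None,
    treatment: Treatment | None = None,
    **trial_kwargs,
) -> tuple[PairPerformance, list[TrialLog]]:
    """Evaluate a pair over five trials (food at each site once, in the given
    order), resetting both networks between trials; returns performance and
    the five logs."""
    world = world or default_world()
    food_order = np.asarray(food_order)
    if sorted(food_order.tolist()) != list(range(len(world.sites))):
        raise ValueError("food_order must be a permutation of the five sites")
    logs = [
        run_trial(sender, receiver, int(site), world, treatment, **trial_kwargs)
        for site in food_order
    ]
    per_trial = np.array([trial_performance(log, world) for log in logs])
    return PairPerformance(per_trial=per_trial), logs


def evaluate_pair(sender, receiver, food_order, world=None, treatment=None) -> PairPerformance:
    """Five-trial evaluation; see :func:`run_pair`."""
    perf, _ = run_pair(sender, receiver, food_order, world, treatment)
    return perf


# ---------------------------------------------------------------------------
# Post-hoc probes on evolved pairs.  Control logs are from run_pair under the
# pair's evolutionary treatment.


def probe_fixed_amplitude(
    sender, receiver, food_order, fixed_amplitude, world=None, treatment=None
) -> PairPerformance:
    """Re-evaluate with the emitted amplitude clamped to a constant,
    removing any food-location information carried by amplitude (gating, and
    hence onset/duration information, is untouched)."""
    world = world or default_world()
    base = treatment or Treatment()
    probe = Treatment(mode=base.mode, probe="fixed_amplitude", fixed_amplitude=fixed_amplitude)
    perf, _ = run_pair(sender, receiver, food_order, world, probe)
    return perf


def mean_amplitude_stream(control_logs) -> np.ndarray:
    """Per-step mean of the emitted amplitude across the five trials."""
    return np.mean([log.emitted for log in control_logs], axis=0)


def probe_mean_amplitude_replay(
    control_logs, receiver, world=None, treatment=None
) -> PairPerformance:
    """Replay each trial feeding the receiver the across-trial mean amplitude.

    The replacement stream is identical in all five trials, so any residual
    performance cannot rest on amplitude differences between trials.  Gating
    still uses the logged sender positions and the live receiver position.
    """
    world = world or default_world()
    a_u = mean_amplitude_stream(control_logs)
    per_trial = []
    for log in control_logs:
        new_log = run_trial(
            sender=None,
            receiver=receiver,
            food_site=log.food_site,
            world=world,
            treatment=treatment,
            sender_replay=(log.sender_pos, log.emitted),
            perceived_amplitude=a_u,
        )
        per_trial.append(trial_performance(new_log, world))
    return PairPerformance(per_trial=np.array(per_trial))


def onset_delay(log_or_perceived, threshold: float = ONSET_THRESHOLD):
    """Onset-delay: the step (1-based) at which the receiver first perceives
    a signal above ``threshold``; None if it never does.

    Both agents begin every trial inside the nest, so a perception episode
    that is already in progress at step 1 is the trial-start co-presence
    artifact and carries no information about food location; it is skipped
    and the start of the next perception episode is reported instead.
    """
    perceived = np.asarray(getattr(log_or_perceived, "perceived", log_or_perceived))
    above = perceived > threshold
    starts = np.nonzero(above & ~np.concatenate(([False], above[:-1])))[0]
    if starts.size and starts[0] == 0:
        starts = starts[1:]
    return int(starts[0]) + 1 if starts.size else None


def onset_shift_steps(control_logs, threshold: float = ONSET_THRESHOLD):
    """Mean absolute pairwise difference of the control onset-delays across
    trials, rounded to whole steps; None when fewer than two trials have a
    measurable onset (probe inapplicable)."""
    onsets = [onset_delay(log, threshold) for log in control_logs]
    onsets = [o for o in onsets if o is not None]
    if len(onsets) < 2:
        return None
    diffs = [abs(a - b) for i, a in enumerate(onsets) for b in onsets[i + 1 :]]
    return int(round(float(np.mean(diffs))))


def probe_onset_shift(
    control_logs, receiver, world=None, treatment=None, threshold: float = ONSET_THRESHOLD
) -> PairPerformance | None:
    """Delay the receiver's perception timeline by the pair's own mean
    between-trial onset difference, destroying onset-delay information while
    leaving amplitude and (approximately) duration untouched.  Returns None
    when the probe is inapplicable (no measurable onsets)."""
    world = world or default_world()
    shift = onset_shift_steps(control_logs, threshold)
    if shift is None:
        return None
    per_trial = []
    for log in control_logs:
        new_log = run_trial(
            sender=None,
            receiver=receiver,
            food_site=log.food_site,
            world=world,
            treatment=treatment,
            sender_replay=(log.sender_pos, log.emitted),
            perceived_shift=shift,
        )
        per_trial.append(trial_performance(new_log, world))
    return PairPerformance(per_trial=np.array(per_trial))


def probe_duration_lock(
    sender, receiver, food_order, world=None, treatment=None
) -> PairPerformance:
    """Re-evaluate with the sender frozen in place upon its first re-entry
    into the nest, fixing the co-presence (signal-duration) pattern."""
    world = world or default_world()
    perf, _ = run_pair(
        sender, receiver, food_order, world, treatment, duration_lock=True
    )
    return perf
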