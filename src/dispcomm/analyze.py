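"""Analysis of evolved communication strategies.

Covers the food-found classification, success histograms, the between-trial
signal-amplitude variation statistic S', onset-delay extraction, the two
evolutionary milestones (first between-trial onset variation; first
generation significantly above the 0.2 no-communication ceiling) and the
nonparametric comparisons used for treatment and probe contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import simulate
from .evolve import EvolutionRun, GenerationHistory
from .simulate import ONSET_THRESHOLD, PairPerformance, TrialLog, onset_delay
from .world import WorldSpec, default_world

#: A receiver "found food" in a trial when it spent at least this many of the
#: last 20 steps on the food-bearing site (equivalently p_T >= 0.15).
FOUND_FOOD_MIN_STEPS = 15


def found_food(trial_log: TrialLog, world: WorldSpec | None = None,
               min_steps: int = FOUND_FOOD_MIN_STEPS) -> bool:
    """True iff the receiver was on food for >= min_steps of the scored steps."""
    world = world or default_world()
    if len(trial_log) != world.trial_steps:
        raise ValueError("incomplete trial log")
    return int(trial_log.on_food(world)[simulate.SCORED_STEPS].sum()) >= min_steps


def found_food_from_counts(counts: np.ndarray, min_steps: int = FOUND_FOOD_MIN_STEPS) -> np.ndarray:
    """Vectorized food-found classification from scored on-food step counts."""
    return np.asarray(counts) >= min_steps


def success_histogram(found: np.ndarray) -> np.ndarray:
    """Six-bin histogram of receivers by number of successful trials (0..5).

    ``found`` is a boolean (n_pairs, 5) matrix; bins sum to the population
    size.
    """
    found = np.asarray(found, dtype=bool)
    if found.ndim != 2 or found.shape[1] != 5:
        raise ValueError("expected a (n_pairs, 5) found-food matrix")
    return np.bincount(found.sum(axis=1), minlength=6)


def signal_variation(
    sender_logs, found: np.ndarray | None = None, restrict_to_found: bool = True
) -> float | None:
    """Mean between-trial amplitude variation S' of one sender.

    For each time step u, the mean absolute difference of emitted amplitude
    over ordered pairs of distinct trials is computed with the coefficient
    2/(|T|(|T|-1)); the statistic is the average over the 100 steps.  Since
    the ordered-pair sum counts each unordered pair twice, S' equals twice
    the mean unordered pairwise difference.  S' = 0 iff the emission
    profiles of the considered trials are identical.

    With ``restrict_to_found``, only trials whose receiver found the food
    enter the trial set T; returns None (statistic undefined) when fewer
    than two trials remain.
    """
    emitted = np.asarray([log.emitted for log in sender_logs])
    if restrict_to_found:
        if found is None:
            raise ValueError("restrict_to_found requires the found-food mask")
        emitted = emitted[np.asarray(found, dtype=bool)]
    m = emitted.shape[0]
    if m < 2:
        return None
    # |s_u,t1 - s_u,t2| over ordered pairs, coefficient 2/(m(m-1)), mean over u
    diffs = np.abs(emitted[:, None, :] - emitted[None, :, :]).sum(axis=(0, 1))
    per_step = 2.0 / (m * (m - 1)) * diffs
    return float(per_step.mean())


def population_signal_variation(per_sender: list[float | None]) -> tuple[float, int]:
    """Mean S' over senders with a defined statistic; returns (mean, n_excluded)."""
    defined = [s for s in per_sender if s is not None]
    excluded = len(per_sender) - len(defined)
    if not defined:
        return float("nan"), excluded
    return float(np.mean(defined)), excluded


@dataclass
class MilestoneReport:
    """Generations (0-based) of the two evolutionary events and their gap.

    ``generation_onset_variation``: first generation whose representative
    sender shows between-trial onset-delay differences beyond tolerance.
    ``generation_exceeds_threshold``: first generation whose per-pair
    performances are significantly above the no-communication ceiling.
    Undefined milestones are None, never silently 0.
    """

    generation_onset_variation: int | None
    generation_exceeds_threshold: int | None

    @property
    def gap(self) -> int | None:
        if None in (self.generation_onset_variation, self.generation_exceeds_threshold):
            return None
        return self.generation_exceeds_threshold - self.generation_onset_variation


def _onset_spread(onsets: np.ndarray) -> float:
    """Max-min spread of the defined (non-negative) onset-delays; 0 when
    fewer than two trials ever perceived a signal."""
    defined = onsets[onsets >= 0]
    if defined.size < 2:
        return 0.0
    return float(defined.max() - defined.min())


def first_onset_variation_generation(
    history: GenerationHistory, tolerance: float = 1.0, aggregation: str = "best"
) -> int | None:
    """First generation with between-trial onset-delay variation.

    ``aggregation="best"`` inspects the best-performing pair of each
    generation; ``"median"`` requires per-pair onsets for the whole
    population (``store_onsets="all"``) and uses the population median
    spread.  Returns None when the variation never exceeds ``tolerance``
    steps.
    """
    if aggregation == "best":
        spreads = np.array([_onset_spread(o) for o in history.best_onsets])
    elif aggregation == "median":
        if history.all_onsets is None:
            raise ValueError("median aggregation needs store_onsets='all'")
        spreads = np.array(
            [np.median([_onset_spread(o) for o in gen]) for gen in history.all_onsets]
        )
    else:
        raise ValueError("aggregation must be 'best' or 'median'")
    hits = np.nonzero(spreads > tolerance)[0]
    return int(hits[0]) if hits.size else None


def first_exceeds_threshold_generation(
    history: GenerationHistory, threshold: float = 0.2, alpha: float = 0.01
) -> int | None:
    """First generation whose per-pair performances are significantly above
    ``threshold`` (one-sided Wilcoxon signed-rank test at ``alpha``)."""
    for g in range(history.n_generations):
        perf = history.performances(g)
        if not np.any(perf > threshold):
            continue
        diffs = perf - threshold
        try:
            _, p = stats.wilcoxon(diffs, alternative="greater")
        except ValueError:  # e.g. all differences zero after zero-handling
            continue
        if p < alpha:
            return g
    return None


def milestone_report(
    history: GenerationHistory,
    threshold: float = 0.2,
    alpha: float = 0.01,
    onset_tolerance: float = 1.0,
    aggregation: str = "best",
) -> MilestoneReport:
    return MilestoneReport(
        generation_onset_variation=first_onset_variation_generation(
            history, onset_tolerance, aggregation
        ),
        generation_exceeds_threshold=first_exceeds_threshold_generation(
            history, threshold, alpha
        ),
    )


@dataclass
class TestReport:
    """A two-sample Mann-Whitney U comparison."""

    statistic: float
    p_value: float
    median_a: float
    median_b: float

    @property
    def a_greater(self) -> bool:
        return self.median_a > self.median_b


def compare_treatments(perf_a, perf_b) -> TestReport:
    """Two-sided Mann-Whitney U between two independent performance samples."""
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestReport(
        statistic=float(u),
        p_value=float(p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def correlate_milestones(x, y) -> tuple[float, float]:
    """Pearson correlation between per-population milestone generations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Final-population analysis: control evaluations, S', probes.


@dataclass
class PairAnalysis:
    control: PairPerformance
    logs: list
    found: np.ndarray  # (5,) bool
    onsets: list
    s_prime: float | None


@dataclass
class PopulationAnalysis:
    """Per-pair control statistics plus probe performances for one population."""

    pairs: list[PairAnalysis]
    probe_totals: dict[str, np.ndarray]  # probe name -> per-pair totals (NaN: inapplicable)

    @property
    def control_totals(self) -> np.ndarray:
        return np.array([p.control.total for p in self.pairs])

    @property
    def found_matrix(self) -> np.ndarray:
        return np.array([p.found for p in self.pairs])

    def mean_signal_variation(self) -> tuple[float, int]:
        return population_signal_variation([p.s_prime for p in self.pairs])

    def probe_test(self, probe: str) -> TestReport:
        """Control vs probe per-pair totals (inapplicable pairs dropped)."""
        probed = self.probe_totals[probe]
        ok = ~np.isnan(probed)
        return compare_treatments(self.control_totals[ok], probed[ok])

    def probe_decreases(self, probe: str, alpha: float = 0.01) -> bool:
        """True when the probe significantly decreased performance."""
        rep = self.probe_test(probe)
        return rep.p_value < alpha and rep.a_greater


def analyze_population(
    run: EvolutionRun,
    probes: tuple[str, ...] = (),
    world: WorldSpec | None = None,
    seed: int = 0,
    fixed_amplitude: float = 0.5,
    onset_threshold: float = ONSET_THRESHOLD,
) -> PopulationAnalysis:
    """Control-evaluate every pair of a run's final population and apply the
    requested probes ("fixed_amplitude", "mean_amplitude_replay",
    "onset_shift", "duration_lock").

    Food orders are re-randomized per pair from ``seed``; control and probe
    evaluations of a pair share the same food order so the manipulation is
    the only difference.
    """
    world = world or default_world()
    rng = np.random.default_rng(seed)
    treatment = run.config.treatment
    integration = run.config.integration
    pop = run.population

    pairs: list[PairAnalysis] = []
    probe_totals = {p: np.full(pop.n_pairs, np.nan) for p in probes}
    for i in range(pop.n_pairs):
        sender, receiver = pop.pair(i)
        food_order = rng.permutation(5)
        perf, logs = simulate.run_pair(
            sender, receiver, food_order, world, treatment, integration=integration
        )
        found = np.array([found_food(log, world) for log in logs])
        pairs.append(
            PairAnalysis(
                control=perf,
                logs=logs,
                found=found,
                onsets=[onset_delay(log, onset_threshold) for log in logs],
                s_prime=signal_variation(logs, found),
            )
        )
        for probe in probes:
            if probe == "fixed_amplitude":
                r = simulate.probe_fixed_amplitude(
                    sender, receiver, food_order, fixed_amplitude, world, treatment
                )
            elif probe == "mean_amplitude_replay":
                r = simulate.probe_mean_amplitude_replay(logs, receiver, world, treatment)
            elif probe == "onset_shift":
                r = simulate.probe_onset_shift(logs, receiver, world, treatment, onset_threshold)
            elif probe == "duration_lock":
                r = simulate.probe_duration_lock(
                    sender, receiver, food_order, world, treatment
                )
            else:
                raise ValueError(f"unknown probe {probe!r}")
            if r is not None:
                probe_totals[probe][i] = r.total
    return PopulationAnalysis(pairs=pairs, probe_totals=probe_totals)
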