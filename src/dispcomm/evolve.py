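"""Artificial evolution: populations, selection, mutation, and the
generational loop with history logging and checkpoint/resume.

A population holds ``n_pairs`` sender genomes and as many receiver genomes;
pair ``i`` is row ``i`` of both arrays.  Every generation each pair is
evaluated over five trials (food at each site once, order re-randomized per
pair per generation).  Senders and receivers are then selected in separate
tournament streams (size 10, sampling with replacement, each individual
scored by its pair's total performance), offspring genes are mutated
independently with per-gene probability ``mu / genome_length`` (so the
expected number of mutations per genome is ``mu`` regardless of role), and
offspring are randomly re-paired.  There is no crossover and no elitism;
generations do not overlap.

A mutated gene is redrawn from a normal distribution centered on its current
value (sd 0.1 by default; ``mutation_center="mid"`` recenters on 0.5
instead) and reflected back into ``[0, 1]`` so the bound is respected
without probability mass piling up at the edges.

All randomness flows through named, independently seeded streams (init,
food order, selection, mutation, pairing) derived from one master seed, so
toggling one stochastic component leaves the draws of the others unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import ctrnn
from . import _kernels
from .simulate import ONSET_THRESHOLD, Treatment
from .world import WorldSpec, default_world

STREAM_NAMES = ("init", "food", "selection", "mutation", "pairing")


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary run.

    Defaults are the full-scale experiment (25'000 generations of 1'000
    pairs); tests and desk runs pass reduced values.
    """

    generations: int = 25_000
    n_pairs: int = 1_000
    tournament_size: int = 10
    mu: float = 0.5  # expected mutations per genome per generation
    mutation_sd: float = 0.1
    mutation_center: str = "gene"  # "gene" (current value) or "mid" (0.5)
    mode: str = "communication"
    integration: str = ctrnn.DEFAULT_INTEGRATION
    pairing: str = "reshuffle"  # or "fixed": keep lifetime pairs
    onset_threshold: float = ONSET_THRESHOLD
    store_onsets: str = "best"  # "best" pair only, or "all" pairs

    def __post_init__(self):
        if self.generations <= 0 or self.n_pairs <= 0:
            raise ValueError("generations and n_pairs must be positive")
        if not 0 < self.mu < min(g.genome_length for g in ctrnn.ARCHITECTURES.values()):
            raise ValueError("mu must be in (0, genome length)")
        if self.tournament_size < 1 or self.tournament_size > self.n_pairs:
            raise ValueError("tournament size must be in [1, n_pairs]")
        Treatment(mode=self.mode)  # validates the mode
        if self.mutation_center not in ("gene", "mid"):
            raise ValueError("mutation_center must be 'gene' or 'mid'")
        if self.pairing not in ("reshuffle", "fixed"):
            raise ValueError("pairing must be 'reshuffle' or 'fixed'")

    @property
    def treatment(self) -> Treatment:
        return Treatment(mode=self.mode)


@dataclass
class RandomStreams:
    """Named RNG streams spawned from one master seed."""

    init: np.random.Generator
    food: np.random.Generator
    selection: np.random.Generator
    mutation: np.random.Generator
    pairing: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RandomStreams":
        children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
        return cls(**{n: np.random.default_rng(s) for n, s in zip(STREAM_NAMES, children)})

    def state(self) -> dict:
        return {n: getattr(self, n).bit_generator.state for n in STREAM_NAMES}

    def restore(self, state: dict) -> None:
        for n in STREAM_NAMES:
            getattr(self, n).bit_generator.state = state[n]


@dataclass
class Population:
    """Sender and receiver genomes; pair i is row i of both matrices."""

    sender_genes: np.ndarray  # (n_pairs, 77)
    receiver_genes: np.ndarray  # (n_pairs, 70)

    def __post_init__(self):
        if self.sender_genes.shape[0] != self.receiver_genes.shape[0]:
            raise ValueError("sender and receiver counts must be equal")

    @property
    def n_pairs(self) -> int:
        return self.sender_genes.shape[0]

    def pair(self, i: int) -> tuple[ctrnn.Genome, ctrnn.Genome]:
        return (
            ctrnn.Genome(self.sender_genes[i].copy(), ctrnn.SENDER),
            ctrnn.Genome(self.receiver_genes[i].copy(), ctrnn.RECEIVER),
        )


def save_population_csv(population: Population, senders_path, receivers_path) -> None:
    """Write genomes as plain CSV, one individual per row, one gene per
    column (the documented gene ordering: weights, biases, time constants)."""
    np.savetxt(senders_path, population.sender_genes, delimiter=",", fmt="%.17g")
    np.savetxt(receivers_path, population.receiver_genes, delimiter=",", fmt="%.17g")


def load_population_csv(senders_path, receivers_path) -> Population:
    """Inverse of :func:`save_population_csv` (validates genome lengths)."""
    senders = np.atleast_2d(np.loadtxt(senders_path, delimiter=","))
    receivers = np.atleast_2d(np.loadtxt(receivers_path, delimiter=","))
    for genes, arch in ((senders, ctrnn.SENDER_ARCH), (receivers, ctrnn.RECEIVER_ARCH)):
        if genes.shape[1] != arch.genome_length:
            raise ValueError(f"expected {arch.genome_length} genes, got {genes.shape[1]}")
    return Population(sender_genes=senders, receiver_genes=receivers)


def init_population(n_pairs: int, rng: np.random.Generator) -> Population:
    """Uniform-[0,1] genomes for every sender and receiver."""
    return Population(
        sender_genes=rng.random((n_pairs, ctrnn.SENDER_ARCH.genome_length)),
        receiver_genes=rng.random((n_pairs, ctrnn.RECEIVER_ARCH.genome_length)),
    )


def mutation_rate(genome_length: int, mu: float) -> float:
    """Per-gene mutation probability mu / genome_length, so the expected
    mutation count per genome equals mu for both roles."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return mu / genome_length


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect real values into [0, 1] (triangle-wave fold)."""
    r = np.mod(x, 2.0)
    return np.where(r > 1.0, 2.0 - r, r)


def mutate_genes(
    genes: np.ndarray,
    per_gene_rate: float,
    rng: np.random.Generator,
    sd: float = 0.1,
    center: str = "gene",
) -> np.ndarray:
    """Independently mutate each gene with the given probability.

    Mutated genes are redrawn from a normal centered on the current value
    (or on 0.5 with ``center="mid"``) and reflected into [0, 1]; unmutated
    genes are copied bit-identically.
    """
    if not 0.0 <= per_gene_rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    out = genes.copy()
    mask = rng.random(genes.shape) < per_gene_rate
    n_mut = int(mask.sum())
    if n_mut:
        loc = genes[mask] if center == "gene" else 0.5
        out[mask] = _reflect_unit(rng.normal(loc, sd, size=n_mut))
    return out


def mutate(genome: ctrnn.Genome, per_gene_rate: float, rng, sd=0.1, center="gene") -> ctrnn.Genome:
    """Single-genome convenience wrapper over :func:`mutate_genes`."""
    new = mutate_genes(genome.genes[None, :], per_gene_rate, rng, sd, center)[0]
    return ctrnn.Genome(genes=new, role=genome.role)


def tournament_select_indices(
    performances: np.ndarray, n_winners: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Run ``n_winners`` independent tournaments of size ``k``.

    Candidates are sampled uniformly with replacement; the best candidate
    wins.  Ties resolve to the first maximal candidate, which is uniform
    among tied individuals because candidate order is itself i.i.d. uniform.
    """
    n = len(performances)
    if n == 0:
        raise ValueError("empty population")
    if k > n:
        raise ValueError("tournament size exceeds population size")
    candidates = rng.integers(0, n, size=(n_winners, k))
    winners = np.argmax(performances[candidates], axis=1)
    return candidates[np.arange(n_winners), winners]


def tournament_select(population, performances, k, rng) -> int:
    """One tournament; returns the winning pair index."""
    return int(tournament_select_indices(np.asarray(performances), 1, k, rng)[0])


def next_generation(
    population: Population,
    performances: np.ndarray,
    config: EvolutionConfig,
    streams: RandomStreams,
) -> Population:
    """Select, mutate and re-pair to produce the next generation.

    Tournaments run separately on the sender group and the receiver group;
    each individual's fitness is its pair's total performance.
    """
    n = population.n_pairs
    k = config.tournament_size
    perf = np.asarray(performances, dtype=float)
    idx_s = tournament_select_indices(perf, n, k, streams.selection)
    idx_r = tournament_select_indices(perf, n, k, streams.selection)

    rate_s = mutation_rate(ctrnn.SENDER_ARCH.genome_length, config.mu)
    rate_r = mutation_rate(ctrnn.RECEIVER_ARCH.genome_length, config.mu)
    senders = mutate_genes(
        population.sender_genes[idx_s], rate_s, streams.mutation,
        config.mutation_sd, config.mutation_center,
    )
    receivers = mutate_genes(
        population.receiver_genes[idx_r], rate_r, streams.mutation,
        config.mutation_sd, config.mutation_center,
    )
    if config.pairing == "reshuffle":
        receivers = receivers[streams.pairing.permutation(n)]
    return Population(sender_genes=senders, receiver_genes=receivers)


def random_food_orders(n_pairs: int, rng: np.random.Generator, n_sites: int = 5) -> np.ndarray:
    """A fresh random site permutation for every pair."""
    return rng.permuted(np.tile(np.arange(n_sites), (n_pairs, 1)), axis=1)


def evaluate_population(
    population: Population,
    food_orders: np.ndarray,
    config: EvolutionConfig,
    world: WorldSpec | None = None,
):
    """Evaluate all pairs through their five trials (compiled kernel).

    Returns ``(totals, counts, onsets)``: per-pair total performance,
    per-pair per-trial scored on-food step counts, and per-pair per-trial
    onset-delays (-1 where no signal was ever perceived).
    """
    world = world or default_world()
    sp = ctrnn.decode_population(population.sender_genes, ctrnn.SENDER_ARCH)
    rp = ctrnn.decode_population(population.receiver_genes, ctrnn.RECEIVER_ARCH)
    counts, onsets = _kernels.evaluate_generation(
        sp.w_in, sp.w_hh, sp.w_out, sp.bias, sp.tau,
        rp.w_in, rp.w_hh, rp.w_out, rp.bias, rp.tau,
        np.ascontiguousarray(food_orders, dtype=np.int64),
        world.site_centers,
        world.site_length / 2.0,
        world.nest.length / 2.0,
        world.max_speed,
        world.trial_steps,
        ctrnn.ALPHA,
        _kernels.MODE_CODES[config.mode],
        config.integration == "printed",
        config.onset_threshold,
    )
    totals = counts.sum(axis=1) * 0.01
    return totals, counts, onsets


@dataclass
class GenerationHistory:
    """Per-generation records of one evolutionary run.

    Per-pair totals are stored in centi-performance units (uint8, exact
    because performance is a multiple of 0.01), alongside summary
    statistics, the best pair's identity and its five per-trial
    onset-delays (and, optionally, onsets for every pair).
    """

    per_pair_centi: np.ndarray  # (G, N) uint8
    best_idx: np.ndarray  # (G,)
    best_onsets: np.ndarray  # (G, 5), -1 = never perceived
    all_onsets: np.ndarray | None = None  # (G, N, 5) when stored

    @property
    def n_generations(self) -> int:
        return self.per_pair_centi.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.per_pair_centi.shape[1]

    def performances(self, generation: int | None = None) -> np.ndarray:
        """Per-pair total performances, one generation or the (G, N) matrix."""
        block = self.per_pair_centi if generation is None else self.per_pair_centi[generation]
        return block.astype(float) / 100.0

    @property
    def mean(self) -> np.ndarray:
        return self.per_pair_centi.mean(axis=1) / 100.0

    def quartiles(self) -> tuple[np.ndarray, np.ndarray]:
        q = np.percentile(self.per_pair_centi, [25, 75], axis=1) / 100.0
        return q[0], q[1]

    def to_dataframe(self):
        import pandas as pd

        q1, q3 = self.quartiles()
        return pd.DataFrame(
            {
                "generation": np.arange(self.n_generations),
                "mean_performance": self.mean,
                "q1_performance": q1,
                "q3_performance": q3,
                "max_performance": self.per_pair_centi.max(axis=1) / 100.0,
                "best_pair": self.best_idx,
                **{f"best_onset_trial{j}": self.best_onsets[:, j] for j in range(5)},
            }
        )


@dataclass
class EvolutionRun:
    """A finished (or checkpointed) run: config, seed, history, population."""

    config: EvolutionConfig
    seed: int
    history: GenerationHistory
    population: Population  # population of the last evaluated generation
    next_generation_index: int = 0  # for resume
    stream_state: dict | None = None

    def save(self, path) -> None:
        arrays = {
            "sender_genes": self.population.sender_genes,
            "receiver_genes": self.population.receiver_genes,
            "per_pair_centi": self.history.per_pair_centi,
            "best_idx": self.history.best_idx,
            "best_onsets": self.history.best_onsets,
        }
        if self.history.all_onsets is not None:
            arrays["all_onsets"] = self.history.all_onsets
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "next_generation_index": self.next_generation_index,
            "stream_state": self.stream_state,
        }
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "EvolutionRun":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            history = GenerationHistory(
                per_pair_centi=z["per_pair_centi"],
                best_idx=z["best_idx"],
                best_onsets=z["best_onsets"],
                all_onsets=z["all_onsets"] if "all_onsets" in z else None,
            )
            population = Population(
                sender_genes=z["sender_genes"], receiver_genes=z["receiver_genes"]
            )
        return cls(
            config=EvolutionConfig(**meta["config"]),
            seed=meta["seed"],
            history=history,
            population=population,
            next_generation_index=meta["next_generation_index"],
            stream_state=meta["stream_state"],
        )


def run_evolution(
    config: EvolutionConfig,
    seed: int,
    world: WorldSpec | None = None,
    resume_from: EvolutionRun | None = None,
    checkpoint_path=None,
    checkpoint_every: int | None = None,
    progress: bool = False,
) -> EvolutionRun:
    """Execute the full generational loop, deterministically under ``seed``.

    With ``resume_from`` the loop continues a checkpointed run (same config
    and seed) and yields bit-identical results to an uninterrupted run.
    """
    world = world or default_world()
    G, N = config.generations, config.n_pairs

    per_pair = np.zeros((G, N), dtype=np.uint8)
    best_idx = np.zeros(G, dtype=np.int32)
    best_onsets = np.full((G, 5), -1, dtype=np.int16)
    all_onsets = np.full((G, N, 5), -1, dtype=np.int16) if config.store_onsets == "all" else None

    streams = RandomStreams.from_seed(seed)
    if resume_from is not None:
        if asdict(resume_from.config) != asdict(config) or resume_from.seed != seed:
            raise ValueError("resume requires the same config and seed")
        g0 = resume_from.next_generation_index
        h = resume_from.history
        per_pair[:g0] = h.per_pair_centi[:g0]
        best_idx[:g0] = h.best_idx[:g0]
        best_onsets[:g0] = h.best_onsets[:g0]
        if all_onsets is not None and h.all_onsets is not None:
            all_onsets[:g0] = h.all_onsets[:g0]
        population = resume_from.population
        streams.restore(resume_from.stream_state)
    else:
        g0 = 0
        population = init_population(N, streams.init)

    iterator = range(g0, G)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="generations")
        except ImportError:
            pass

    for g in iterator:
        food_orders = random_food_orders(N, streams.food)
        totals, counts, onsets = evaluate_population(population, food_orders, config, world)
        per_pair[g] = np.round(totals * 100).astype(np.uint8)
        b = int(np.argmax(totals))
        best_idx[g] = b
        best_onsets[g] = onsets[b]
        if all_onsets is not None:
            all_onsets[g] = onsets

        last = g == G - 1
        if not last:
            population = next_generation(population, totals, config, streams)

        if checkpoint_path is not None and (
            last or (checkpoint_every and (g + 1) % checkpoint_every == 0)
        ):
            from pathlib import Path

            target = Path(checkpoint_path)
            if target.suffix != ".npz":  # directory: keep one file per checkpoint
                target.mkdir(parents=True, exist_ok=True)
                target = target / f"checkpoint_gen{g + 1:07d}.npz"
            EvolutionRun(
                config=config,
                seed=seed,
                history=GenerationHistory(
                    per_pair[: g + 1].copy(),
                    best_idx[: g + 1].copy(),
                    best_onsets[: g + 1].copy(),
                    all_onsets[: g + 1].copy() if all_onsets is not None else None,
                ),
                population=population,
                next_generation_index=g + 1,
                stream_state=streams.state(),
            ).save(target)

    return EvolutionRun(
        config=config,
        seed=seed,
        history=GenerationHistory(per_pair, best_idx, best_onsets, all_onsets),
        population=population,
        next_generation_index=G,
        stream_state=streams.state(),
    )
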