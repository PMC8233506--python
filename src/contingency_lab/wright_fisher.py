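"""Individual-based Wright-Fisher simulation of a recurrent focal allele.

Models the fate of a beneficial loss-of-function allele (the lacI- class of
repressor mutations) arising repeatedly by mutation in an asexual
population, while competing background mutations -- drawn from a
distribution of fitness effects (DFE) with deleterious and beneficial
classes -- create clonal interference and hitchhiking.

Each generation, in order: (i) background mutations arise (Poisson with
genome-wide rate U per individual), each at a new site, with a selection
coefficient drawn from the DFE class proportions; (ii) focal mutations
arise in focal-wild-type individuals at rate mu_focal (one-way: no back
mutation); (iii) the next generation of exactly n_pop individuals is drawn
multinomially with weights proportional to fitness, which is multiplicative
across carried mutations (the focal allele contributes 1 + s_focal).  A
replicate ends when the focal-allele frequency exceeds the fixation
threshold, or at the generation horizon.

Internally the population is stored as counts per fitness class
(individuals sharing a fitness value and focal state), not per individual;
classes with identical (fitness, focal) are merged.  Since selection and
resampling depend on genotype only through fitness and focal state, this
representation is distributionally exact and makes populations of 1e5
individuals over thousands of generations tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFEClass",
    "SimConfig",
    "ReplicateOutcome",
    "FixationSummary",
    "DEFAULT_DFE",
    "WrightFisherSimulation",
    "next_generation_counts",
    "run_replicate",
    "substitution_frequency",
    "extrapolate_fluctuating",
    "combined_fs",
    "sweep_population_sizes",
]


@dataclass(frozen=True)
class DFEClass:
    """One class of background mutations: selection coefficient and weight."""

    effect: float      # selection coefficient; may be negative, must be > -1
    proportion: float  # fraction of background mutations in this class

    def __post_init__(self) -> None:
        if self.effect <= -1:
            raise ValueError(f"effect must exceed -1 (lethal boundary), got {self.effect}")
        if not 0 <= self.proportion <= 1:
            raise ValueError(f"proportion must lie in [0, 1], got {self.proportion}")


# Configurable placeholder DFE preserving the 3-deleterious + 3-beneficial
# class structure; class effects and proportions are free parameters of any
# study and should be set from measured values where available.
DEFAULT_DFE: tuple[DFEClass, ...] = (
    DFEClass(effect=-0.10, proportion=0.30),
    DFEClass(effect=-0.03, proportion=0.30),
    DFEClass(effect=-0.01, proportion=0.30),
    DFEClass(effect=+0.01, proportion=0.05),
    DFEClass(effect=+0.03, proportion=0.03),
    DFEClass(effect=+0.08, proportion=0.02),
)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one evolutionary simulation."""

    n_pop: int                      # population size N
    u_genome: float = 7e-4          # genome-wide background mutation rate U
    mu_focal: float = 1.72e-7       # focal (lacI+ -> lacI-) mutation rate
    s_focal: float = 0.0831         # focal selection coefficient
    dfe: tuple[DFEClass, ...] = DEFAULT_DFE
    horizon: int = 8000             # generations
    fix_threshold: float = 0.95     # focal frequency counted as fixed

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError(f"n_pop must be >= 2, got {self.n_pop}")
        if not 0 <= self.mu_focal < 1:
            raise ValueError(f"mu_focal must lie in [0, 1), got {self.mu_focal}")
        if self.u_genome < 0:
            raise ValueError(f"u_genome must be non-negative, got {self.u_genome}")
        if not 0 < self.fix_threshold <= 1:
            raise ValueError(f"fix_threshold must lie in (0, 1], got {self.fix_threshold}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.s_focal <= -1:
            raise ValueError(f"s_focal must exceed -1, got {self.s_focal}")
        dfe = tuple(self.dfe)
        object.__setattr__(self, "dfe", dfe)
        if dfe:
            total = sum(c.proportion for c in dfe)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"DFE proportions must sum to 1 (got {total})")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "dfe" in d:
            d["dfe"] = tuple(DFEClass(**c) if isinstance(c, dict) else c for c in d["dfe"])
        return cls(**d)


@dataclass(frozen=True)
class ReplicateOutcome:
    """Fate of the focal allele in one replicate population."""

    fixed: bool
    fix_generation: int | None
    final_focal_freq: float
    checkpoint_freqs: dict = field(default_factory=dict)  # generation -> focal freq


@dataclass(frozen=True)
class FixationSummary:
    """Substitution frequency f_s with bootstrap 95% CI."""

    f_s: float
    ci_low: float
    ci_high: float
    n_reps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.f_s <= self.ci_high <= 1.0:
            raise ValueError(f"inconsistent summary bounds: {self}")


def next_generation_counts(counts: np.ndarray, fitness: np.ndarray,
                           n_pop: int, rng: np.random.Generator,
                           n_draws: int = 1) -> np.ndarray:
    """Multinomial Wright-Fisher resampling with fitness-weighted probabilities."""
    w = counts * fitness
    p = w / w.sum()
    return rng.multinomial(n_pop, p, size=n_draws if n_draws > 1 else None)


class WrightFisherSimulation:
    """Mutable simulation state for one replicate; ``step()`` advances one generation."""

    def __init__(self, config: SimConfig, seed):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.generation = 0
        # class-level state: parallel arrays + index for merging equal classes
        self.counts = np.array([config.n_pop], dtype=np.int64)
        self.fitness = np.array([1.0])
        self.focal = np.array([False])
        self._index: dict[tuple[float, bool], int] = {(1.0, False): 0}
        self._effects = np.array([c.effect for c in config.dfe])
        self._props = np.array([c.proportion for c in config.dfe])

    # -- internal helpers -------------------------------------------------

    def _add(self, fit: float, foc: bool, n: int) -> None:
        key = (fit, foc)
        idx = self._index.get(key)
        if idx is None:
            self._index[key] = len(self.counts)
            self.counts = np.append(self.counts, n)
            self.fitness = np.append(self.fitness, fit)
            self.focal = np.append(self.focal, foc)
        else:
            self.counts[idx] += n

    def _allocate_events(self, n_events: int, mask=None) -> np.ndarray:
        """Distribute mutation events over classes proportional to their counts."""
        c = self.counts if mask is None else np.where(mask, self.counts, 0)
        tot = c.sum()
        return self.rng.multinomial(n_events, c / tot)

    def _prune(self) -> None:
        alive = self.counts > 0
        if not alive.all():
            self.counts = self.counts[alive]
            self.fitness = self.fitness[alive]
            self.focal = self.focal[alive]
            self._index = {(f, bool(o)): i
                           for i, (f, o) in enumerate(zip(self.fitness, self.focal))}

    # -- public API --------------------------------------------------------

    @property
    def focal_frequency(self) -> float:
        return float(self.counts[self.focal].sum()) / self.config.n_pop

    def step(self) -> None:
        cfg = self.config
        rng = self.rng
        # (i) background mutations: total events Poisson(N*U), hosts uniform
        if cfg.u_genome > 0 and len(self._effects):
            n_events = rng.poisson(cfg.n_pop * cfg.u_genome)
            if n_events:
                per_class = self._allocate_events(n_events)
                for src in np.nonzero(per_class)[0]:
                    n_src = min(int(per_class[src]), int(self.counts[src]))
                    if n_src == 0:
                        continue
                    kinds = rng.multinomial(n_src, self._props)
                    src_fit = self.fitness[src]
                    src_foc = bool(self.focal[src])
                    for kind in np.nonzero(kinds)[0]:
                        n_k = int(kinds[kind])
                        self.counts[src] -= n_k
                        self._add(src_fit * (1.0 + self._effects[kind]), src_foc, n_k)
        # (ii) focal mutations in focal-wild-type individuals
        if cfg.mu_focal > 0:
            wt = ~self.focal
            n_wt = int(self.counts[wt].sum())
            if n_wt:
                n_new = rng.binomial(n_wt, cfg.mu_focal)
                if n_new:
                    per_class = self._allocate_events(n_new, mask=wt)
                    for src in np.nonzero(per_class)[0]:
                        n_src = min(int(per_class[src]), int(self.counts[src]))
                        if n_src == 0:
                            continue
                        self.counts[src] -= n_src
                        self._add(self.fitness[src] * (1.0 + cfg.s_focal), True, n_src)
        # (iii) fitness-weighted multinomial resampling to exactly n_pop
        self.counts = next_generation_counts(self.counts, self.fitness, cfg.n_pop, rng)
        self._prune()
        self.generation += 1

    def run(self, checkpoints=()) -> ReplicateOutcome:
        cfg = self.config
        checkpoint_set = set(checkpoints)
        recorded: dict[int, float] = {}
        fixed = False
        fix_gen = None
        while self.generation < cfg.horizon:
            self.step()
            freq = self.focal_frequency
            if self.generation in checkpoint_set:
                recorded[self.generation] = freq
            if freq > cfg.fix_threshold:
                fixed = True
                fix_gen = self.generation
                # frequency can only be censused up to here; later checkpoints
                # inherit the fixed state
                for g in checkpoint_set:
                    if g >= self.generation:
                        recorded[g] = freq
                break
        return ReplicateOutcome(fixed=fixed, fix_generation=fix_gen,
                                final_focal_freq=self.focal_frequency,
                                checkpoint_freqs=recorded)


def run_replicate(config: SimConfig, seed, checkpoints=()) -> ReplicateOutcome:
    """Simulate one replicate population to fixation or the horizon."""
    return WrightFisherSimulation(config, seed).run(checkpoints=checkpoints)


def substitution_frequency(outcomes, n_boot: int = 1000, seed=0) -> FixationSummary:
    """f_s = fraction of replicates fixing the focal allele, with bootstrap CI."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one replicate outcome")
    fixed = np.array([o.fixed for o in outcomes], dtype=float)
    f_s = float(fixed.mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(fixed, size=(n_boot, fixed.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FixationSummary(f_s=f_s, ci_low=min(float(lo), f_s),
                           ci_high=max(float(hi), f_s), n_reps=fixed.size)


def extrapolate_fluctuating(f_2k: float) -> float:
    """Two-epoch extrapolation f_2k + f_2k (1 - f_2k).

    For regimes alternating between sugars every 2,000 generations, focal
    mutations not fixed within a lactose epoch are assumed lost in the
    following glucose epoch; a second lactose epoch then offers an
    independent chance of fixation among the 1 - f_2k populations.
    """
    if not 0.0 <= f_2k <= 1.0:
        raise ValueError(f"f_2k must lie in [0, 1], got {f_2k}")
    return f_2k + f_2k * (1.0 - f_2k)


def combined_fs(f_lac_8000: float, f_2k: float) -> float:
    """Combined substitution frequency across the three lactose regimes.

    Unweighted mean of the constant-lactose value at the full horizon and
    two copies of the fluctuating-regime extrapolation (each regime
    contributed equally many populations).
    """
    if not 0.0 <= f_lac_8000 <= 1.0:
        raise ValueError(f"f_lac_8000 must lie in [0, 1], got {f_lac_8000}")
    f_fluct = extrapolate_fluctuating(f_2k)
    return (f_lac_8000 + 2.0 * f_fluct) / 3.0


def sweep_population_sizes(config: SimConfig, sizes, reps: int, seed,
                           n_boot: int = 1000) -> list[FixationSummary]:
    """Run ``reps`` replicates at each population size; summaries in input order.

    Duplicate sizes get independent sub-seed streams.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    summaries = []
    for i, n in enumerate(sizes):
        cfg = SimConfig(n_pop=int(n), u_genome=config.u_genome,
                        mu_focal=config.mu_focal, s_focal=config.s_focal,
                        dfe=config.dfe, horizon=config.horizon,
                        fix_threshold=config.fix_threshold)
        size_seq = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        outcomes = [run_replicate(cfg, s) for s in size_seq.spawn(reps)]
        summaries.append(substitution_frequency(
            outcomes, n_boot=n_boot,
            seed=np.random.SeedSequence(entropy=root.entropy, spawn_key=(i, 1))))
    return summaries
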