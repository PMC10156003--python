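"""End-to-end parameter calibration.

The pipeline: sample parameters uniformly over their widest plausible
ranges, run Monte-Carlo simulations and process each into a simplified
image, train the encoder ensemble on those images, narrow the search
bounds to the min/max parameter values of the n training simulations
nearest the target in projected space, then minimize the ensemble
distance between the target image and candidate simulations with a
genetic algorithm (tournament selection, blend crossover, Gaussian
mutation, elitism).  Each GA candidate is evaluated with a single
simulation replicate; the population itself averages over simulator
stochasticity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abm
from .imaging import ProcessConfig, SimplifiedImage, process
from .representation import (
    EncoderConfig,
    EncoderEnsemble,
    ensemble_distances,
    ensemble_distance,
    train_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterRanges",
    "TrainingSet",
    "NarrowedBounds",
    "GAConfig",
    "FitResult",
    "sample_parameters",
    "params_from_vector",
    "simulation_seed",
    "build_training_set",
    "estimate_bounds",
    "DistanceObjective",
    "ga_optimize",
    "fit",
    "example1_self_fit",
]


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter sampling intervals (the widest plausible ranges)."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if len(self.names) != len(lo) or len(lo) != len(hi):
            raise ValueError("names/lower/upper lengths disagree")
        if not (lo < hi).all():
            raise ValueError("each lower bound must be strictly below its upper bound")

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "ParameterRanges":
        names = tuple(d.keys())
        lo = np.array([d[n][0] for n in names], dtype=float)
        hi = np.array([d[n][1] for n in names], dtype=float)
        return cls(names=names, lower=lo, upper=hi)

    def contains(self, vec: np.ndarray) -> bool:
        v = np.asarray(vec, dtype=float)
        return bool((v >= self.lower - 1e-12).all() and (v <= self.upper + 1e-12).all())


def sample_parameters(ranges: ParameterRanges, n: int, seed: int) -> np.ndarray:
    """n independent uniform draws per dimension, reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(ranges.names)))
    return ranges.lower + u * (ranges.upper - ranges.lower)


def params_from_vector(names, vec, base):
    """Return a copy of ``base`` parameters with ``names`` overridden by ``vec``."""
    updates = {name: float(v) for name, v in zip(names, vec)}
    return dataclasses.replace(base, **updates)


def simulation_seed(master_seed: int, row: int, replicate: int) -> int:
    """Deterministic per-(row, replicate) seed, independent of execution order."""
    ss = np.random.SeedSequence([int(master_seed), int(row), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class TrainingSet:
    """Monte-Carlo simulations processed into simplified images.

    ``images`` is (n_rows * replicates, H, W, C); ``row_index[i]`` maps
    image i back to its parameter row.  Rows whose simulation failed are
    flagged in ``failed`` and excluded from distance computations.
    """

    params: np.ndarray  # (n_rows, n_params)
    param_names: tuple[str, ...]
    images: np.ndarray  # (n_images, H, W, C)
    row_index: np.ndarray  # (n_images,)
    seeds: np.ndarray  # (n_images,)
    channel_names: tuple[str, ...]
    failed: np.ndarray  # (n_images,) bool

    @property
    def n_rows(self) -> int:
        return len(self.params)


def build_training_set(
    params_matrix: np.ndarray,
    param_names,
    base_params,
    sim_cfg: abm.SimConfig,
    process_cfg: ProcessConfig,
    replicates: int,
    seed: int,
) -> TrainingSet:
    """Simulate and process every parameter row x replicate.

    Results depend only on (row, replicate, seed), never on execution
    order, so the loop is embarrassingly parallel by contract.
    """
    params_matrix = np.asarray(params_matrix, dtype=float)
    n_rows = len(params_matrix)
    images, rows, seeds, failed = [], [], [], []
    shape = None
    for i in range(n_rows):
        p = params_from_vector(param_names, params_matrix[i], base_params)
        for r in range(replicates):
            s = simulation_seed(seed, i, r)
            rows.append(i)
            seeds.append(s)
            try:
                table = abm.simulate(p, sim_cfg, s)
                img = process(table, process_cfg)
                images.append(img.values)
                failed.append(False)
                shape = img.values.shape
            except Exception as exc:  # degenerate simulation: record, not fatal
                logger.warning("simulation row %d replicate %d failed: %s", i, r, exc)
                images.append(None)
                failed.append(True)
    if shape is None:
        raise RuntimeError("every training simulation failed")
    stack = np.stack([im if im is not None else np.zeros(shape) for im in images])
    return TrainingSet(
        params=params_matrix,
        param_names=tuple(param_names),
        images=stack,
        row_index=np.asarray(rows),
        seeds=np.asarray(seeds),
        channel_names=tuple(process_cfg.fit_channels or process_cfg.schema.names),
        failed=np.asarray(failed, dtype=bool),
    )


@dataclass(frozen=True)
class NarrowedBounds:
    """Search bounds from the n training simulations nearest the target."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    n_closest: int
    selected_rows: np.ndarray
    distances: np.ndarray  # distances of the selected images, ascending


def estimate_bounds(
    ens: EncoderEnsemble,
    target: SimplifiedImage,
    ts: TrainingSet,
    n_closest: int,
) -> NarrowedBounds:
    """Min/max parameter values over the ``n_closest`` nearest training images.

    Ties are broken by training-set index (stable sort).
    """
    valid = np.flatnonzero(~ts.failed)
    if not (1 <= n_closest <= len(valid)):
        raise ValueError(f"n_closest must be in [1, {len(valid)}], got {n_closest}")
    d = ensemble_distances(ens, target, ts.images[valid])
    order = np.argsort(d, kind="stable")[:n_closest]
    chosen_imgs = valid[order]
    chosen_rows = ts.row_index[chosen_imgs]
    sel = ts.params[chosen_rows]
    return NarrowedBounds(
        names=ts.param_names,
        lower=sel.min(axis=0),
        upper=sel.max(axis=0),
        n_closest=n_closest,
        selected_rows=chosen_rows,
        distances=d[order],
    )


@dataclass
class DistanceObjective:
    """Simulate a candidate, process it, and measure distance to the target.

    One simulation replicate per evaluation.  By default every call uses
    a fresh seed drawn from the caller-supplied value; pass
    ``fixed_seed`` to pin the simulator stream (useful to verify that a
    target is at distance zero from its own generating run).  Degenerate
    simulations (e.g. no tumor channel left to crop to) return
    ``penalty`` instead of raising.
    """

    target: SimplifiedImage
    ensemble: EncoderEnsemble
    base_params: object
    names: tuple[str, ...]
    sim_cfg: abm.SimConfig
    process_cfg: ProcessConfig
    penalty: float = 1e3
    fixed_seed: int | None = None
    n_evaluations: int = 0

    def __call__(self, vec: np.ndarray, seed: int | None = None) -> float:
        self.n_evaluations += 1
        s = self.fixed_seed if self.fixed_seed is not None else seed
        if s is None:
            raise ValueError("objective needs a seed (or construct with fixed_seed)")
        p = params_from_vector(self.names, vec, self.base_params)
        try:
            table = abm.simulate(p, self.sim_cfg, int(s))
            img = process(table, self.process_cfg)
        except Exception as exc:
            logger.info("degenerate simulation at %s: %s -> penalty", vec, exc)
            return float(self.penalty)
        return ensemble_distance(self.ensemble, self.target, img)


@dataclass
class GAConfig:
    """Genetic-algorithm settings (population 300 for ex1, 400 for ex2)."""

    population: int = 300
    generations: int = 10
    tournament: int = 3
    crossover_prob: float = 0.9
    blend_alpha: float = 0.5
    mutation_sigma: float = 0.1  # fraction of each parameter's range
    mutation_prob: float = 0.2  # per-gene
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


@dataclass
class FitResult:
    """GA trace plus the narrowed bounds and best parameter set."""

    param_names: tuple[str, ...]
    best_params: dict[str, float]
    best_value: float
    trace_best: np.ndarray  # per generation, monotone non-increasing
    trace_mean: np.ndarray
    population: np.ndarray
    fitness: np.ndarray
    top10: pd.DataFrame  # rows: best/max/min/mean/cv over the 10 best evaluations
    narrowed_bounds: NarrowedBounds | None
    seeds: dict = field(default_factory=dict)

    @property
    def plateau_generation(self) -> int:
        """First generation whose best objective is within 5% of the final best."""
        final = self.trace_best[-1]
        cut = final * 1.05 if final > 0 else final + 1e-12
        return int(np.argmax(self.trace_best <= cut))


def _top10_summary(names, archive_params: np.ndarray, archive_fitness: np.ndarray) -> pd.DataFrame:
    order = np.argsort(archive_fitness, kind="stable")[:10]
    top = archive_params[order]
    mean = top.mean(axis=0)
    std = top.std(axis=0, ddof=1) if len(top) > 1 else np.zeros(top.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, std / np.abs(mean), np.inf)
    return pd.DataFrame(
        [top[0], top.max(axis=0), top.min(axis=0), mean, cv],
        index=["best", "max", "min", "mean", "cv"],
        columns=list(names),
    )


def ga_optimize(objective, bounds, cfg: GAConfig) -> FitResult:
    """Minimize ``objective(vec, seed=...)`` over box bounds with a GA.

    ``bounds`` is a NarrowedBounds or ParameterRanges-like object with
    ``names``, ``lower``, ``upper``.  Selection is tournament (size k),
    crossover is BLX-alpha blending, mutation adds Gaussian noise with
    standard deviation ``mutation_sigma`` x range per gene and results
    are clipped to the bounds.  Elitism guarantees the best-so-far trace
    is non-increasing.
    """
    lo = np.asarray(bounds.lower, dtype=float)
    hi = np.asarray(bounds.upper, dtype=float)
    names = tuple(bounds.names)
    p = len(lo)
    rng = np.random.default_rng(cfg.seed)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        vals = np.empty(len(pop))
        n_fail = 0
        for i, x in enumerate(pop):
            try:
                vals[i] = objective(x, seed=int(rng.integers(0, 2**31 - 1)))
            except Exception as exc:
                n_fail += 1
                vals[i] = np.inf
                logger.warning("objective failed at %s: %s", x, exc)
        if n_fail == len(pop):
            raise RuntimeError("objective failed on every individual of a generation")
        return vals

    pop = lo + rng.random((cfg.population, p)) * (hi - lo)
    fitness = evaluate(pop)
    archive_p, archive_f = [pop.copy()], [fitness.copy()]
    trace_best = [float(fitness.min())]
    trace_mean = [float(np.mean(fitness[np.isfinite(fitness)]))]

    for _ in range(cfg.generations):
        order = np.argsort(fitness, kind="stable")
        elites = pop[order[: cfg.elitism]].copy()
        elite_fit = fitness[order[: cfg.elitism]].copy()
        children = []
        while len(children) < cfg.population - cfg.elitism:
            idx1 = rng.integers(0, cfg.population, cfg.tournament)
            idx2 = rng.integers(0, cfg.population, cfg.tournament)
            p1 = pop[idx1[np.argmin(fitness[idx1])]]
            p2 = pop[idx2[np.argmin(fitness[idx2])]]
            if rng.random() < cfg.crossover_prob:
                gamma = rng.uniform(-cfg.blend_alpha, 1.0 + cfg.blend_alpha, p)
                child = p1 + gamma * (p2 - p1)
            else:
                child = p1.copy()
            mut = rng.random(p) < cfg.mutation_prob
            noise = rng.normal(0.0, cfg.mutation_sigma * (hi - lo))
            child = np.where(mut, child + noise, child)
            children.append(np.clip(child, lo, hi))
        children = np.asarray(children)
        child_fit = evaluate(children)
        pop = np.vstack([elites, children])
        fitness = np.concatenate([elite_fit, child_fit])
        archive_p.append(children.copy())
        archive_f.append(child_fit.copy())
        trace_best.append(float(fitness.min()))
        trace_mean.append(float(np.mean(fitness[np.isfinite(fitness)])))

    archive_params = np.vstack(archive_p)
    archive_fitness = np.concatenate(archive_f)
    best_idx = int(np.argmin(archive_fitness))
    return FitResult(
        param_names=names,
        best_params={n: float(v) for n, v in zip(names, archive_params[best_idx])},
        best_value=float(archive_fitness[best_idx]),
        trace_best=np.asarray(trace_best),
        trace_mean=np.asarray(trace_mean),
        population=pop,
        fitness=fitness,
        top10=_top10_summary(names, archive_params, archive_fitness),
        narrowed_bounds=None,
        seeds={"ga": int(cfg.seed)},
    )


def fit(
    target,
    ens: EncoderEnsemble,
    ts: TrainingSet,
    base_params,
    sim_cfg: abm.SimConfig,
    process_cfg: ProcessConfig,
    ga_cfg: GAConfig,
    n_closest: int = 100,
    penalty: float = 1e3,
    bounds_override: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Full fitting stage: process target, narrow bounds, run the GA.

    ``target`` may be a cell table (DataFrame) or an already processed
    SimplifiedImage.  ``bounds_override`` replaces individual narrowed
    bounds (audit-logged) for the rare case where manual adjustment is
    required.
    """
    if isinstance(target, pd.DataFrame):
        target = process(target, process_cfg)
    bounds = estimate_bounds(ens, target, ts, n_closest)
    if bounds_override:
        lo, hi = bounds.lower.copy(), bounds.upper.copy()
        for name, (a, b) in bounds_override.items():
            i = bounds.names.index(name)
            logger.warning(
                "manual bound override for %s: [%g, %g] -> [%g, %g]", name, lo[i], hi[i], a, b
            )
            lo[i], hi[i] = a, b
        bounds = dataclasses.replace(bounds, lower=lo, upper=hi)
    objective = DistanceObjective(
        target=target,
        ensemble=ens,
        base_params=base_params,
        names=bounds.names,
        sim_cfg=sim_cfg,
        process_cfg=process_cfg,
        penalty=penalty,
    )
    result = ga_optimize(objective, bounds, ga_cfg)
    result.narrowed_bounds = bounds
    result.seeds["objective_evaluations"] = objective.n_evaluations
    return result


def example1_self_fit(
    master_seed: int,
    fit_names: tuple[str, ...] = ("kill_prob",),
    n_train: int = 100,
    replicates: int = 1,
    n_members: int = 3,
    n_closest: int = 20,
    ga_population: int = 20,
    ga_generations: int = 8,
    sim_cfg: abm.SimConfig | None = None,
    encoder_cfg: EncoderConfig | None = None,
    target_size: tuple[int, int] = (32, 32),
):
    """Desk-scale self-fit of the PD-L1 model against its own base simulation.

    Generates a base simulation at the nominal parameters, builds a
    training set varying only ``fit_names`` over their widest ranges,
    trains a small encoder ensemble, narrows bounds, and runs the GA.
    Returns ``(FitResult, nominal_params)``.  All randomness derives
    from ``master_seed``.
    """
    from .imaging import EX1_SCHEMA

    sim_cfg = sim_cfg or abm.SimConfig()
    # contrastive loss on ~100 images plateaus by ~100 epochs; train past it
    encoder_cfg = encoder_cfg or EncoderConfig(batch_size=32, epochs=120)
    process_cfg = ProcessConfig(schema=EX1_SCHEMA, cell_diameter=sim_cfg.cell_diameter,
                                tumor_channels=("tumor",), target=target_size)
    nominal = abm.nominal_parameters_ex1()
    all_ranges = abm.default_ranges_ex1()
    ranges = ParameterRanges.from_dict({n: all_ranges[n] for n in fit_names})

    ss = np.random.SeedSequence(master_seed)
    seed_target, seed_sample, seed_train, seed_ens, seed_ga = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)
    ]

    base_table = abm.simulate(nominal, sim_cfg, seed_target)
    target = process(base_table, process_cfg)

    matrix = sample_parameters(ranges, n_train, seed_sample)
    ts = build_training_set(matrix, ranges.names, nominal, sim_cfg, process_cfg,
                            replicates, seed_train)
    ens = train_ensemble(ts.images[~ts.failed], encoder_cfg, n_members, seed_ens)

    ga_cfg = GAConfig(population=ga_population, generations=ga_generations, seed=seed_ga)
    result = fit(target, ens, ts, nominal, sim_cfg, process_cfg, ga_cfg, n_closest=n_closest)
    result.seeds.update(
        {"master": master_seed, "target": seed_target, "sample": seed_sample,
         "training": seed_train, "ensemble": seed_ens}
    )
    return result, nominal
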