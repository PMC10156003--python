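"""Off-lattice, center-based tumor--T-cell agent-based model.

Each cell is a point with a radius in a continuous 2-D domain (units:
micrometers).  Two model variants are provided:

* ``ex1`` -- immune suppression via PD-L1: tumor cells proliferate, gain
  PD-L1 expression in the presence of T cells, and suppress adjacent
  T cells with probability equal to their PD-L1 level.  T cells are
  recruited at the tumor rim, migrate inward up to an infiltration
  limit, and kill adjacent live tumor cells.  Killed tumor cells are
  removed.
* ``ex2`` -- hypoxic core: no PD-L1 dynamics; live tumor cells die
  spontaneously with a basal probability, elevated inside a static
  hypoxic disc centered on the initial tumor centroid.  Dead tumor
  cells persist in place (they are never removed and never move).

Mechanics are resolved by iterative pairwise overlap relaxation: any
two overlapping cells are pushed apart along their center line until
the maximum residual overlap falls below a tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "KINDS",
    "Cell",
    "ABMParametersEx1",
    "ABMParametersEx2",
    "SimConfig",
    "SimulationState",
    "init_state",
    "neighbors_within",
    "tumor_radius",
    "step",
    "simulate",
    "state_to_table",
    "nominal_parameters_ex1",
    "default_ranges_ex1",
]

KINDS = ("tumor_live", "tumor_dead", "tcell_active", "tcell_suppressed")
TUMOR_LIVE, TUMOR_DEAD, TCELL_ACTIVE, TCELL_SUPPRESSED = range(4)
_KIND_CODE = {name: code for code, name in enumerate(KINDS)}


@dataclass(frozen=True)
class Cell:
    """Read-only view of a single agent."""

    id: int
    kind: str
    position: np.ndarray  # (2,) micrometers
    radius: float
    pdl1: float


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass
class ABMParametersEx1:
    """Fitted parameters of the PD-L1 suppression variant.

    kill_prob
        Probability per adjacent pair per timestep that an active T cell
        kills a live tumor cell.
    infiltration
        Dimensionless fraction of the current tumor radius that T cells
        may penetrate; they halt once within ``(1 - infiltration) * R``
        of the tumor centroid.
    pdl1_max
        Cap on per-cell PD-L1, itself a per-step suppression probability.
    pdl1_rate
        PD-L1 increment per timestep while at least one T cell is within
        interaction range.
    """

    kill_prob: float
    infiltration: float
    pdl1_max: float
    pdl1_rate: float

    variant = "ex1"

    def __post_init__(self) -> None:
        _check_prob("kill_prob", self.kill_prob)
        if not (0.0 < self.infiltration <= 1.0):
            raise ValueError(f"infiltration must be in (0, 1], got {self.infiltration}")
        _check_prob("pdl1_max", self.pdl1_max)
        if not (0.0 <= self.pdl1_rate <= self.pdl1_max):
            raise ValueError(
                f"pdl1_rate must lie in [0, pdl1_max={self.pdl1_max}], got {self.pdl1_rate}"
            )


@dataclass
class ABMParametersEx2:
    """Fitted parameters of the hypoxic-core variant."""

    kill_prob: float
    infiltration: float
    basal_death_prob: float
    hypoxic_radius: float
    hypoxic_death_prob: float

    variant = "ex2"

    def __post_init__(self) -> None:
        _check_prob("kill_prob", self.kill_prob)
        if not (0.0 < self.infiltration <= 1.0):
            raise ValueError(f"infiltration must be in (0, 1], got {self.infiltration}")
        _check_prob("basal_death_prob", self.basal_death_prob)
        _check_prob("hypoxic_death_prob", self.hypoxic_death_prob)
        if self.hypoxic_radius < 0:
            raise ValueError("hypoxic_radius must be >= 0")
        if self.hypoxic_death_prob < self.basal_death_prob:
            raise ValueError("hypoxic_death_prob must be >= basal_death_prob")


@dataclass
class SimConfig:
    """Fixed (non-fitted) constants of a simulation.

    Defaults are desk-scale: an initial tumor disc of radius 80 um
    (cell diameter 20 um) evolved for 80 steps yields a mixed
    tumor / T-cell / suppressed-T snapshot in a fraction of a second.
    """

    domain_size: float = 1000.0  # um; cosmetic, recruitment is rim-relative
    cell_diameter: float = 20.0  # um
    n_steps: int = 80
    proliferation_prob: float = 0.025  # per live tumor cell per step
    recruitment_rate: float = 2.0  # expected new T cells per step
    migration_step: float = 10.0  # um per step
    interaction_radius_factor: float = 1.1  # x (sum of radii) = "nearby"
    initial_tumor_radius: float = 80.0  # um
    variant: str = "ex1"
    overlap_tol: float = 0.05  # stop relaxing below this fraction of radius
    max_relax_iter: int = 50

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be > 0")
        if self.variant not in ("ex1", "ex2"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class SimulationState:
    """Struct-of-arrays container for all agents at one timestep."""

    ids: np.ndarray  # (n,) int64, unique
    kind: np.ndarray  # (n,) int8, codes into KINDS
    pos: np.ndarray  # (n, 2) float64, um
    radius: np.ndarray  # (n,) float64, um
    pdl1: np.ndarray  # (n,) float64
    t: int = 0
    next_id: int = 0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))  # initial tumor centroid

    @property
    def n(self) -> int:
        return len(self.ids)

    def cell(self, index: int) -> Cell:
        return Cell(
            id=int(self.ids[index]),
            kind=KINDS[self.kind[index]],
            position=self.pos[index].copy(),
            radius=float(self.radius[index]),
            pdl1=float(self.pdl1[index]),
        )

    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n)]

    def copy(self) -> "SimulationState":
        return SimulationState(
            ids=self.ids.copy(),
            kind=self.kind.copy(),
            pos=self.pos.copy(),
            radius=self.radius.copy(),
            pdl1=self.pdl1.copy(),
            t=self.t,
            next_id=self.next_id,
            origin=self.origin.copy(),
        )


def init_state(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulationState:
    """Hexagonally packed tumor disc of radius ``cfg.initial_tumor_radius``."""
    d = cfg.cell_diameter
    R = cfg.initial_tumor_radius
    center = np.array([cfg.domain_size / 2.0, cfg.domain_size / 2.0])
    dy = d * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = -R
    while y <= R + 1e-9:
        offset = (d / 2.0) if (j % 2) else 0.0
        x = -R + offset
        while x <= R + 1e-9:
            if x * x + y * y <= R * R:
                pts.append((x, y))
            x += d
        y += dy
        j += 1
    if not pts:
        pts = [(0.0, 0.0)]
    pos = np.asarray(pts, dtype=float) + center
    n = len(pos)
    return SimulationState(
        ids=np.arange(n, dtype=np.int64),
        kind=np.full(n, TUMOR_LIVE, dtype=np.int8),
        pos=pos,
        radius=np.full(n, d / 2.0),
        pdl1=np.zeros(n),
        t=0,
        next_id=n,
        origin=pos.mean(axis=0),
    )


def neighbors_within(state: SimulationState, focal: Cell | int, radius: float) -> list[Cell]:
    """All cells (excluding *focal*) within ``radius`` of focal's center, by id."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    focal_id = focal.id if isinstance(focal, Cell) else int(focal)
    where = np.flatnonzero(state.ids == focal_id)
    if len(where) == 0:
        raise KeyError(f"cell id {focal_id} is not part of this state")
    i = int(where[0])
    tree = cKDTree(state.pos)
    idx = tree.query_ball_point(state.pos[i], radius)
    idx = [j for j in idx if j != i]
    idx.sort(key=lambda j: int(state.ids[j]))
    return [state.cell(j) for j in idx]


def _tumor_mask(state: SimulationState) -> np.ndarray:
    return (state.kind == TUMOR_LIVE) | (state.kind == TUMOR_DEAD)


def tumor_radius(state: SimulationState) -> float:
    """Max distance from the tumor centroid to any tumor cell (live + dead)."""
    mask = _tumor_mask(state)
    if not mask.any():
        raise ValueError("state contains no tumor cells")
    pts = state.pos[mask]
    centroid = pts.mean(axis=0)
    return float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).max())


def _tumor_centroid(state: SimulationState) -> np.ndarray:
    mask = _tumor_mask(state)
    return state.pos[mask].mean(axis=0)


def _interaction_pairs(state: SimulationState, factor: float) -> np.ndarray:
    """Index pairs (i < j) with center distance <= factor * (r_i + r_j)."""
    if state.n < 2:
        return np.empty((0, 2), dtype=int)
    cutoff = factor * 2.0 * float(state.radius.max())
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.sqrt(((state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]]) ** 2).sum(axis=1))
    keep = d <= factor * (state.radius[pairs[:, 0]] + state.radius[pairs[:, 1]])
    pairs = pairs[keep]
    # canonical order so Bernoulli draws are reproducible
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def _relax_overlaps(state: SimulationState, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Push overlapping cells apart along their center line, in place.

    Immovable kinds (dead tumor cells, suppressed T cells) never move;
    their overlap is resolved entirely by the movable partner.
    """
    movable = (state.kind == TUMOR_LIVE) | (state.kind == TCELL_ACTIVE)
    if state.n < 2:
        return
    rmin = float(state.radius.min())
    rmax = float(state.radius.max())
    tol = cfg.overlap_tol * rmin
    omega = 1.5  # over-relaxation: plain half-pushes converge slowly in dense packings
    slack = 1.5  # candidate cutoff margin so the pair list survives a few sweeps
    n = state.n
    pairs = None
    fresh = False

    def rebuild():
        tree = cKDTree(state.pos)
        cand = tree.query_pairs(slack * 2.0 * rmax, output_type="ndarray")
        if len(cand):
            mi, mj = movable[cand[:, 0]], movable[cand[:, 1]]
            cand = cand[mi | mj]  # both-immovable pairs can never be resolved
            mi, mj = movable[cand[:, 0]], movable[cand[:, 1]]
            both = mi & mj
            wi = np.where(both, -0.5 * omega, np.where(mi, -omega, 0.0))
            wj = np.where(both, 0.5 * omega, np.where(mj, omega, 0.0))
        else:
            cand = cand.reshape(0, 2)
            wi = wj = np.empty(0)
        rsum = state.radius[cand[:, 0]] + state.radius[cand[:, 1]] if len(cand) else np.empty(0)
        return cand, wi, wj, rsum

    for sweep in range(cfg.max_relax_iter):
        if pairs is None or sweep % 6 == 0:
            pairs, wi, wj, rsum = rebuild()
            fresh = True
        if len(pairs) == 0:
            if fresh:
                return
            pairs = None
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        delta = state.pos[j] - state.pos[i]
        dist = np.sqrt((delta**2).sum(axis=1))
        overlap = rsum - dist
        active = overlap > tol
        if not active.any():
            if fresh:
                return
            pairs = None  # stale list says converged: verify against a fresh tree
            continue
        fresh = False
        ia, ja = i[active], j[active]
        da, dista, ova = delta[active], dist[active], overlap[active]
        # coincident centers: separate along a random direction
        degen = dista < 1e-9
        if degen.any():
            theta = rng.uniform(0.0, 2.0 * np.pi, int(degen.sum()))
            da[degen] = np.column_stack([np.cos(theta), np.sin(theta)])
            dista[degen] = 1.0
        push = (ova / dista)[:, None] * da  # overlap-long vector along the center line
        sx = np.bincount(ia, wi[active] * push[:, 0], minlength=n)
        sy = np.bincount(ia, wi[active] * push[:, 1], minlength=n)
        sx += np.bincount(ja, wj[active] * push[:, 0], minlength=n)
        sy += np.bincount(ja, wj[active] * push[:, 1], minlength=n)
        state.pos[:, 0] += sx
        state.pos[:, 1] += sy
    # loop exhausted: accept residual overlap (the contract caps the sweep count)


def _append_cells(
    state: SimulationState, pos: np.ndarray, kind: int, pdl1: float = 0.0
) -> None:
    k = len(pos)
    if k == 0:
        return
    new_radius = float(state.radius[0]) if state.n else 10.0
    new_ids = np.arange(state.next_id, state.next_id + k, dtype=np.int64)
    state.ids = np.concatenate([state.ids, new_ids])
    state.kind = np.concatenate([state.kind, np.full(k, kind, dtype=np.int8)])
    state.pos = np.vstack([state.pos, pos])
    state.radius = np.concatenate([state.radius, np.full(k, new_radius)])
    state.pdl1 = np.concatenate([state.pdl1, np.full(k, pdl1)])
    state.next_id += k


def step(
    state: SimulationState,
    params: ABMParametersEx1 | ABMParametersEx2,
    cfg: SimConfig,
    rng: np.random.Generator,
    events: list | None = None,
) -> SimulationState:
    """Advance one timestep.  Phases, in fixed order:

    1. tumor proliferation (daughter adjacent, then relaxation)
    2. PD-L1 update (ex1 only)
    3. T-cell recruitment at the rim and inward migration
    4. killing by active T cells
    5. suppression of active T cells by tumor PD-L1 (ex1 only)
    6. death: ex1 removes killed cells; ex2 converts killed/spontaneously
       dead cells to persistent ``tumor_dead``
    7. overlap relaxation

    Within each phase all Bernoulli pair-draws are taken synchronously
    against the phase-start state, so no agent ordering can bias events.
    Returns a new state; ``events`` (if given) collects tuples
    ``(t, "kill"|"suppress"|"death", actor_id, subject_id)``.
    """
    if params.variant != cfg.variant:
        raise ValueError(
            f"parameter variant {params.variant!r} does not match config variant {cfg.variant!r}"
        )
    s = state.copy()
    factor = cfg.interaction_radius_factor

    # -- 1. proliferation ---------------------------------------------------
    live = np.flatnonzero(s.kind == TUMOR_LIVE)
    if len(live):
        births = live[rng.random(len(live)) < cfg.proliferation_prob]
        if len(births):
            theta = rng.uniform(0.0, 2.0 * np.pi, len(births))
            # daughter placed adjacent (touching) at a random angle; crowding
            # with other neighbors is resolved by the relaxation pass
            offsets = np.column_stack([np.cos(theta), np.sin(theta)]) * (2.0 * s.radius[births, None])
            _append_cells(s, s.pos[births] + offsets, TUMOR_LIVE)
            _relax_overlaps(s, cfg, rng)

    # -- 2. PD-L1 update (ex1) ----------------------------------------------
    if cfg.variant == "ex1":
        pairs = _interaction_pairs(s, factor)
        if len(pairs):
            ki, kj = s.kind[pairs[:, 0]], s.kind[pairs[:, 1]]
            tcell = lambda k: (k == TCELL_ACTIVE) | (k == TCELL_SUPPRESSED)  # noqa: E731
            contact = np.zeros(s.n, dtype=bool)
            m = (ki == TUMOR_LIVE) & tcell(kj)
            contact[pairs[m, 0]] = True
            m = (kj == TUMOR_LIVE) & tcell(ki)
            contact[pairs[m, 1]] = True
            gain = contact & (s.kind == TUMOR_LIVE)
            s.pdl1[gain] = np.minimum(s.pdl1[gain] + params.pdl1_rate, params.pdl1_max)

    # -- 3. recruitment + migration ------------------------------------------
    has_tumor = _tumor_mask(s).any()
    if has_tumor and cfg.recruitment_rate > 0:
        base = int(np.floor(cfg.recruitment_rate))
        n_new = base + int(rng.random() < (cfg.recruitment_rate - base))
        if n_new:
            centroid = _tumor_centroid(s)
            R = tumor_radius(s)
            theta = rng.uniform(0.0, 2.0 * np.pi, n_new)
            ring = R + cfg.cell_diameter
            pos = centroid + ring * np.column_stack([np.cos(theta), np.sin(theta)])
            _append_cells(s, pos, TCELL_ACTIVE)
    if has_tumor:
        centroid = _tumor_centroid(s)
        R = tumor_radius(s)
        limit = (1.0 - params.infiltration) * R
        active = np.flatnonzero(s.kind == TCELL_ACTIVE)
        if len(active):
            rel = s.pos[active] - centroid
            r = np.sqrt((rel**2).sum(axis=1))
            move = r > limit + 1e-12
            r_new = np.maximum(r[move] - cfg.migration_step, limit)
            scale = np.where(r[move] > 1e-12, r_new / r[move], 1.0)
            s.pos[active[move]] = centroid + rel[move] * scale[:, None]

    # -- 4. killing -----------------------------------------------------------
    pairs = _interaction_pairs(s, factor)
    killed = np.zeros(s.n, dtype=bool)
    if len(pairs):
        ki, kj = s.kind[pairs[:, 0]], s.kind[pairs[:, 1]]
        a = (ki == TCELL_ACTIVE) & (kj == TUMOR_LIVE)
        b = (kj == TCELL_ACTIVE) & (ki == TUMOR_LIVE)
        tc = np.concatenate([pairs[a, 0], pairs[b, 1]])
        tu = np.concatenate([pairs[a, 1], pairs[b, 0]])
        if len(tc):
            hit = rng.random(len(tc)) < params.kill_prob
            killed[tu[hit]] = True
            if events is not None:
                for c, u in zip(tc[hit], tu[hit]):
                    events.append((s.t, "kill", int(s.ids[c]), int(s.ids[u])))

    # -- 5. suppression (ex1) -------------------------------------------------
    if cfg.variant == "ex1" and len(pairs):
        ki, kj = s.kind[pairs[:, 0]], s.kind[pairs[:, 1]]
        a = (ki == TUMOR_LIVE) & (kj == TCELL_ACTIVE) & ~killed[pairs[:, 0]]
        b = (kj == TUMOR_LIVE) & (ki == TCELL_ACTIVE) & ~killed[pairs[:, 1]]
        tu = np.concatenate([pairs[a, 0], pairs[b, 1]])
        tc = np.concatenate([pairs[a, 1], pairs[b, 0]])
        if len(tu):
            hit = rng.random(len(tu)) < s.pdl1[tu]
            for u, c in zip(tu[hit], tc[hit]):
                if s.kind[c] == TCELL_ACTIVE:
                    s.kind[c] = TCELL_SUPPRESSED
                    if events is not None:
                        events.append((s.t, "suppress", int(s.ids[u]), int(s.ids[c])))

    # -- 6. death -------------------------------------------------------------
    if cfg.variant == "ex1":
        if killed.any():
            keep = ~killed
            s.ids, s.kind, s.pos = s.ids[keep], s.kind[keep], s.pos[keep]
            s.radius, s.pdl1 = s.radius[keep], s.pdl1[keep]
    else:
        live = s.kind == TUMOR_LIVE
        alive = live & ~killed
        if alive.any():
            dist = np.sqrt(((s.pos - s.origin) ** 2).sum(axis=1))
            p = np.where(
                dist <= params.hypoxic_radius,
                params.hypoxic_death_prob,
                params.basal_death_prob,
            )
            died = alive & (rng.random(s.n) < p)
        else:
            died = np.zeros(s.n, dtype=bool)
        gone = (killed & live) | died
        if gone.any():
            if events is not None:
                for i in np.flatnonzero(died):
                    events.append((s.t, "death", int(s.ids[i]), int(s.ids[i])))
            s.kind[gone] = TUMOR_DEAD

    # -- 7. relaxation ---------------------------------------------------------
    _relax_overlaps(s, cfg, rng)
    if not np.isfinite(s.pos).all():
        raise RuntimeError("non-finite cell position after mechanics relaxation")

    s.t += 1
    return s


def state_to_table(state: SimulationState) -> pd.DataFrame:
    """Export a state as a cell table (the common currency of the pipeline)."""
    return pd.DataFrame(
        {
            "id": state.ids,
            "kind": [KINDS[k] for k in state.kind],
            "x_um": state.pos[:, 0],
            "y_um": state.pos[:, 1],
            "radius_um": state.radius,
            "pdl1": state.pdl1,
        }
    )


def simulate(
    params: ABMParametersEx1 | ABMParametersEx2,
    cfg: SimConfig,
    seed: int,
    return_state: bool = False,
    events: list | None = None,
):
    """Run ``init_state`` + ``cfg.n_steps`` steps; return the final cell table.

    The same ``(params, cfg, seed)`` always yields a bitwise-identical
    table.  Tumor extinction is not an error: the table is returned with
    ``attrs["extinct"] = True``.
    """
    rng = np.random.default_rng(seed)
    state = init_state(cfg, rng)
    for _ in range(cfg.n_steps):
        state = step(state, params, cfg, rng, events=events)
    table = state_to_table(state)
    table.attrs["extinct"] = bool(not (_tumor_mask(state)).any())
    table.attrs["seed"] = int(seed)
    table.attrs["variant"] = cfg.variant
    table.attrs["params"] = dataclasses.asdict(params)
    table.attrs["config"] = dataclasses.asdict(cfg)
    if return_state:
        return table, state
    return table


def nominal_parameters_ex1() -> ABMParametersEx1:
    """The nominal parameter set used for the self-fit base simulation."""
    return ABMParametersEx1(kill_prob=0.02, infiltration=0.8, pdl1_max=0.01, pdl1_rate=5e-5)


def default_ranges_ex1() -> dict[str, tuple[float, float]]:
    """Widest plausible sampling ranges for the four fitted ex1 parameters."""
    return {
        "kill_prob": (0.001, 0.1),
        "infiltration": (0.05, 1.0),
        "pdl1_max": (0.001, 0.05),
        "pdl1_rate": (1e-5, 2e-4),
    }
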