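"""Synthetic test inputs.

Three generators, each reproducible bit-for-bit from a manifest:

* ``make_base_simulation`` -- the PD-L1 model run at its nominal
  parameters; the self-fit target.
* ``make_ring_tumor`` -- a parametric image-scale cell table emulating a
  thin circular tumor section with a dead hypoxic core (live rim, dead
  center), standing in for a segmented live/dead fluorescence image.
  Its default diameter (5,500 um) deliberately exceeds the simulated
  tumor scale so the cross-scale comparison path is exercised.
* ``make_family_pair`` -- two families of processed images with
  within-family stochastic variation, for encoder separation tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import abm
from .imaging import EX1_SCHEMA, EX2_SCHEMA, ProcessConfig, SimplifiedImage, process

__all__ = [
    "RingTumorSpec",
    "FixtureManifest",
    "make_base_simulation",
    "make_ring_tumor",
    "make_family_pair",
]


@dataclass(frozen=True)
class RingTumorSpec:
    """Parametric live/dead disc.  Defaults mimic a ~5,500-um-diameter
    tumor section whose center is dead (hypoxic core) and rim alive."""

    outer_radius: float = 2750.0  # um
    dead_core_radius: float = 1175.0  # um; scaled analogue of a ~640-um core on a 1,500-um tumor
    cell_spacing: float = 25.0  # um between lattice sites
    live_density: float = 0.9  # occupancy probability outside the core
    dead_density: float = 0.9  # occupancy probability inside the core
    jitter: float = 4.0  # Gaussian positional noise, um
    mixing: float = 0.0  # fraction of labels flipped near the core boundary
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dead_core_radius < self.outer_radius):
            raise ValueError("dead_core_radius must be in [0, outer_radius)")
        for name in ("live_density", "dead_density"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be > 0")


@dataclass
class FixtureManifest:
    generator: str
    spec: dict
    seed: int
    checksum: str  # sha256 of the CSV serialization

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _checksum(table: pd.DataFrame) -> str:
    return hashlib.sha256(table.to_csv(index=False).encode()).hexdigest()


def make_base_simulation(
    nominal: abm.ABMParametersEx1 | None = None,
    sim_cfg: abm.SimConfig | None = None,
    seed: int = 0,
    process_cfg: ProcessConfig | None = None,
):
    """Run the PD-L1 model at the nominal parameters.

    Returns ``(cell_table, simplified_image, manifest)``.
    """
    nominal = nominal or abm.nominal_parameters_ex1()
    sim_cfg = sim_cfg or abm.SimConfig()
    process_cfg = process_cfg or ProcessConfig(
        schema=EX1_SCHEMA, cell_diameter=sim_cfg.cell_diameter, tumor_channels=("tumor",)
    )
    table = abm.simulate(nominal, sim_cfg, seed)
    img = process(table, process_cfg)
    manifest = FixtureManifest(
        generator="base_ex1",
        spec={"params": dataclasses.asdict(nominal), "config": dataclasses.asdict(sim_cfg)},
        seed=seed,
        checksum=_checksum(table),
    )
    return table, img, manifest


def make_ring_tumor(spec: RingTumorSpec):
    """Lattice-with-jitter placement of live/dead cells in a disc.

    Cells sit on a square lattice at ``cell_spacing``, are retained with
    the class-specific density, jittered by Gaussian noise, and labeled
    ``tumor_dead`` inside the core and ``tumor_live`` outside.  With
    ``mixing`` > 0 that fraction of cells within half a core radius of
    the boundary have their label flipped (live/dead overlap seen in
    real stains).  Returns ``(cell_table, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    R, s = spec.outer_radius, spec.cell_spacing
    coords = np.arange(-R, R + s / 2, s)
    xx, yy = np.meshgrid(coords, coords)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    r = np.sqrt((pts**2).sum(axis=1))
    inside = r <= R
    if not inside.any():
        raise ValueError("cell_spacing too large: no lattice site falls inside the disc")
    pts, r = pts[inside], r[inside]
    dead = r <= spec.dead_core_radius
    density = np.where(dead, spec.dead_density, spec.live_density)
    keep = rng.random(len(pts)) < density
    pts, dead, r = pts[keep], dead[keep], r[keep]
    pts = pts + rng.normal(0.0, spec.jitter, pts.shape)
    if spec.mixing > 0 and spec.dead_core_radius > 0:
        band = np.abs(r - spec.dead_core_radius) < 0.5 * spec.dead_core_radius
        flip = band & (rng.random(len(pts)) < spec.mixing)
        dead = dead ^ flip
    table = pd.DataFrame(
        {
            "id": np.arange(len(pts)),
            "kind": np.where(dead, "tumor_dead", "tumor_live"),
            "x_um": pts[:, 0] + R,
            "y_um": pts[:, 1] + R,
            "radius_um": np.full(len(pts), s / 2.0),
            "pdl1": np.zeros(len(pts)),
        }
    )
    manifest = FixtureManifest(
        generator="ring_tumor",
        spec=dataclasses.asdict(spec),
        seed=spec.seed,
        checksum=_checksum(table),
    )
    return table, manifest


DEAD_CELL_PROCESS = ProcessConfig(
    schema=EX2_SCHEMA,
    cell_diameter=20.0,
    tumor_channels=("tumor", "dead"),
    target=(32, 32),
    fit_channels=("dead",),
)


def make_family_pair(
    spec_a: RingTumorSpec,
    spec_b: RingTumorSpec,
    n: int,
    seed: int,
    process_cfg: ProcessConfig | None = None,
):
    """n processed images per family, with per-image stochastic variation.

    Family specs should differ in at least one structural parameter;
    identical specs produce statistically indistinguishable families.
    """
    if n < 2:
        raise ValueError("need n >= 2 images per family")
    process_cfg = process_cfg or DEAD_CELL_PROCESS
    rng = np.random.default_rng(seed)
    out: list[list[SimplifiedImage]] = []
    for spec in (spec_a, spec_b):
        family = []
        for _ in range(n):
            member = dataclasses.replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
            table, _ = make_ring_tumor(member)
            family.append(process(table, process_cfg))
        out.append(family)
    return out[0], out[1]
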