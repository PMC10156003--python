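"""Convert cell tables into "simplified images".

A cell table (from a segmented fluorescence image or from an ABM
snapshot) is reduced to a small fixed-size multi-channel array in
[0, 1] through four stages:

1. ``rasterize`` -- bin continuous coordinates onto a grid whose pitch
   is one cell diameter, one channel per cell class (presence, 0/1) or
   per continuous property (accumulated, then max-normalized);
2. ``crop_to_tumor`` -- crop all channels to the bounding box of the
   tumor channels, which removes translation and absolute position;
3. ``downsample`` -- area-weighted resampling to a uniform target size
   (default 32 x 32), turning discrete cell locations into densities;
4. per-channel rescale so every nonzero channel attains a maximum of 1.

Because cropping is relative and resizing is anisotropic to a square
target, the comparison is between relative spatial patterns, not
absolute sizes -- which is what allows an image and a smaller simulated
tumor to be compared across spatial scales.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "ChannelSchema",
    "GridStack",
    "SimplifiedImage",
    "ProcessConfig",
    "EX1_SCHEMA",
    "EX2_SCHEMA",
    "read_cell_table",
    "write_cell_table",
    "rasterize",
    "crop_to_tumor",
    "resize_area",
    "downsample",
    "process",
]


class CellTableSchemaError(ValueError):
    """A required column is missing or a cell class is not in the schema."""


class CellTableParseError(ValueError):
    """A coordinate or property value could not be parsed."""


@dataclass(frozen=True)
class Channel:
    """One output channel.

    mode "presence": 1 where at least one cell of ``kind`` falls in a bin.
    mode "continuous": per-bin sum of ``prop`` over cells of ``kind``
    (all kinds if ``kind`` is None), then scaled to max 1.
    """

    name: str
    mode: str  # "presence" | "continuous"
    kind: str | None = None
    prop: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("presence", "continuous"):
            raise ValueError(f"unknown channel mode {self.mode!r}")
        if self.mode == "presence" and self.kind is None:
            raise ValueError(f"presence channel {self.name!r} needs a kind")
        if self.mode == "continuous" and self.prop is None:
            raise ValueError(f"continuous channel {self.name!r} needs a property")


@dataclass(frozen=True)
class ChannelSchema:
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("schema needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names in {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def kinds(self) -> set[str]:
        return {c.kind for c in self.channels if c.kind is not None}


EX1_SCHEMA = ChannelSchema(
    (
        Channel("tumor", "presence", kind="tumor_live"),
        Channel("tcell", "presence", kind="tcell_active"),
        Channel("tcell_suppressed", "presence", kind="tcell_suppressed"),
        Channel("pdl1", "continuous", kind="tumor_live", prop="pdl1"),
    )
)

EX2_SCHEMA = ChannelSchema(
    (
        Channel("tumor", "presence", kind="tumor_live"),
        Channel("dead", "presence", kind="tumor_dead"),
    )
)


@dataclass
class GridStack:
    """Full-resolution grids: one bin = one cell diameter."""

    values: np.ndarray  # (rows, cols, channels)
    channel_names: tuple[str, ...]
    cell_diameter: float
    origin: np.ndarray  # (x, y) um of the (row 0, col 0) bin corner

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, :, self.channel_names.index(name)]


@dataclass
class SimplifiedImage:
    """Fixed-size multi-channel array in [0, 1]; the unit of comparison."""

    values: np.ndarray  # (H, W, channels)
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[2] != len(self.channel_names):
            raise ValueError("values must be (H, W, n_channels)")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("simplified-image values must lie in [0, 1]")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, :, self.channel_names.index(name)]

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("values", data=self.values)
            d.attrs["channel_names"] = json.dumps(list(self.channel_names))

    @classmethod
    def load_h5(cls, path) -> "SimplifiedImage":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][...]
            names = tuple(json.loads(f["values"].attrs["channel_names"]))
        return cls(values=values, channel_names=names)


def read_cell_table(
    path,
    column_map: dict[str, str],
    schema: ChannelSchema,
    pixel_size: float = 1.0,
    default_kind: str | None = None,
) -> pd.DataFrame:
    """Read a delimited cell table (e.g. ImageJ *Analyze Particles* output).

    Parameters
    ----------
    column_map
        Maps logical names to file columns.  Required: ``"x"``, ``"y"``.
        Optional: ``"kind"`` (cell-class column); any other key is taken
        as a property name mapped to its column (e.g. ``{"pdl1": "Mean"}``).
    pixel_size
        Multiplicative factor converting file coordinates to micrometers
        (1.0 if the file is already in um).
    default_kind
        Class assigned to every row when no kind column is mapped
        (single-stain files).
    """
    df = pd.read_csv(path)
    for key in ("x", "y"):
        if key not in column_map:
            raise CellTableSchemaError(f"column_map must name a {key!r} column")
        if column_map[key] not in df.columns:
            raise CellTableSchemaError(
                f"mapped {key!r} column {column_map[key]!r} not found in {list(df.columns)}"
            )

    def _numeric(col: str, logical: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = int(bad[0]) if len(bad) else int(vals.index[vals.isna()][0])
            raise CellTableParseError(f"non-numeric {logical} value in row {row} (column {col!r})")
        return vals.to_numpy(float)

    out = pd.DataFrame(
        {
            "x_um": _numeric(column_map["x"], "x-coordinate") * pixel_size,
            "y_um": _numeric(column_map["y"], "y-coordinate") * pixel_size,
        }
    )
    if not np.isfinite(out[["x_um", "y_um"]].to_numpy()).all():
        raise CellTableParseError("non-finite coordinate in cell table")

    if "kind" in column_map:
        if column_map["kind"] not in df.columns:
            raise CellTableSchemaError(f"kind column {column_map['kind']!r} not found")
        kinds = df[column_map["kind"]].astype(str)
    else:
        if default_kind is None:
            raise CellTableSchemaError("no kind column mapped and no default_kind given")
        kinds = pd.Series([default_kind] * len(df))
    unknown = set(kinds.unique()) - schema.kinds
    if unknown:
        raise CellTableSchemaError(
            f"cell class(es) {sorted(unknown)} not present in channel schema {sorted(schema.kinds)}"
        )
    out["kind"] = kinds.to_numpy()

    for logical, col in column_map.items():
        if logical in ("x", "y", "kind"):
            continue
        if col not in df.columns:
            raise CellTableSchemaError(f"property column {col!r} (for {logical!r}) not found")
        vals = _numeric(col, f"property {logical!r}")
        if (vals < 0).any():
            raise CellTableParseError(f"property {logical!r} has negative values")
        out[logical] = vals
    return out


def write_cell_table(table: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a cell table as CSV, optionally with a JSON metadata sidecar."""
    table.to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as f:
            json.dump(sidecar, f, indent=2, default=str)


def rasterize(cells: pd.DataFrame, schema: ChannelSchema, cell_diameter: float) -> GridStack:
    """Bin cells onto a grid with pitch ``cell_diameter``.

    Bin ``i`` along each axis covers ``[i*d, (i+1)*d)`` measured from the
    minimum cell coordinate.  Rows index y (downward), columns index x.
    """
    if len(cells) == 0:
        raise ValueError("cannot rasterize an empty cell table")
    if cell_diameter <= 0:
        raise ValueError("cell_diameter must be > 0")
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite coordinates in cell table")
    ox, oy = float(x.min()), float(y.min())
    col = np.floor((x - ox) / cell_diameter).astype(int)
    row = np.floor((y - oy) / cell_diameter).astype(int)
    H, W = int(row.max()) + 1, int(col.max()) + 1
    kinds = cells["kind"].to_numpy()
    values = np.zeros((H, W, len(schema.channels)))
    for ci, ch in enumerate(schema.channels):
        mask = np.ones(len(cells), dtype=bool) if ch.kind is None else (kinds == ch.kind)
        if ch.mode == "presence":
            values[row[mask], col[mask], ci] = 1.0
        else:
            if ch.prop not in cells.columns:
                raise CellTableSchemaError(
                    f"continuous channel {ch.name!r} needs property column {ch.prop!r}"
                )
            np.add.at(values[:, :, ci], (row[mask], col[mask]), cells[ch.prop].to_numpy(float)[mask])
            peak = values[:, :, ci].max()
            if peak > 0:
                values[:, :, ci] /= peak
    return GridStack(
        values=values,
        channel_names=schema.names,
        cell_diameter=cell_diameter,
        origin=np.array([ox, oy]),
    )


def crop_to_tumor(grids: GridStack, tumor_channels: tuple[str, ...]) -> GridStack:
    """Crop all channels to the bounding box where any tumor channel is nonzero."""
    idx = [grids.channel_names.index(name) for name in tumor_channels]
    mask = (grids.values[:, :, idx] > 0).any(axis=2)
    if not mask.any():
        raise ValueError(f"tumor channels {tumor_channels} are all empty; cannot crop")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    d = grids.cell_diameter
    return GridStack(
        values=grids.values[r0:r1, c0:c1, :],
        channel_names=grids.channel_names,
        cell_diameter=d,
        origin=grids.origin + np.array([c0 * d, r0 * d]),
    )


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix W where out = W @ in is exact area averaging.

    Output bin o covers ``[o, o+1) * n_in/n_out`` on the input axis; its
    value is the overlap-weighted mean of the input bins it covers.
    """
    scale = n_in / n_out
    W = np.zeros((n_out, n_in))
    for o in range(n_out):
        lo, hi = o * scale, (o + 1) * scale
        i0 = int(np.floor(lo))
        i1 = min(int(np.ceil(hi)), n_in)
        for i in range(i0, i1):
            W[o, i] = max(0.0, min(hi, i + 1) - max(lo, i))
    return W / scale


def resize_area(channel: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Exact area-interpolated resize of a single 2-D channel."""
    H, W = target
    if H < 1 or W < 1:
        raise ValueError("target dimensions must be >= 1")
    R = _area_weights(channel.shape[0], H)
    C = _area_weights(channel.shape[1], W)
    return R @ channel @ C.T


def downsample(grids: GridStack, target: tuple[int, int]) -> SimplifiedImage:
    """Area-resample each channel to ``target`` and rescale to max 1.

    Upsampling (target larger than the grid) is permitted but logged,
    since it does not aggregate cells into densities.
    """
    H, W = target
    if H < 1 or W < 1:
        raise ValueError("target dimensions must be >= 1")
    rows, cols = grids.values.shape[:2]
    if H > rows or W > cols:
        logger.info("downsample target %s exceeds grid size (%d, %d): upsampling", target, rows, cols)
    out = np.empty((H, W, grids.values.shape[2]))
    for ci in range(grids.values.shape[2]):
        ch = resize_area(grids.values[:, :, ci], target)
        peak = ch.max()
        if peak > 0:
            ch = ch / peak
        out[:, :, ci] = np.clip(ch, 0.0, 1.0)
    return SimplifiedImage(values=out, channel_names=grids.channel_names)


@dataclass
class ProcessConfig:
    """End-to-end processing recipe for one model/image family."""

    schema: ChannelSchema
    cell_diameter: float = 20.0
    tumor_channels: tuple[str, ...] = ("tumor",)
    target: tuple[int, int] = (32, 32)
    fit_channels: tuple[str, ...] | None = None  # None = keep all


def process(cells: pd.DataFrame, cfg: ProcessConfig) -> SimplifiedImage:
    """rasterize -> crop_to_tumor -> downsample -> restrict to fit channels."""
    grids = rasterize(cells, cfg.schema, cfg.cell_diameter)
    grids = crop_to_tumor(grids, cfg.tumor_channels)
    img = downsample(grids, cfg.target)
    if cfg.fit_channels is not None:
        idx = [img.channel_names.index(n) for n in cfg.fit_channels]
        img = SimplifiedImage(
            values=img.values[:, :, idx], channel_names=tuple(cfg.fit_channels)
        )
    return img
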