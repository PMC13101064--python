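"""Mosaic preprocessing: flat-field correction, max projection, stitching,
pseudo-RGB composition, masked brightness, and grouped tile-dataset export.

Tiles arrive as 16-bit grayscale z-stacks on a regular grid with a known
overlap fraction; assembly reproduces the acquisition pipeline: per-tile
flat-field correction, per-slice stitching at known grid positions, then a
max projection over z.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "BrightnessRecord",
    "flat_field_correct",
    "max_project",
    "stitch_mosaic",
    "compose_rgb",
    "assemble_channel",
    "assemble_sample",
    "channel_brightness",
    "export_tile_dataset",
    "dihedral_variants",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a tiled acquisition.

    The stitched mosaic side along columns is
    ``cols * tile_size - (cols - 1) * overlap_px`` where
    ``overlap_px = round(overlap * tile_size)`` (26 px for 10% of 256,
    giving the 3016-px side of a 13x13 grid).
    """

    rows: int = 13
    cols: int = 13
    tile_size: int = 256
    overlap: float = 0.10

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.tile_size < 1:
            raise ValueError("tile_size must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.overlap_px >= self.tile_size:
            raise ValueError("overlap_px must be smaller than tile_size")

    @property
    def overlap_px(self) -> int:
        return int(round(self.overlap * self.tile_size))

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap_px

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the stitched mosaic in pixels."""
        h = self.rows * self.tile_size - (self.rows - 1) * self.overlap_px
        w = self.cols * self.tile_size - (self.cols - 1) * self.overlap_px
        return h, w

    def tile_origin(self, r: int, c: int) -> tuple[int, int]:
        """Top-left pixel of tile (r, c) in mosaic coordinates."""
        return r * self.stride, c * self.stride


@dataclass(frozen=True)
class BrightnessRecord:
    """Per-sample masked mean brightness per channel, FAD-normalized.

    ``raw`` holds the mean over strictly positive pixels (detector counts);
    ``normalized`` divides by the sample's FAD mean, so FAD is exactly 1.
    Channels whose image is all-zero appear in ``undefined`` and carry NaN.
    """

    sample_id: str
    label: str
    preparation: str
    raw: dict[str, float] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    undefined: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Tile-level operations
# ---------------------------------------------------------------------------

def flat_field_correct(tile: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Divide out the illumination profile: ``tile / (flat / mean(flat))``.

    Output dtype matches the input; integer outputs are rounded and clipped
    to the dtype range.
    """
    tile = np.asarray(tile)
    flat = np.asarray(flat, dtype=float)
    if tile.shape != flat.shape:
        raise ValueError(f"shape mismatch: tile {tile.shape} vs flat {flat.shape}")
    if np.any(flat <= 0):
        raise ValueError("flat field must be strictly positive")
    corrected = tile.astype(float) * (flat.mean() / flat)
    if np.issubdtype(tile.dtype, np.integer):
        info = np.iinfo(tile.dtype)
        corrected = np.clip(np.rint(corrected), info.min, info.max)
    return corrected.astype(tile.dtype)


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis of a stack of slices."""
    stack = np.asarray(zstack)
    if stack.ndim < 3 or stack.shape[0] < 1:
        if stack.ndim == 2:
            raise ValueError("expected a stack with a leading z axis")
        raise ValueError("empty z-stack")
    return stack.max(axis=0)


def _feather_weights(spec: GridSpec, r: int, c: int) -> np.ndarray:
    """Separable linear feather ramp for tile (r, c).

    Within an overlap strip the two contributing tiles get weights
    (k+1)/(ov+1) and (ov-k)/(ov+1), which sum to 1 exactly, so consistent
    tiles blend back to their common value.
    """
    ts, ov = spec.tile_size, spec.overlap_px
    wy = np.ones(ts)
    wx = np.ones(ts)
    if ov > 0:
        ramp = np.arange(1, ov + 1) / (ov + 1)
        if r > 0:
            wy[:ov] = ramp
        if r < spec.rows - 1:
            wy[-ov:] = ramp[::-1]
        if c > 0:
            wx[:ov] = ramp
        if c < spec.cols - 1:
            wx[-ov:] = ramp[::-1]
    return np.outer(wy, wx)


def stitch_mosaic(tiles: np.ndarray, spec: GridSpec, mode: str = "feather") -> np.ndarray:
    """Stitch a (rows, cols, H, W) tile array at known grid positions.

    mode="feather" blends overlap strips with complementary linear ramps;
    mode="first" lets the lexicographically first tile win in overlaps,
    which is bit-exact for tiles cropped from a common image.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4 or tiles.shape[:2] != (spec.rows, spec.cols):
        raise ValueError(f"expected tiles of shape ({spec.rows}, {spec.cols}, H, W)")
    if tiles.shape[2:] != (spec.tile_size, spec.tile_size):
        raise ValueError("tile size does not match grid spec")
    if mode not in ("feather", "first"):
        raise ValueError(f"unknown stitch mode {mode!r}")

    out_shape = spec.shape
    ts = spec.tile_size
    if mode == "first":
        mosaic = np.zeros(out_shape, dtype=tiles.dtype)
        written = np.zeros(out_shape, dtype=bool)
        for r in range(spec.rows):
            for c in range(spec.cols):
                y, x = spec.tile_origin(r, c)
                region = (slice(y, y + ts), slice(x, x + ts))
                fresh = ~written[region]
                mosaic[region][fresh] = tiles[r, c][fresh]
                written[region] = True
        return mosaic

    acc = np.zeros(out_shape, dtype=float)
    wsum = np.zeros(out_shape, dtype=float)
    for r in range(spec.rows):
        for c in range(spec.cols):
            y, x = spec.tile_origin(r, c)
            w = _feather_weights(spec, r, c)
            acc[y:y + ts, x:x + ts] += w * tiles[r, c]
            wsum[y:y + ts, x:x + ts] += w
    mosaic = acc / wsum
    if np.issubdtype(tiles.dtype, np.integer):
        info = np.iinfo(tiles.dtype)
        mosaic = np.clip(np.rint(mosaic), info.min, info.max).astype(tiles.dtype)
    return mosaic


def _rescale_plane(channel: np.ndarray) -> np.ndarray:
    """Min-max rescale one channel over its nonzero pixels to uint8."""
    ch = np.asarray(channel, dtype=float)
    nz = ch[ch > 0]
    if nz.size == 0:
        return np.zeros(ch.shape, dtype=np.uint8)
    lo, hi = float(nz.min()), float(nz.max())
    if hi == lo:
        return np.where(ch > 0, 255, 0).astype(np.uint8)
    scaled = np.clip((ch - lo) / (hi - lo), 0.0, 1.0)
    return np.rint(scaled * 255).astype(np.uint8)


def compose_rgb(red: np.ndarray, green: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Stack three grayscale channels into an 8-bit pseudo-RGB image.

    Each channel is independently min-max rescaled over its nonzero pixels;
    an all-zero channel yields an all-zero plane.
    """
    red, green, blue = (np.asarray(c) for c in (red, green, blue))
    if not (red.shape == green.shape == blue.shape):
        raise ValueError("channel shape mismatch")
    return np.dstack([_rescale_plane(red), _rescale_plane(green), _rescale_plane(blue)])


# ---------------------------------------------------------------------------
# Sample assembly and brightness
# ---------------------------------------------------------------------------

def assemble_channel(tile_grid, flat: np.ndarray | None = None, mode: str = "feather") -> np.ndarray:
    """Assemble one channel image: correct tiles, stitch each z-slice, max-project.

    ``tile_grid`` is a synthetic.TileGrid (tiles array of shape
    (rows, cols, z, H, W) plus a GridSpec).
    """
    tiles = tile_grid.tiles
    spec = tile_grid.spec
    n_z = tiles.shape[2]
    mosaics = []
    for z in range(n_z):
        slab = tiles[:, :, z]
        if flat is not None:
            slab = np.stack([
                np.stack([flat_field_correct(slab[r, c], flat) for c in range(spec.cols)])
                for r in range(spec.rows)
            ])
        mosaics.append(stitch_mosaic(slab, spec, mode=mode))
    return max_project(np.stack(mosaics))


def assemble_sample(record, flat: np.ndarray | None = None, mode: str = "feather") -> dict[str, np.ndarray]:
    """Assemble all channels of a SampleRecord, caching into record.images."""
    for ch, grid in record.tiles.items():
        if ch not in record.images:
            record.images[ch] = assemble_channel(grid, flat=flat, mode=mode)
    return record.images


def channel_brightness(sample, flat: np.ndarray | None = None) -> BrightnessRecord:
    """Masked mean brightness per channel, normalized by the FAD mean.

    Background (zero) pixels are discarded before averaging. A channel that
    is entirely zero is flagged undefined (NaN), never silently 0; an
    all-zero FAD channel is an error because normalization is undefined.
    """
    images = sample.images if sample.images else assemble_sample(sample, flat=flat)
    if "FAD" not in images:
        raise ValueError(f"sample {sample.sample_id!r} has no FAD channel")
    raw: dict[str, float] = {}
    undefined: list[str] = []
    for ch, img in images.items():
        pos = img[img > 0]
        if pos.size == 0:
            undefined.append(ch)
            raw[ch] = float("nan")
        else:
            raw[ch] = float(pos.mean())
    fad = raw["FAD"]
    if not math.isfinite(fad) or fad <= 0:
        raise ValueError(f"sample {sample.sample_id!r}: FAD channel is all zero, "
                         "normalization undefined")
    normalized = {ch: v / fad for ch, v in raw.items()}
    return BrightnessRecord(
        sample_id=sample.sample_id,
        label=sample.label,
        preparation=sample.preparation,
        raw=raw,
        normalized=normalized,
        undefined=tuple(undefined),
    )


def brightness_to_frame(records: list[BrightnessRecord]) -> pd.DataFrame:
    """Tabulate normalized brightness records (one row per sample)."""
    channels = sorted({ch for r in records for ch in r.normalized})
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "label": r.label, "preparation": r.preparation}
        for ch in channels:
            row[ch] = r.normalized.get(ch, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tile dataset export (grouped split, crop, augmentation)
# ---------------------------------------------------------------------------

def dihedral_variants(image: np.ndarray) -> list[np.ndarray]:
    """The 8 rotation/reflection variants of an image (dihedral group D4)."""
    variants = []
    flipped = image[:, ::-1]
    for k in range(4):
        variants.append(np.rot90(image, k))
    for k in range(4):
        variants.append(np.rot90(flipped, k))
    return variants


def _crop_overlap(tile: np.ndarray, spec: GridSpec, r: int, c: int) -> np.ndarray:
    """Remove duplicated overlap strips: crop the top/left interior edges."""
    ov = spec.overlap_px
    y0 = ov if r > 0 else 0
    x0 = ov if c > 0 else 0
    return tile[y0:, x0:]


def export_tile_dataset(
    cohort: list,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    augment: bool = False,
    seed: int = 0,
    out_dir: str | None = None,
    rgb_channels: tuple[str, str, str] | None = None,
) -> pd.DataFrame:
    """Partition samples into train/val/test and enumerate their tiles.

    The split is grouped: every tile inherits its sample's partition, so no
    sample leaks across partitions. Counts are floor(split[0]*N) train,
    floor(split[1]*N) validation, remainder test. Tiles are max-projected
    over z and cropped by the overlap on interior edges; with ``augment``,
    each training tile contributes its 8 dihedral variants. If ``out_dir``
    and ``rgb_channels`` are given, pseudo-RGB tile PNGs are written.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if all(s > 0 for s in split) and len(cohort) < 3:
        raise ValueError("need at least 3 samples for a three-way split")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n = len(cohort)
    n_train = int(math.floor(split[0] * n))
    n_val = int(math.floor(split[1] * n))
    partition_of: dict[str, str] = {}
    for pos, idx in enumerate(order):
        part = "train" if pos < n_train else ("val" if pos < n_train + n_val else "test")
        partition_of[cohort[idx].sample_id] = part

    writer = None
    if out_dir is not None and rgb_channels is not None:
        import imageio.v3 as iio

        def writer(path, img):  # noqa: F811
            full = os.path.join(out_dir, path)
            os.makedirs(os.path.dirname(full), exist_ok=True)
            iio.imwrite(full, img)

    rows = []
    for record in cohort:
        part = partition_of[record.sample_id]
        spec = next(iter(record.tiles.values())).spec
        for r in range(spec.rows):
            for c in range(spec.cols):
                planes = {}
                if rgb_channels is not None:
                    for ch in rgb_channels:
                        if ch not in record.tiles:
                            raise ValueError(f"channel {ch!r} missing from sample "
                                             f"{record.sample_id!r}")
                        tile = max_project(record.tiles[ch].tiles[r, c])
                        planes[ch] = _crop_overlap(tile, spec, r, c)
                variants = [0] if not (augment and part == "train") else range(8)
                for k in variants:
                    suffix = f"_d{k}" if augment and part == "train" else ""
                    path = os.path.join(
                        part, f"{record.sample_id}_r{r:02d}_c{c:02d}{suffix}.png")
                    if writer is not None:
                        rgb = compose_rgb(*(planes[ch] for ch in rgb_channels))
                        if k:
                            rgb = np.dstack([dihedral_variants(rgb[..., i])[k]
                                             for i in range(3)])
                        writer(path, np.ascontiguousarray(rgb))
                    rows.append({
                        "sample_id": record.sample_id,
                        "label": record.label,
                        "preparation": record.preparation,
                        "partition": part,
                        "tile_path": path,
                    })
    return pd.DataFrame(rows)
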