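"""Synthetic multiphoton-microscopy phantoms of tumor vs normal pancreas.

Generates multi-channel tile z-stacks with the acquisition geometry of the
study cohort (13x13 grids of 256-px 16-bit tiles, 10% overlap, five z-slices)
and the contrasts the downstream analysis assumes:

* SHG collagen fibers are denser and brighter in tumor tissue;
* fixed-frozen samples are globally brighter than FFPE, most of all in SHG;
* autofluorescence channels (NADH, FAD, lipofuscin, porphyrin) are cellular
  blob textures, with a blob-size shift in tumors;
* tiles carry vignetting, per-slice defocus blur/attenuation, shot noise and
  Gaussian read noise;
* the NADH channel is absent from fixed-frozen samples (mounting-medium
  fluorescence at that excitation wavelength makes it unusable).

Each phantom retains its noiseless full-field truth image per channel so
that preprocessing can be tested against a known ground truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as _draw_line

from .preprocess import GridSpec

__all__ = [
    "CHANNELS",
    "FROZEN_CHANNELS",
    "CohortDesign",
    "PhantomParams",
    "TileGrid",
    "SampleRecord",
    "make_vignette",
    "render_tile_stacks",
    "generate_tissue_phantom",
    "generate_cohort",
    "write_sample_tiffs",
    "write_cohort",
    "save_config",
]

CHANNELS = ("NADH", "FAD", "Lipofuscin", "Porphyrin", "SHG")
FROZEN_CHANNELS = tuple(c for c in CHANNELS if c != "NADH")

CLASSES = ("tumor", "normal")
PREPARATIONS = ("FFPE", "frozen")


def _default_counts() -> dict[tuple[str, str], int]:
    return {
        ("tumor", "FFPE"): 27,
        ("normal", "FFPE"): 21,
        ("tumor", "frozen"): 7,
        ("normal", "frozen"): 7,
    }


def _default_channels() -> dict[str, tuple[str, ...]]:
    return {"FFPE": CHANNELS, "frozen": FROZEN_CHANNELS}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition and acquisition geometry.

    Defaults reproduce the study design: 27/21 FFPE tumor/normal plus 7/7
    fixed-frozen, a 13x13 grid of 256-px tiles with 10% overlap and five
    z-slices at 2 µm steps. Fixed-frozen preparations exclude NADH.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=_default_counts)
    channels: dict[str, tuple[str, ...]] = field(default_factory=_default_channels)
    grid: GridSpec = field(default_factory=GridSpec)
    n_z: int = 5
    z_step_um: float = 2.0

    def __post_init__(self) -> None:
        for (label, prep), count in self.counts.items():
            if label not in CLASSES or prep not in PREPARATIONS:
                raise ValueError(f"unknown cohort cell ({label!r}, {prep!r})")
            if count < 0:
                raise ValueError("cohort counts must be non-negative")
        if not (0.0 <= self.grid.overlap < 0.5):
            raise ValueError("overlap fraction must be in [0, 0.5)")
        if self.n_z < 1:
            raise ValueError("need at least one z-slice")
        for prep, chans in self.channels.items():
            for ch in chans:
                if ch not in CHANNELS:
                    raise ValueError(f"unknown channel {ch!r}")
        if "NADH" in self.channels.get("frozen", ()):
            raise ValueError("fixed-frozen preparations must exclude NADH")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def restricted(self, preparation: str) -> "CohortDesign":
        """The same design keeping only one preparation's cells."""
        counts = {k: v for k, v in self.counts.items() if k[1] == preparation}
        return replace(self, counts=counts)


def _default_background() -> dict[str, float]:
    return {"NADH": 120.0, "FAD": 150.0, "Lipofuscin": 100.0,
            "Porphyrin": 90.0, "SHG": 60.0}


def _default_frozen_brightness() -> dict[str, float]:
    # Fixed-frozen samples read brighter than FFPE, most of all in SHG.
    return {"NADH": 1.5, "FAD": 1.5, "Lipofuscin": 1.5,
            "Porphyrin": 1.5, "SHG": 1.8}


@dataclass(frozen=True)
class PhantomParams:
    """Tunable texture and noise parameters of the tissue phantom.

    Densities are per megapixel of field area; intensities are 16-bit
    detector counts; sigmas and lengths are pixels.
    """

    background: dict[str, float] = field(default_factory=_default_background)
    blob_density: float = 800.0
    blob_intensity: float = 9000.0
    blob_sigma: float = 3.0
    fiber_density: float = 120.0
    fiber_length: float = 80.0
    fiber_width: float = 2.0
    fiber_intensity: float = 9000.0
    tumor_shg_density_mult: float = 2.0
    tumor_shg_brightness_mult: float = 1.5
    tumor_blob_sigma_mult: float = 1.25
    frozen_brightness: dict[str, float] = field(default_factory=_default_frozen_brightness)
    vignette_strength: float = 0.25
    read_noise_sd: float = 30.0
    shot_noise: bool = True
    gain_jitter_sd: float = 0.0
    defocus_blur: float = 1.2
    defocus_attenuation: float = 0.15

    def __post_init__(self) -> None:
        for name in ("blob_density", "blob_intensity", "blob_sigma",
                     "fiber_density", "fiber_length", "fiber_width",
                     "fiber_intensity", "read_noise_sd", "gain_jitter_sd",
                     "defocus_blur", "defocus_attenuation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background levels must be non-negative")
        for ch in self.background:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError("vignette_strength must be in [0, 1)")


@dataclass
class TileGrid:
    """Tile z-stacks on a grid: uint16 array (rows, cols, z, tile, tile)."""

    tiles: np.ndarray
    spec: GridSpec

    @property
    def n_z(self) -> int:
        return self.tiles.shape[2]


@dataclass
class SampleRecord:
    """One specimen: metadata plus per-channel tiles/images.

    ``truth`` retains the noiseless full-field image per channel (uint16)
    for oracle tests; ``images`` caches assembled channel images.
    """

    sample_id: str
    label: str
    preparation: str
    site: str = "synthetic"
    tiles: dict[str, TileGrid] = field(default_factory=dict)
    images: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"unknown preparation {self.preparation!r}")
        if self.preparation == "frozen" and "NADH" in self.tiles:
            raise ValueError("fixed-frozen samples carry no NADH channel")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.tiles) if self.tiles else tuple(self.images)


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

def make_vignette(tile_size: int, strength: float, normalize: bool = True) -> np.ndarray:
    """Radial vignetting field for one tile, 1 - strength*(r/r_corner)^2.

    With ``normalize`` the field is rescaled to mean 1 (a gain convention),
    so flat-field correction with this same field recovers the unvignetted
    tile exactly up to rounding.
    """
    ax = np.arange(tile_size) - (tile_size - 1) / 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r2 = yy ** 2 + xx ** 2
    field_ = 1.0 - strength * r2 / r2.max()
    if normalize:
        field_ = field_ / field_.mean()
    return field_


def _render_blobs(shape: tuple[int, int], rng: np.random.Generator,
                  density: float, intensity: float, sigma: float) -> np.ndarray:
    """Cellular autofluorescence: Gaussian blobs at uniform positions."""
    h, w = shape
    n = int(round(density * h * w / 1e6))
    img = np.zeros(shape, dtype=float)
    if n == 0 or intensity == 0:
        return img
    ys = rng.integers(0, h, n)
    xs = rng.integers(0, w, n)
    amps = intensity * (0.5 + rng.random(n))
    # Impulse scaled so the blurred peak is ~amp.
    np.add.at(img, (ys, xs), amps * 2 * np.pi * sigma ** 2)
    return gaussian_filter(img, sigma, mode="constant")


def _render_fibers(shape: tuple[int, int], rng: np.random.Generator,
                   density: float, length: float, width: float,
                   intensity: float) -> np.ndarray:
    """SHG collagen: straight fiber segments blurred to a finite width."""
    h, w = shape
    n = int(round(density * h * w / 1e6))
    img = np.zeros(shape, dtype=float)
    if n == 0 or intensity == 0:
        return img
    amp = intensity * np.sqrt(2 * np.pi) * max(width, 0.5)
    for _ in range(n):
        y0 = rng.uniform(0, h)
        x0 = rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        seg = length * (0.5 + rng.random())
        y1 = y0 + seg * np.sin(theta)
        x1 = x0 + seg * np.cos(theta)
        rr, cc = _draw_line(int(round(y0)), int(round(x0)),
                            int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] += amp * (0.7 + 0.6 * rng.random())
    return gaussian_filter(img, max(width, 0.5), mode="constant")


def render_tile_stacks(
    truth: np.ndarray,
    spec: GridSpec,
    *,
    n_z: int = 1,
    vignette: np.ndarray | None = None,
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
    defocus_blur: float = 1.2,
    defocus_attenuation: float = 0.15,
    rng: np.random.Generator | int | None = 0,
) -> TileGrid:
    """Cut a truth image into tile z-stacks with defocus, vignetting, noise.

    Each tile at grid position (r, c) covers the truth region implied by the
    overlap. The focal z-slice (stack center) is unblurred and unattenuated;
    off-focus slices get a Gaussian blur of ``defocus_blur * |dz|`` pixels
    and intensity factor ``1 - defocus_attenuation * |dz|``. Output tiles
    are uint16, clipped to [0, 65535].
    """
    truth = np.asarray(truth)
    h, w = spec.shape
    if truth.shape[0] < h or truth.shape[1] < w:
        raise ValueError(f"truth image {truth.shape} smaller than stitched "
                         f"extent {(h, w)}")
    if vignette is not None and vignette.shape != (spec.tile_size, spec.tile_size):
        raise ValueError("vignette field must match the tile size")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    ts = spec.tile_size
    focus = (n_z - 1) / 2
    tiles = np.empty((spec.rows, spec.cols, n_z, ts, ts), dtype=np.uint16)
    for r in range(spec.rows):
        for c in range(spec.cols):
            y, x = spec.tile_origin(r, c)
            crop = truth[y:y + ts, x:x + ts]
            for z in range(n_z):
                dz = abs(z - focus)
                clean = (z == focus == 0 and vignette is None
                         and not shot_noise and read_noise_sd == 0)
                if clean:
                    # Noiseless single-slice path: the tile IS the crop.
                    tiles[r, c, z] = crop
                    continue
                img = crop.astype(float)
                if dz > 0 and defocus_blur > 0:
                    img = gaussian_filter(img, defocus_blur * dz)
                img *= max(0.0, 1.0 - defocus_attenuation * dz)
                if vignette is not None:
                    img = img * vignette
                if shot_noise:
                    img = rng.poisson(np.clip(img, 0, None)).astype(float)
                if read_noise_sd > 0:
                    img = img + rng.normal(0.0, read_noise_sd, img.shape)
                tiles[r, c, z] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return TileGrid(tiles=tiles, spec=spec)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def generate_tissue_phantom(
    class_label: str,
    preparation: str,
    params: PhantomParams | None = None,
    seed: int = 0,
    *,
    grid: GridSpec | None = None,
    n_z: int = 5,
    channels: tuple[str, ...] | None = None,
    sample_id: str | None = None,
) -> SampleRecord:
    """Generate one tumor/normal phantom with per-channel tile z-stacks.

    Identical (class, preparation, params, seed, geometry) give bit-identical
    output. The ground-truth full-field image per channel is retained on the
    record for oracle tests.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if preparation not in PREPARATIONS:
        raise ValueError(f"unknown preparation {preparation!r}")
    params = params or PhantomParams()
    grid = grid or GridSpec()
    if channels is None:
        channels = CHANNELS if preparation == "FFPE" else FROZEN_CHANNELS
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
    if preparation == "frozen" and "NADH" in channels:
        raise ValueError("NADH cannot be generated for fixed-frozen samples")

    rng = np.random.default_rng(seed)
    shape = grid.shape
    tumor = class_label == "tumor"

    vignette = None
    if params.vignette_strength > 0:
        vignette = make_vignette(grid.tile_size, params.vignette_strength)

    record = SampleRecord(
        sample_id=sample_id or f"{preparation}_{class_label}_{seed}",
        label=class_label,
        preparation=preparation,
    )
    for ch in CHANNELS:  # fixed iteration order keeps draws deterministic
        if ch not in channels:
            continue
        if ch == "SHG":
            density = params.fiber_density * (params.tumor_shg_density_mult if tumor else 1.0)
            intensity = params.fiber_intensity * (params.tumor_shg_brightness_mult if tumor else 1.0)
            structure = _render_fibers(shape, rng, density, params.fiber_length,
                                       params.fiber_width, intensity)
        else:
            sigma = params.blob_sigma * (params.tumor_blob_sigma_mult if tumor else 1.0)
            structure = _render_blobs(shape, rng, params.blob_density,
                                      params.blob_intensity, sigma)
        img = structure + params.background.get(ch, 0.0)
        if preparation == "frozen":
            img = img * params.frozen_brightness.get(ch, 1.0)
        if params.gain_jitter_sd > 0:
            img = img * float(np.exp(rng.normal(0.0, params.gain_jitter_sd)))
        truth = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        record.truth[ch] = truth
        record.tiles[ch] = render_tile_stacks(
            truth, grid,
            n_z=n_z,
            vignette=vignette,
            read_noise_sd=params.read_noise_sd,
            shot_noise=params.shot_noise,
            defocus_blur=params.defocus_blur,
            defocus_attenuation=params.defocus_attenuation,
            rng=rng,
        )
    return record


def _sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed from the master seed and sample index."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(design: CohortDesign | None = None,
                    params: PhantomParams | None = None,
                    seed: int = 0) -> list[SampleRecord]:
    """Generate one SampleRecord per design cell count, with unique ids.

    Per-sample seeds derive deterministically from the master seed and the
    sample's index in a fixed cell order, so cohorts are reproducible.
    """
    design = design or CohortDesign()
    params = params or PhantomParams()
    if design.total == 0:
        raise ValueError("empty cohort design (all cell counts are zero)")
    cohort: list[SampleRecord] = []
    index = 0
    for prep in PREPARATIONS:
        for label in CLASSES:
            for k in range(design.counts.get((label, prep), 0)):
                record = generate_tissue_phantom(
                    label, prep, params,
                    seed=_sample_seed(seed, index),
                    grid=design.grid,
                    n_z=design.n_z,
                    channels=design.channels[prep],
                    sample_id=f"{prep}_{label}_{k:02d}",
                )
                cohort.append(record)
                index += 1
    return cohort


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_sample_tiffs(record: SampleRecord, out_dir: str) -> list[str]:
    """Write each tile z-stack as a multi-page 16-bit grayscale TIFF."""
    import tifffile

    paths = []
    for ch, grid in record.tiles.items():
        ch_dir = os.path.join(out_dir, record.sample_id, ch)
        os.makedirs(ch_dir, exist_ok=True)
        for r in range(grid.spec.rows):
            for c in range(grid.spec.cols):
                path = os.path.join(ch_dir, f"tile_r{r:02d}_c{c:02d}.tif")
                tifffile.imwrite(path, grid.tiles[r, c])
                paths.append(path)
    return paths


def write_cohort(cohort: list[SampleRecord], out_dir: str,
                 write_tiles: bool = True) -> str:
    """Write cohort tiles plus a JSON manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for record in cohort:
        entry = {
            "sample_id": record.sample_id,
            "label": record.label,
            "preparation": record.preparation,
            "site": record.site,
            "channels": list(record.channels),
            "path": record.sample_id,
        }
        if write_tiles:
            write_sample_tiffs(record, out_dir)
        manifest.append(entry)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def save_config(design: CohortDesign, params: PhantomParams, path: str) -> None:
    """Serialize the cohort design and phantom parameters as YAML."""
    import yaml

    payload = {
        "design": {
            "counts": {f"{label}/{prep}": v
                       for (label, prep), v in design.counts.items()},
            "channels": {k: list(v) for k, v in design.channels.items()},
            "grid": {"rows": design.grid.rows, "cols": design.grid.cols,
                     "tile_size": design.grid.tile_size,
                     "overlap": design.grid.overlap},
            "n_z": design.n_z,
            "z_step_um": design.z_step_um,
        },
        "params": {
            "background": dict(params.background),
            "blob_density": params.blob_density,
            "blob_intensity": params.blob_intensity,
            "blob_sigma": params.blob_sigma,
            "fiber_density": params.fiber_density,
            "fiber_length": params.fiber_length,
            "fiber_width": params.fiber_width,
            "fiber_intensity": params.fiber_intensity,
            "tumor_shg_density_mult": params.tumor_shg_density_mult,
            "tumor_shg_brightness_mult": params.tumor_shg_brightness_mult,
            "tumor_blob_sigma_mult": params.tumor_blob_sigma_mult,
            "frozen_brightness": dict(params.frozen_brightness),
            "vignette_strength": params.vignette_strength,
            "read_noise_sd": params.read_noise_sd,
            "shot_noise": params.shot_noise,
            "gain_jitter_sd": params.gain_jitter_sd,
            "defocus_blur": params.defocus_blur,
            "defocus_attenuation": params.defocus_attenuation,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path: str) -> tuple[CohortDesign, PhantomParams]:
    """Inverse of :func:`save_config`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    d = payload["design"]
    counts = {}
    for key, v in d["counts"].items():
        label, prep = key.split("/")
        counts[(label, prep)] = int(v)
    design = CohortDesign(
        counts=counts,
        channels={k: tuple(v) for k, v in d["channels"].items()},
        grid=GridSpec(**d["grid"]),
        n_z=int(d["n_z"]),
        z_step_um=float(d["z_step_um"]),
    )
    params = PhantomParams(**payload["params"])
    return design, params
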