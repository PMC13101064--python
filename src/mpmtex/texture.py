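"""Gray-level co-occurrence matrices and the 13 Haralick texture features.

A channel image is linearly quantized to G gray levels, pixel pairs at
distance 1 are accumulated symmetrically in the four angular directions
(0, 45, 90, 135 degrees), each directional matrix is normalized to sum 1,
and the four are averaged entrywise — pancreatic tissue is treated as
rotationally symmetric. The 13 classical Haralick statistics are computed
from the averaged matrix; the unstable 14th is never computed. All
logarithms are natural and 0*log(0) := 0.

Degenerate conventions (documented, deterministic):

* f3 (correlation) := 0 when a marginal standard deviation is zero;
* f12 := 0 when max(HX, HY) = 0;
* f13's exponent argument is clamped at 0 before the square root;
* f7 (sum variance) is computed about the sum average f6 (the circulating
  definition writes f8 there, a known misprint);
* f10 (difference variance) defaults to the variance of the difference
  distribution; ``f10_variant="raw_moment"`` gives the uncentred second
  moment instead, a variant that appears in some sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

__all__ = [
    "HARALICK_FEATURE_NAMES",
    "GLCMatrix",
    "HaralickVector",
    "FeatureTable",
    "quantize_gray",
    "compute_glcm",
    "haralick13",
    "build_feature_table",
    "feature_column_names",
]

HARALICK_FEATURE_NAMES = (
    "angular second moment",
    "contrast",
    "correlation",
    "sum of squares: variance",
    "inverse difference moment",
    "sum average",
    "sum variance",
    "sum entropy",
    "entropy",
    "difference variance",
    "difference entropy",
    "information measure of correlation 1",
    "information measure of correlation 2",
)


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    distance: int = 1
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    averaged: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(m < 0):
            raise ValueError("GLCM entries must be non-negative")
        if abs(float(m.sum()) - 1.0) > 1e-9:
            raise ValueError("GLCM entries must sum to 1")


@dataclass(frozen=True)
class HaralickVector:
    """The 13 Haralick statistics of one GLCM, in canonical order f1..f13."""

    values: tuple[float, ...]
    names: tuple[str, ...] = HARALICK_FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.values) != 13:
            raise ValueError("expected 13 feature values")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, i: int) -> float:
        return self.values[i]


@dataclass
class FeatureTable:
    """Samples x named-features matrix with class/preparation metadata.

    Feature columns are named ``"<Channel> <NN>"`` with NN the 1-based,
    zero-padded Haralick index (e.g. ``"SHG 06"`` is the sum average of the
    SHG image).
    """

    sample_ids: list[str]
    labels: list[str]
    preparations: list[str]
    features: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.labels) == len(self.preparations) == n == len(self.features)):
            raise ValueError("metadata and feature matrix lengths disagree")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.features.columns)) != self.features.shape[1]:
            raise ValueError("duplicate feature names")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def width(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.sample_ids, self.labels, self.preparations,
                            self.features[columns].copy())

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame({
            "sample_id": self.sample_ids,
            "label": self.labels,
            "preparation": self.preparations,
        })
        return pd.concat([meta, self.features.reset_index(drop=True)], axis=1)


def feature_column_names(channels: tuple[str, ...] | list[str]) -> list[str]:
    return [f"{ch} {k:02d}" for ch in channels for k in range(1, 14)]


# ---------------------------------------------------------------------------
# Quantization and GLCM accumulation
# ---------------------------------------------------------------------------

def quantize_gray(image: np.ndarray, levels: int = 64) -> np.ndarray:
    """Linear equal-width binning of [min, max] into ``levels`` gray levels.

    A constant image maps to all zeros. Integer images are binned with
    exact integer arithmetic so a ramp 0..levels-1 is the identity.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    mn, mx = img.min(), img.max()
    if mn == mx:
        return np.zeros(img.shape, dtype=np.uint8 if levels <= 256 else np.int64)
    if np.issubdtype(img.dtype, np.integer):
        span = int(mx) - int(mn) + 1
        q = (img.astype(np.int64) - int(mn)) * levels // span
    else:
        q = np.floor((img - mn) / (mx - mn) * levels).astype(np.int64)
        q = np.minimum(q, levels - 1)
    return q.astype(np.uint8 if levels <= 256 else np.int64)


def compute_glcm(
    image: np.ndarray,
    distance: int = 1,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    average: bool = True,
    levels: int | None = None,
) -> GLCMatrix:
    """Symmetric, normalized co-occurrence matrix of a quantized image.

    Ordered pixel pairs at the given offset are accumulated in both orders
    per direction, each directional matrix normalized to sum 1, and (with
    ``average``) the directional matrices averaged entrywise.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if len(angles) == 0:
        raise ValueError("empty direction set")
    if min(img.shape) <= distance:
        raise ValueError("image too small for the requested offset")
    if img.min() < 0:
        raise ValueError("quantized image must be non-negative")
    if levels is None:
        levels = max(2, int(img.max()) + 1)
    if img.max() >= levels:
        raise ValueError("image values must be < levels")

    glcm = graycomatrix(img.astype(np.uint8), [distance], np.deg2rad(angles),
                        levels=levels, symmetric=True, normed=True)
    per_dir = glcm[:, :, 0, :]
    if not np.all(np.isfinite(per_dir)):
        raise ValueError("a requested direction has no pixel pairs")
    matrix = per_dir.mean(axis=-1) if average else per_dir[..., 0]
    return GLCMatrix(matrix=matrix, levels=levels, distance=distance,
                     angles=tuple(angles), averaged=average)


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def haralick13(glcm: GLCMatrix | np.ndarray, f10_variant: str = "variance") -> HaralickVector:
    """The 13 Haralick statistics of a normalized GLCM (natural logs)."""
    P = np.asarray(glcm.matrix if isinstance(glcm, GLCMatrix) else glcm, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if np.any(P < 0):
        raise ValueError("GLCM entries must be non-negative")
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized to sum 1")
    if f10_variant not in ("variance", "raw_moment"):
        raise ValueError(f"unknown f10 variant {f10_variant!r}")

    G = P.shape[0]
    i = np.arange(G, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj).astype(int)
    summ = (ii + jj).astype(int)
    p_sum = np.bincount(summ.ravel(), weights=P.ravel(), minlength=2 * G - 1)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=G)
    ks = np.arange(2 * G - 1, dtype=float)
    kd = np.arange(G, dtype=float)

    f1 = float((P ** 2).sum())
    f2 = float((kd ** 2 * p_diff).sum())
    cross = float((ii * jj * P).sum())
    f3 = (cross - mux * muy) / (sx * sy) if sx * sy > 0 else 0.0
    f4 = float(((i - mux) ** 2 * px).sum())
    f5 = float((P / (1.0 + (ii - jj) ** 2)).sum())
    f6 = float((ks * p_sum).sum())
    f7 = float(((ks - f6) ** 2 * p_sum).sum())
    f8 = _entropy(p_sum)
    f9 = _entropy(P.ravel())
    mu_d = float((kd * p_diff).sum())
    if f10_variant == "variance":
        f10 = float(((kd - mu_d) ** 2 * p_diff).sum())
    else:
        f10 = float((kd ** 2 * p_diff).sum())
    f11 = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pq = np.outer(px, py)
    mask = pq > 0
    hxy1 = float(-(P[mask] * np.log(pq[mask])).sum())
    hxy2 = _entropy(pq.ravel())
    denom = max(hx, hy)
    f12 = (f9 - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - f9))
    f13 = float(np.sqrt(max(arg, 0.0)))

    return HaralickVector(values=(f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13))


# ---------------------------------------------------------------------------
# Per-sample feature tables
# ---------------------------------------------------------------------------

def build_feature_table(
    cohort: list,
    channels: tuple[str, ...] | list[str],
    levels: int = 64,
    source: str = "stitched",
    distance: int = 1,
) -> FeatureTable:
    """13 Haralick features per channel per sample, on stitched images.

    Every sample must provide every requested channel (requesting NADH for
    a fixed-frozen sample is an error). ``source="stitched"`` assembles the
    per-channel max-projection mosaics if not already cached on the record.
    """
    if source != "stitched":
        raise ValueError("only source='stitched' is supported")
    if not cohort:
        raise ValueError("empty cohort")
    from .preprocess import assemble_sample

    columns = feature_column_names(channels)
    rows = []
    ids, labels, preps = [], [], []
    for record in cohort:
        assemble_sample(record)
        row = []
        for ch in channels:
            if ch not in record.images:
                raise ValueError(
                    f"channel {ch!r} missing from sample {record.sample_id!r}")
            q = quantize_gray(record.images[ch], levels)
            glcm = compute_glcm(q, distance=distance, levels=levels)
            row.extend(haralick13(glcm).values)
        rows.append(row)
        ids.append(record.sample_id)
        labels.append(record.label)
        preps.append(record.preparation)
    features = pd.DataFrame(rows, columns=columns)
    return FeatureTable(ids, labels, preps, features)
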