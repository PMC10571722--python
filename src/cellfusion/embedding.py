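"""Embedded whole-slide maps: per-window cell-type abundance grids.

A mapped nuclei table is converted into a 3-channel grid in which cell
``(c, i, j)`` holds the number of nuclei of merged class ``c`` whose centroid
falls in the 64 x 64 px window at row ``i``, column ``j`` (window membership
by centroid, half-open windows, so conservation is exact).  At the default
window size this is a 64-fold lateral reduction of the slide.  The map is then
brought to the model's fixed input resolution (default 256) by area-weighted
sum pooling, which preserves total count mass, and optionally normalized
(log1p by default: window counts are heavy-tailed) and augmented.

Augmentation operates on the count grid itself — there is no RGB image at
this stage — so "brightness/contrast/saturation" jitter is interpreted
photometrically on channels: brightness and contrast rescale multiplicatively
around zero / around the mean, and saturation mixes each channel toward the
per-pixel channel mean.  Geometric augmentations are right-angle rotations,
flips, and a random resized crop ("scaling").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

from .nuclei_io import MERGED_CLASSES, NucleiTable, ValidationError

DEFAULT_WINDOW_SIZE = 64
DEFAULT_INPUT_RESOLUTION = 256


@dataclass
class EmbeddedMap:
    """3-channel grid of per-window nucleus counts (the reduced slide)."""

    counts: np.ndarray  # (3, H_w, W_w), non-negative
    window_size: int = DEFAULT_WINDOW_SIZE
    channel_order: tuple[str, ...] = MERGED_CLASSES
    slide_width: int | None = None
    slide_height: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.channel_order):
            raise ValidationError(
                f"counts must be ({len(self.channel_order)}, H, W), got {self.counts.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def channel_sums(self) -> dict[str, float]:
        return {
            name: float(self.counts[c].sum()) for c, name in enumerate(self.channel_order)
        }

    def total(self) -> float:
        return float(self.counts.sum())


def build_embedded_map(table: NucleiTable, window_size: int = DEFAULT_WINDOW_SIZE) -> EmbeddedMap:
    """Count nuclei of each merged class per half-open window.

    Grid dimensions are ``ceil(slide / window_size)``; every mapped nucleus
    lands in exactly one window, so channel sums equal per-class counts.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    if not table.is_mapped:
        raise ValidationError("table must be class-mapped before embedding")
    h_w = -(-table.slide_height // window_size)  # ceil div
    w_w = -(-table.slide_width // window_size)
    counts = np.zeros((len(MERGED_CLASSES), h_w, w_w), dtype=np.int64)
    if len(table) > 0:
        cols = (table.records["centroid_x"].to_numpy() // window_size).astype(np.intp)
        rows = (table.records["centroid_y"].to_numpy() // window_size).astype(np.intp)
        for c, name in enumerate(MERGED_CLASSES):
            mask = (table.records["merged_class"] == name).to_numpy()
            np.add.at(counts[c], (rows[mask], cols[mask]), 1)
    return EmbeddedMap(
        counts=counts,
        window_size=window_size,
        slide_width=table.slide_width,
        slide_height=table.slide_height,
    )


def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) matrix of fractional overlaps between uniform bins.

    Row sums are the scale factor n_in / n_out; columns sum to 1, so applying
    the matrix along an axis redistributes mass exactly (sum pooling view).
    """
    edges_out = np.linspace(0.0, n_in, n_out + 1)
    A = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = edges_out[i], edges_out[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            A[i, j] = max(0.0, min(hi, j + 1) - max(lo, j))
    return A


def resize_to_input(
    emap: EmbeddedMap,
    resolution: int = DEFAULT_INPUT_RESOLUTION,
    mode: Literal["area", "bilinear", "pad"] = "area",
) -> np.ndarray:
    """Bring a map to the fixed model resolution, shape (3, R, R).

    ``area`` (default) distributes each source cell's count mass over the
    target cells it overlaps, so the total is preserved exactly for any
    integer or fractional scale factor.  ``bilinear`` interpolates values
    instead (not mass-preserving).  ``pad`` zero-pads (or center-crops) to
    the target without resampling.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    grid = np.asarray(emap.counts, dtype=np.float64)
    _, h, w = grid.shape
    if h == 0 or w == 0:
        raise ValidationError("cannot resize an empty map")
    if mode == "pad":
        out = np.zeros((grid.shape[0], resolution, resolution))
        hs = min(h, resolution)
        ws = min(w, resolution)
        oy, ox = (resolution - hs) // 2, (resolution - ws) // 2
        iy, ix = (h - hs) // 2, (w - ws) // 2
        out[:, oy : oy + hs, ox : ox + ws] = grid[:, iy : iy + hs, ix : ix + ws]
        return out
    if mode == "bilinear":
        from scipy.ndimage import zoom

        return zoom(grid, (1, resolution / h, resolution / w), order=1, grid_mode=True, mode="grid-constant")
    if mode != "area":
        raise ValidationError(f"unknown resize mode {mode!r}")
    Ah = _overlap_matrix(h, resolution)
    Aw = _overlap_matrix(w, resolution)
    return np.einsum("ri,cij,sj->crs", Ah, grid, Aw, optimize=True)


def normalize_counts(
    grid: EmbeddedMap | np.ndarray,
    scheme: Literal["none", "log1p", "max_scale"] = "log1p",
) -> np.ndarray:
    """Monotone per-entry normalization of a count grid."""
    x = np.asarray(grid.counts if isinstance(grid, EmbeddedMap) else grid, dtype=np.float64)
    if scheme == "none":
        return x.copy()
    if scheme == "log1p":
        return np.log1p(x)
    if scheme == "max_scale":
        m = x.max()
        return x / m if m > 0 else x.copy()
    raise ValidationError(f"unknown normalization scheme {scheme!r}")


@dataclass
class AugmentationSpec:
    """Stochastic train-time transforms of the model input grid.

    Geometric: right-angle rotation, horizontal/vertical flip, and a random
    resized crop with area scale drawn from ``scale_range``.  Photometric:
    multiplicative brightness, contrast around the per-channel mean, and
    saturation mixing toward the per-pixel channel mean; each jitter factor
    is drawn uniformly from ``1 ± range``.  Defaults are mild.
    """

    enable_rotation: bool = True
    enable_flip: bool = True
    scale_range: tuple[float, float] = (0.9, 1.0)
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi <= 1.0):
            raise ValidationError("scale_range must satisfy 0 < lo <= hi <= 1")
        for name in ("brightness", "contrast", "saturation"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} jitter range must be >= 0")


def augment(grid: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to a (3, R, R) grid.

    Deterministic given (grid, spec, rng state).  Rotation and flip permute
    entries and therefore conserve channel sums; the crop and photometric
    jitters do not.
    """
    out = np.asarray(grid, dtype=np.float64)
    if out.ndim != 3:
        raise ValidationError("augment expects a (C, R, R) grid")
    r = out.shape[1]

    if spec.enable_rotation:
        k = int(rng.integers(0, 4))
        out = np.rot90(out, k=k, axes=(1, 2))
    if spec.enable_flip:
        if rng.random() < 0.5:
            out = out[:, :, ::-1]
        if rng.random() < 0.5:
            out = out[:, ::-1, :]

    lo, hi = spec.scale_range
    if hi < 1.0 or lo < 1.0:
        scale = float(rng.uniform(lo, hi))
        side = max(1, int(round(out.shape[1] * np.sqrt(scale))))
        y0 = int(rng.integers(0, out.shape[1] - side + 1))
        x0 = int(rng.integers(0, out.shape[2] - side + 1))
        crop = out[:, y0 : y0 + side, x0 : x0 + side]
        crop_map = EmbeddedMap(counts=crop, window_size=1)
        out = resize_to_input(crop_map, out.shape[1], mode="area")

    if spec.brightness > 0:
        out = out * float(rng.uniform(1 - spec.brightness, 1 + spec.brightness))
    if spec.contrast > 0:
        f = float(rng.uniform(1 - spec.contrast, 1 + spec.contrast))
        mean = out.mean(axis=(1, 2), keepdims=True)
        out = mean + f * (out - mean)
    if spec.saturation > 0:
        f = float(rng.uniform(1 - spec.saturation, 1 + spec.saturation))
        channel_mean = out.mean(axis=0, keepdims=True)
        out = channel_mean + f * (out - channel_mean)
    return np.ascontiguousarray(out)


def prepare_model_input(
    emap: EmbeddedMap,
    resolution: int = DEFAULT_INPUT_RESOLUTION,
    normalization: Literal["none", "log1p", "max_scale"] = "log1p",
    resize_mode: Literal["area", "bilinear", "pad"] = "area",
) -> np.ndarray:
    """Resize then normalize a map into the fixed (3, R, R) model input."""
    grid = resize_to_input(emap, resolution, mode=resize_mode)
    return normalize_counts(grid, normalization)


def save_embedded_map(emap: EmbeddedMap, path: str | Path) -> None:
    """Persist as a 3-page TIFF (one page per channel) + sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(emap.counts, dtype=np.float32), photometric="minisblack")
    sidecar = {
        "window_size": emap.window_size,
        "channel_order": list(emap.channel_order),
        "slide_width": emap.slide_width,
        "slide_height": emap.slide_height,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_embedded_map(path: str | Path) -> EmbeddedMap:
    """Load a map written by :func:`save_embedded_map`."""
    path = Path(path)
    counts = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EmbeddedMap(
        counts=np.asarray(counts),
        window_size=int(sidecar["window_size"]),
        channel_order=tuple(sidecar["channel_order"]),
        slide_width=sidecar.get("slide_width"),
        slide_height=sidecar.get("slide_height"),
    )
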