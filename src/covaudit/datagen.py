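"""Synthetic crop-tile generation and stand-in black-box classifiers.

Emulates aerial soybean defoliation tiles: fixed-size single-channel images
with a darker "defoliated" blob structure over a brighter canopy background.
A tile is labeled *defoliated* when strictly more than 10% of its pixels are
defoliated in the ground-truth mask, else *healthy*. Ground-truth masks are
retained alongside every image so the labeling rule and oracle classifiers
are exactly computable.

Labels are integers throughout the package: 0 = healthy, 1 = defoliated.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image as PILImage

HEALTHY = 0
DEFOLIATED = 1

#: Default strict labeling threshold: defoliated iff fraction > this value.
DEFAULT_LABEL_THRESHOLD = 0.10

_BIAS_MODES = ("none", "half_left", "corner", "shadow_gradient")


@dataclass(frozen=True)
class Image:
    """A single-channel crop tile.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    pixels : ndarray of shape (H, W)
        Intensities in [0, 1].
    field_location : (row, col) tuple, optional
        Tile coordinates in the source field, used for spot-check manifests.
    """

    id: str
    pixels: np.ndarray
    field_location: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def features(self) -> np.ndarray:
        """Row-major flattened feature vector (feature index = row*W + col)."""
        return self.pixels.ravel()


@dataclass(frozen=True)
class GenConfig:
    """Configuration for the synthetic field-tile generator.

    Defaults mirror the real survey conditions the generator emulates:
    108x108 tiles, balanced classes (the class balance of the original
    survey is not published, so it is an explicit parameter here).
    """

    n_images: int = 500
    H: int = 108
    W: int = 108
    defoliated_fraction_target: float = 0.5
    blob_count_range: tuple[int, int] = (1, 5)
    blob_radius_range: tuple[int, int] = (3, 14)
    bias_mode: str = "none"
    noise_sd: float = 0.05
    seed: int = 0

    #: Intensity of healthy canopy and of defoliated pixels, before noise.
    canopy_intensity: float = 0.65
    defoliation_intensity: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.defoliated_fraction_target <= 1.0):
            raise ValueError("defoliated_fraction_target must be in [0, 1]")
        if self.bias_mode not in _BIAS_MODES:
            raise ValueError(
                f"unknown bias_mode {self.bias_mode!r}; expected one of {_BIAS_MODES}"
            )
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if self.H < 1 or self.W < 1:
            raise ValueError("H and W must be >= 1")


def label_by_defoliation_fraction(
    image: Image, ground_truth_mask: np.ndarray, threshold: float = DEFAULT_LABEL_THRESHOLD
) -> int:
    """Label a tile from its ground-truth defoliation mask.

    Returns ``DEFOLIATED`` iff the defoliated-pixel fraction is *strictly*
    greater than ``threshold`` (a tile at exactly the threshold is healthy).
    """
    mask = np.asarray(ground_truth_mask)
    if mask.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.pixels.shape}"
        )
    fraction = float(np.count_nonzero(mask)) / mask.size
    return DEFOLIATED if fraction > threshold else HEALTHY


def _disk_mask(H: int, W: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:H, :W]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _place_blobs(
    rng: np.random.Generator,
    cfg: GenConfig,
    target_frac: float,
    max_frac: float = 1.0,
) -> np.ndarray:
    """Union of random disks until the mask reaches ``target_frac`` coverage.

    A disk that would push coverage past ``max_frac`` is rejected, so
    healthy tiles never accidentally cross the labeling threshold. Under
    ``half_left`` every disk lies entirely in columns < W/2; under
    ``corner`` in the top-left quadrant. ``shadow_gradient`` biases only
    intensities, not blob placement.
    """
    H, W = cfg.H, cfg.W
    mask = np.zeros((H, W), dtype=bool)
    if target_frac <= 0.0:
        return mask
    lo_r, hi_r = cfg.blob_radius_range
    lo_r = max(1, min(lo_r, min(H, W) // 2))
    hi_r = max(lo_r, min(hi_r, min(H, W) // 2))
    if cfg.bias_mode == "half_left":
        col_hi = W / 2.0  # disks must satisfy cx + r < W/2
    elif cfg.bias_mode == "corner":
        col_hi = W / 2.0
    else:
        col_hi = float(W)
    row_hi = H / 2.0 if cfg.bias_mode == "corner" else float(H)

    for _ in range(500):
        if mask.mean() >= target_frac:
            break
        r = rng.uniform(lo_r, hi_r)
        # Clamp the radius so a biased disk can fit strictly inside its region.
        r = min(r, max(1.0, col_hi / 2.0 - 1.0), max(1.0, row_hi / 2.0 - 1.0))
        cy = rng.uniform(r, row_hi - r - 1e-9) if row_hi - r > r else row_hi / 2.0
        cx = rng.uniform(r, col_hi - r - 1e-9) if col_hi - r > r else col_hi / 2.0
        candidate = mask | _disk_mask(H, W, cy, cx, r)
        if candidate.mean() <= max_frac:
            mask = candidate
    return mask


def _render(rng: np.random.Generator, cfg: GenConfig, mask: np.ndarray) -> np.ndarray:
    px = np.full((cfg.H, cfg.W), cfg.canopy_intensity)
    px[mask] = cfg.defoliation_intensity
    if cfg.bias_mode == "shadow_gradient":
        # Illumination ramp across columns, darkest on the right edge.
        px -= 0.20 * (np.arange(cfg.W) / max(1, cfg.W - 1))[None, :]
    if cfg.noise_sd > 0:
        px = px + rng.normal(0.0, cfg.noise_sd, size=px.shape)
    return np.clip(px, 0.0, 1.0)


def generate_field_images(
    config: GenConfig,
) -> list[tuple[Image, np.ndarray, int]]:
    """Generate ``config.n_images`` tiles with ground-truth masks and labels.

    Deterministic given ``config.seed``: each image draws from its own
    counter-derived random stream, so datasets are stable under reordering.
    Tiles are assigned ``field_location`` coordinates on a near-square grid.
    """
    out: list[tuple[Image, np.ndarray, int]] = []
    if config.n_images == 0:
        return out
    field_cols = max(1, math.ceil(math.sqrt(config.n_images)))
    for i in range(config.n_images):
        rng = np.random.default_rng([config.seed, i])
        is_defoliated = rng.random() < config.defoliated_fraction_target
        if is_defoliated:
            # Strictly above the 10% rule, with margin for the fill loop.
            target_frac = rng.uniform(0.14, 0.40)
            max_frac = 1.0
        else:
            target_frac = 0.0 if rng.random() < 0.3 else rng.uniform(0.0, 0.08)
            # Keep healthy tiles safely under the strict >10% threshold.
            max_frac = 0.095
        mask = _place_blobs(rng, config, target_frac, max_frac)
        pixels = _render(rng, config, mask)
        image = Image(
            id=f"tile_{i:05d}",
            pixels=pixels,
            field_location=(i // field_cols, i % field_cols),
        )
        out.append((image, mask, label_by_defoliation_fraction(image, mask)))
    return out


# ---------------------------------------------------------------------------
# Stand-in black-box classifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlackBoxClassifier:
    """A deterministic image -> label function being validated.

    The whole method rests on the black box being a function in the strict
    mathematical sense: the same image always yields the same label, so
    surrogate training labels are noiseless.
    """

    kind: str
    _fn: Callable[[Image], int]
    params: dict = field(default_factory=dict)

    def __call__(self, image: Image) -> int:
        return self._fn(image)

    def label_all(self, images: Sequence[Image]) -> list[int]:
        return [self._fn(img) for img in images]


def make_blackbox(kind: str, params: dict) -> BlackBoxClassifier:
    """Construct a stand-in black box.

    Kinds
    -----
    ``fraction_oracle``
        Labels by the per-image defoliated fraction of a stored mask lookup
        (``params['masks']``: id -> mask; optional ``threshold``).
    ``region_restricted``
        Same rule but only the pixels inside ``params['region']`` count
        (fraction computed over the informative region); used to emulate a
        spatially biased model.
    ``threshold_rule``
        Labels defoliated when the mean intensity falls below
        ``params['cutoff']`` (defoliated canopy is darker).
    """
    if kind == "fraction_oracle":
        masks = {k: np.asarray(v, dtype=bool) for k, v in params["masks"].items()}
        threshold = float(params.get("threshold", DEFAULT_LABEL_THRESHOLD))

        def fn(image: Image) -> int:
            mask = masks[image.id]
            frac = float(np.count_nonzero(mask)) / mask.size
            return DEFOLIATED if frac > threshold else HEALTHY

    elif kind == "region_restricted":
        masks = {k: np.asarray(v, dtype=bool) for k, v in params["masks"].items()}
        region = np.asarray(params["region"], dtype=bool)
        threshold = float(params.get("threshold", DEFAULT_LABEL_THRESHOLD))
        n_region = int(np.count_nonzero(region))
        if n_region == 0:
            raise ValueError("informative region mask is empty")

        def fn(image: Image) -> int:
            mask = masks[image.id]
            if mask.shape != region.shape:
                raise ValueError("mask/region shape mismatch")
            frac = float(np.count_nonzero(mask & region)) / n_region
            return DEFOLIATED if frac > threshold else HEALTHY

    elif kind == "threshold_rule":
        cutoff = float(params["cutoff"])

        def fn(image: Image) -> int:
            return DEFOLIATED if float(image.pixels.mean()) < cutoff else HEALTHY

    else:
        raise ValueError(f"unknown black-box kind {kind!r}")

    return BlackBoxClassifier(kind=kind, _fn=fn, params=dict(params))


# ---------------------------------------------------------------------------
# Disk I/O: 8-bit grayscale PNG images/masks, CSV labels
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: Sequence[tuple[Image, np.ndarray, int]], out_dir: str | Path
) -> None:
    """Write images/ and masks/ as 8-bit grayscale PNG plus labels.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        for image, mask, label in dataset:
            arr = np.round(image.pixels * 255.0).astype(np.uint8)
            PILImage.fromarray(arr, mode="L").save(out / "images" / f"{image.id}.png")
            PILImage.fromarray(
                (np.asarray(mask, dtype=np.uint8) * 255), mode="L"
            ).save(out / "masks" / f"{image.id}.png")
            writer.writerow([image.id, label])


def read_images(image_dir: str | Path) -> list[Image]:
    """Read a directory of grayscale PNG tiles (sorted by filename)."""
    paths = sorted(Path(image_dir).glob("*.png"))
    images = []
    for p in paths:
        arr = np.asarray(PILImage.open(p).convert("L"), dtype=float) / 255.0
        images.append(Image(id=p.stem, pixels=arr))
    return images


def read_labels(csv_path: str | Path) -> dict[str, int]:
    """Read an ``id,label`` CSV into a dict (label 0/1, 1 = defoliated)."""
    labels: dict[str, int] = {}
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["id"]] = int(row["label"])
    return labels
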