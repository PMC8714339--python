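"""Synthetic B-mode gallbladder-ultrasound phantoms with exact ground truth.

A phantom emulates the gross appearance of a transabdominal gallbladder scan:
a dark (hypoechoic) bile-filled lumen enclosed by an echogenic wall, optional
lesion blobs of intermediate echogenicity inside the lumen, and optionally a
bright stone arc with a distal acoustic shadow.  The label mask is rasterized
from the noiseless geometry; multiplicative gamma speckle is applied to the
image only, so masks are pixel-exact by construction.

Class ids: 0 background, 1 wall, 2 lumen, 3 lesion, 4 stone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

CLASS_BACKGROUND = 0
CLASS_WALL = 1
CLASS_LUMEN = 2
CLASS_LESION = 3
CLASS_STONE = 4
CLASS_IDS = (CLASS_BACKGROUND, CLASS_WALL, CLASS_LUMEN, CLASS_LESION, CLASS_STONE)
CLASS_NAMES = ("bg", "wall", "lumen", "lesion", "stone")

MANIFEST_COLUMNS = ["filename", "seed", "n_bg", "n_wall", "n_lumen", "n_lesion", "n_stone"]

_SHADOW_ATTENUATION = 0.35
_MASK64 = (1 << 64) - 1


class ParameterError(ValueError):
    """A phantom parameter violates its documented range."""


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom family.

    Contrasts are mean reflectivities in [0, 1] per class id; ``speckle_shape``
    is the gamma concentration k of the unit-mean multiplicative noise (larger
    k = weaker speckle, variance 1/k).
    """

    image_height: int = 128
    image_width: int = 128
    lumen_axes_range: tuple[float, float] = (28.0, 44.0)
    wall_thickness_range: tuple[float, float] = (4.0, 8.0)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (6.0, 12.0)
    stone_probability: float = 0.3
    class_contrasts: dict[int, float] = field(
        default_factory=lambda: {
            CLASS_BACKGROUND: 0.20,
            CLASS_WALL: 0.55,
            CLASS_LUMEN: 0.05,
            CLASS_LESION: 0.70,
            CLASS_STONE: 0.95,
        }
    )
    speckle_shape: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lumen_axes_range", "wall_thickness_range",
                     "lesion_count_range", "lesion_radius_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ParameterError(f"{name}: low {lo} exceeds high {hi}")
            if lo < 0:
                raise ParameterError(f"{name}: negative bound {lo}")
        if self.image_height < 8 or self.image_width < 8:
            raise ParameterError("image_height/image_width must be at least 8 pixels")
        if not 0.0 <= self.stone_probability <= 1.0:
            raise ParameterError(f"stone_probability {self.stone_probability} outside [0, 1]")
        if self.speckle_shape <= 0:
            raise ParameterError(f"speckle_shape must be positive, got {self.speckle_shape}")
        half = min(self.image_height, self.image_width) / 2
        reach = self.lumen_axes_range[1] + self.wall_thickness_range[1]
        if reach + 2 > half:
            raise ParameterError(
                "lumen_axes_range + wall_thickness_range: outer ellipse "
                f"(reach {reach:.1f}px) does not fit a {self.image_height}x"
                f"{self.image_width} image"
            )
        missing = [c for c in CLASS_IDS if c not in self.class_contrasts]
        if missing:
            raise ParameterError(f"class_contrasts missing class ids {missing}")
        for c, v in self.class_contrasts.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"class_contrasts[{c}] = {v} outside [0, 1]")


@dataclass(frozen=True)
class PhantomSample:
    """One phantom: speckled image, exact label mask, and provenance."""

    image: np.ndarray  # float in [0, 1], (H, W)
    mask: np.ndarray   # uint8 class ids, (H, W)
    metadata: dict

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def derive_seed(master_seed: int, index: int) -> int:
    """Per-sample seed from a master seed, splitmix64-mixed.

    The scheme is fixed so that manifests are portable: the i-th sample of a
    dataset can be regenerated in isolation from (master_seed, i).
    """
    return _splitmix64(master_seed ^ _splitmix64(index + 1)) & ((1 << 63) - 1)


def apply_speckle(clean: np.ndarray, shape_param: float, seed: int,
                  clip: bool = True) -> np.ndarray:
    """Multiply by i.i.d. unit-mean gamma(k, 1/k) noise and clip to [0, 1].

    Gamma multiplicative noise is the standard surrogate for fully developed
    B-mode speckle; variance of the multiplier is 1/k.  ``clip=False`` skips
    the final clip, exposing the raw multiplicative model (useful when
    checking its moments; clipping truncates the upper tail).
    """
    if shape_param <= 0:
        raise ParameterError(f"shape_param must be positive, got {shape_param}")
    clean = np.asarray(clean, dtype=np.float64)
    rng = np.random.default_rng(seed)
    noisy = clean * rng.gamma(shape_param, 1.0 / shape_param, size=clean.shape)
    return np.clip(noisy, 0.0, 1.0) if clip else noisy


def _draw_geometry(params: PhantomParams, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Rasterize the noiseless anatomy; returns (mask, geometry record)."""
    h, w = params.image_height, params.image_width
    mask = np.zeros((h, w), dtype=np.uint8)

    ay = rng.uniform(*params.lumen_axes_range)
    ax = rng.uniform(*params.lumen_axes_range)
    wall = rng.uniform(*params.wall_thickness_range)
    # jitter the center but keep the outer ellipse inside the frame
    slack_y = h / 2 - (ay + wall) - 1
    slack_x = w / 2 - (ax + wall) - 1
    cy = h / 2 + rng.uniform(-1, 1) * min(slack_y, 0.08 * h)
    cx = w / 2 + rng.uniform(-1, 1) * min(slack_x, 0.08 * w)

    rr, cc = ellipse(cy, cx, ay + wall, ax + wall, shape=mask.shape)
    mask[rr, cc] = CLASS_WALL
    rr, cc = ellipse(cy, cx, ay, ax, shape=mask.shape)
    mask[rr, cc] = CLASS_LUMEN

    lo, hi = params.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1))
    lesions = []
    for _ in range(n_lesions):
        r = rng.uniform(*params.lesion_radius_range)
        r = min(r, min(ay, ax) - 2)  # degenerate lumen: shrink instead of reject
        if r < 1:
            continue
        # uniform position in the lumen ellipse shrunk by the lesion radius,
        # so the disk is contained in the lumen by construction
        rho = np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        ly = cy + rho * (ay - r - 1) * np.sin(theta)
        lx = cx + rho * (ax - r - 1) * np.cos(theta)
        rr, cc = disk((ly, lx), r, shape=mask.shape)
        mask[rr, cc] = CLASS_LESION
        lesions.append({"center": (float(ly), float(lx)), "radius": float(r)})

    stone = None
    if rng.uniform() < params.stone_probability:
        rs = max(2.0, 0.25 * min(ay, ax))
        sy = cy + 0.55 * ay
        sx = cx + rng.uniform(-0.3, 0.3) * ax
        rr, cc = disk((sy, sx), rs, shape=mask.shape)
        keep = rr <= sy  # proximal arc only: the distal half is shadowed out
        mask[rr[keep], cc[keep]] = CLASS_STONE
        stone = {"center": (float(sy), float(sx)), "radius": float(rs)}

    geometry = {
        "lumen_center": (float(cy), float(cx)),
        "lumen_axes": (float(ay), float(ax)),
        "wall_thickness": float(wall),
        "lesions": lesions,
        "stone": stone,
    }
    return mask, geometry


def _render_clean(mask: np.ndarray, params: PhantomParams, geometry: dict) -> np.ndarray:
    lut = np.zeros(max(CLASS_IDS) + 1)
    for c in CLASS_IDS:
        lut[c] = params.class_contrasts[c]
    clean = lut[mask]
    stone = geometry["stone"]
    if stone is not None:
        # distal acoustic shadow: attenuate anechoic classes below the stone
        sy, sx = stone["center"]
        rs = stone["radius"]
        h, w = mask.shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        column = (np.abs(cols - sx) <= rs) & (rows > sy)
        soft = column & np.isin(mask, (CLASS_BACKGROUND, CLASS_LUMEN))
        clean = np.where(soft, clean * _SHADOW_ATTENUATION, clean)
    return clean


def generate_phantom(params: PhantomParams, seed: int | None = None) -> PhantomSample:
    """Generate one phantom; a pure function of (params, seed)."""
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    mask, geometry = _draw_geometry(params, rng)
    clean = _render_clean(mask, params, geometry)
    noise_seed = derive_seed(seed, 0x5BECC1E)
    image = apply_speckle(clean, params.speckle_shape, noise_seed)
    metadata = {"params": dataclasses.asdict(params), "seed": int(seed),
                "geometry": geometry}
    return PhantomSample(image=image, mask=mask, metadata=metadata)


def class_pixel_counts(mask: np.ndarray) -> dict[str, int]:
    counts = np.bincount(mask.ravel(), minlength=len(CLASS_IDS))
    return {f"n_{name}": int(counts[c]) for c, name in zip(CLASS_IDS, CLASS_NAMES)}


def write_sample(sample: PhantomSample, image_path: Path, mask_path: Path) -> None:
    """8-bit grayscale PNG image (round(255*value)) + indexed-PNG class mask."""
    iio.imwrite(image_path, np.round(255 * sample.image).astype(np.uint8))
    iio.imwrite(mask_path, sample.mask.astype(np.uint8))


def load_pair(image_path: Path, mask_path: Path) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(iio.imread(image_path), dtype=np.float64) / 255.0
    mask = np.asarray(iio.imread(mask_path)).astype(np.int64)
    return image, mask


def mask_path_for(image_path: Path) -> Path:
    image_path = Path(image_path)
    return image_path.with_name(image_path.stem + "_mask.png")


def generate_dataset(params: PhantomParams, n: int, seed: int, out_dir: Path) -> pd.DataFrame:
    """Write n image/mask PNG pairs plus a CSV manifest; returns the manifest.

    Per-sample seeds are ``derive_seed(seed, i)``, so any row can be
    regenerated independently of the others.
    """
    params.validate()
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(n):
            sample_seed = derive_seed(seed, i)
            sample = generate_phantom(params, sample_seed)
            name = f"phantom_{i:04d}.png"
            write_sample(sample, out_dir / name, mask_path_for(out_dir / name))
            rows.append({"filename": name, "seed": sample_seed,
                         **class_pixel_counts(sample.mask)})
        manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    except OSError as exc:
        raise OSError(f"cannot write dataset to {out_dir}: {exc}") from exc
    manifest.attrs["root"] = str(out_dir)
    return manifest


def load_dataset(manifest: Path | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Load all image/mask pairs of a manifest into (N,H,W) arrays."""
    if isinstance(manifest, (str, Path)):
        root = Path(manifest).parent
        manifest = pd.read_csv(manifest)
    else:
        root = Path(manifest.attrs.get("root", "."))
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    images, masks = [], []
    for name in manifest["filename"]:
        img, msk = load_pair(root / name, mask_path_for(root / name))
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)
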