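"""Image/mask IO, resizing, augmentation, dataset splitting, and a
synthetic fundus generator with analytically known cup-to-disc ratio.

Masks are three-class label images — 0 background, 1 disc rim, 2 cup —
stored as indexed PNG.  The synthetic generator emulates the photometric
structure the segmentation task relies on: a bright elliptical optic disc
containing a brighter elliptical cup on a darker, vignetted, noisy orange
background crossed by dark vessel-like strokes, with the two anatomical
classes covering only a few percent of the image (the class imbalance the
focal loss addresses).  Because disc and cup are analytic ellipses, the
ground-truth CDR (ratio of vertical semi-axes) is known exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .exceptions import ConfigurationError, ShapeError

BACKGROUND, RIM, CUP = 0, 1, 2
VALID_CODES = (BACKGROUND, RIM, CUP)

_PALETTE = [0, 0, 0, 128, 128, 128, 255, 255, 255] + [0] * (256 - 3) * 3

#: flip set and 14-offset translation grid; combined they expand every
#: image 4 x 14 = 56-fold (50 inputs -> 2,800 training pairs)
DEFAULT_FLIPS = ("none", "horizontal", "vertical", "both")
DEFAULT_TRANSLATIONS = (
    (0, 0),
    (16, 0), (-16, 0), (0, 16), (0, -16),
    (32, 0), (-32, 0), (0, 32), (0, -32),
    (16, 16), (-16, -16), (16, -16), (-16, 16),
    (32, 32),
)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_mask(path, mask: np.ndarray):
    """Write a label mask as single-channel indexed PNG (lossless)."""
    mask = np.asarray(mask)
    _validate_codes(mask)
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(_PALETTE)
    img.save(path, format="PNG")


def load_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ConfigurationError(f"masks must be PNG, got {path.suffix!r}")
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    _validate_codes(arr)
    return arr.astype(np.uint8)


def _validate_codes(mask: np.ndarray):
    codes = np.unique(mask)
    bad = sorted(set(codes.tolist()) - set(VALID_CODES))
    if bad:
        raise ShapeError(f"mask contains invalid class codes {bad}; "
                         f"expected subset of {list(VALID_CODES)}")


def save_image(path, image: np.ndarray):
    """Write a float [0,1] HxWx3 image as 8-bit PNG/JPEG."""
    arr = (np.clip(np.asarray(image), 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return arr.astype(np.float32) / 255.0


def load_pair(image_path, mask_path):
    """Load (image float [0,1] HxWx3, validated label mask)."""
    image = load_image(image_path)
    mask = load_mask(mask_path)
    if image.shape[:2] != mask.shape:
        raise ShapeError(
            f"image size {image.shape[:2]} does not match mask size {mask.shape}")
    return image, mask


# ---------------------------------------------------------------------------
# resizing / augmentation
# ---------------------------------------------------------------------------

def resize_pair(image: np.ndarray, mask: np.ndarray, target: int = 512):
    """Bilinear for the image, nearest-neighbour for the mask (codes kept)."""
    if target <= 0:
        raise ConfigurationError("target size must be positive")
    image_r = _sk_resize(image, (target, target), order=1, mode="reflect",
                         anti_aliasing=image.shape[0] > target,
                         preserve_range=True).astype(np.float32)
    mask_r = _sk_resize(mask, (target, target), order=0, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return image_r, mask_r.round().astype(np.uint8)


@dataclass
class AugmentationSpec:
    flips: tuple = DEFAULT_FLIPS
    translations: tuple = DEFAULT_TRANSLATIONS

    def validate(self, shape):
        if (0, 0) not in tuple(self.translations):
            raise ConfigurationError("translations must include (0, 0)")
        bad = [f for f in self.flips
               if f not in ("none", "horizontal", "vertical", "both")]
        if bad:
            raise ConfigurationError(f"unknown flips {bad}")
        h, w = shape[:2]
        for dx, dy in self.translations:
            if abs(dx) >= w or abs(dy) >= h:
                raise ConfigurationError(
                    f"offset ({dx},{dy}) not smaller than image size {h}x{w}")


def _flip(arr: np.ndarray, mode: str) -> np.ndarray:
    if mode in ("horizontal", "both"):
        arr = arr[:, ::-1]
    if mode in ("vertical", "both"):
        arr = arr[::-1]
    return arr


def _translate(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift by (dx right, dy down), filling vacated pixels with zeros."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec | None = None):
    """Every flip x translation applied identically to image and mask."""
    spec = spec or AugmentationSpec()
    spec.validate(image.shape)
    out = []
    for f in spec.flips:
        fi, fm = _flip(image, f), _flip(mask, f)
        for dx, dy in spec.translations:
            out.append((_translate(fi, dx, dy), _translate(fm, dx, dy)))
    return out


# ---------------------------------------------------------------------------
# synthetic fundus generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    size: int = 512
    disc_semi_axes: tuple = (55.0, 60.0)      # (horizontal a, vertical b) px
    cup_semi_axes: tuple = (22.0, 24.0)
    center_jitter: float = 20.0
    background_level: float = 0.45
    rim_level: float = 0.85
    cup_level: float = 0.97
    noise_sd: float = 0.03
    vessel_curve_count: int = 6
    seed: int = 0

    def validate(self):
        if not (self.cup_semi_axes[0] < self.disc_semi_axes[0]
                and self.cup_semi_axes[1] < self.disc_semi_axes[1]):
            raise ConfigurationError(
                "cup semi-axes must be strictly smaller than disc semi-axes")
        if self.size <= 0 or self.size % 16:
            raise ConfigurationError("size must be a positive multiple of 16")

    @property
    def true_cdr(self) -> float:
        """Analytic CDR of the rasterized image: ratio of the quantized
        vertical semi-axes (see :func:`generate_synthetic`)."""
        return _quantize_semi_axis(self.cup_semi_axes[1]) / _quantize_semi_axis(
            self.disc_semi_axes[1])


def _quantize_semi_axis(b: float) -> float:
    """Nearest half-integer of the form floor(b)+0.5.

    With integer ellipse centres, a vertical semi-axis b = m + 0.5 covers
    exactly the rows centre-m ... centre+m, i.e. a vertical diameter of
    exactly 2b pixels, so the drawn structure has a well-defined analytic
    extent instead of one that flips by a row with sub-pixel placement.
    """
    return np.floor(b) + 0.5


def _ellipse(size, cy, cx, a, b):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def generate_synthetic(config: SyntheticConfig | None = None):
    """Deterministic synthetic fundus image.

    Returns (image HxWx3 float [0,1], label mask, true CDR).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.size
    a_d = _quantize_semi_axis(config.disc_semi_axes[0])
    b_d = _quantize_semi_axis(config.disc_semi_axes[1])
    a_c = _quantize_semi_axis(config.cup_semi_axes[0])
    b_c = _quantize_semi_axis(config.cup_semi_axes[1])
    jitter = config.center_jitter
    cy = round(s / 2 + rng.uniform(-jitter, jitter))
    cx = round(s / 2 + rng.uniform(-jitter, jitter))
    # cup offset inside the disc (nasal shift), kept strictly inside
    off_y = round(rng.uniform(-0.3, 0.3) * (b_d - b_c))
    off_x = round(rng.uniform(-0.3, 0.3) * (a_d - a_c))

    disc = _ellipse(s, cy, cx, a_d, b_d)
    cup = _ellipse(s, cy + off_y, cx + off_x, a_c, b_c)
    if not (cup <= disc).all():
        raise ConfigurationError("cup ellipse is not strictly inside the disc")
    mask = np.zeros((s, s), dtype=np.uint8)
    mask[disc] = RIM
    mask[cup] = CUP

    yy, xx = np.mgrid[0:s, 0:s]
    r2 = ((yy - s / 2) ** 2 + (xx - s / 2) ** 2) / (s / 2) ** 2
    vignette = 1.0 - 0.5 * r2
    lum = config.background_level * vignette
    lum = np.where(disc, config.rim_level, lum)
    lum = np.where(cup, config.cup_level, lum)

    # dark curved vessel strokes: quadratic Bezier polylines radiating from
    # the disc centre
    vessel = np.zeros((s, s), dtype=bool)
    for _ in range(config.vessel_curve_count):
        ang = rng.uniform(0, 2 * np.pi)
        p0 = np.array([cy, cx])
        p2 = p0 + (1.3 * s) * np.array([np.sin(ang), np.cos(ang)])
        p1 = (p0 + p2) / 2 + rng.normal(0, s * 0.12, size=2)
        t = np.linspace(0, 1, 4 * s)[:, None]
        pts = ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2).round().astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < s) & (pts[:, 1] >= 0) & (pts[:, 1] < s)
        pts = pts[ok]
        width = int(rng.integers(1, 3))
        for wy in range(-width, width + 1):
            for wx in range(-width, width + 1):
                y = np.clip(pts[:, 0] + wy, 0, s - 1)
                x = np.clip(pts[:, 1] + wx, 0, s - 1)
                vessel[y, x] = True
    lum = np.where(vessel, lum * 0.45, lum)

    tint = np.array([1.0, 0.55, 0.30])        # fundus orange
    image = lum[..., None] * tint[None, None, :]
    image = image + rng.normal(0, config.noise_sd, size=image.shape)
    return np.clip(image, 0, 1).astype(np.float32), mask, config.true_cdr


@dataclass
class SyntheticSample:
    image: np.ndarray
    mask: np.ndarray
    true_cdr: float
    glaucomatous: int


def make_synthetic_dataset(n: int, seed: int = 0, size: int = 512,
                           glaucoma_fraction: float = 0.25,
                           view: str = "fundus") -> list[SyntheticSample]:
    """A cohort with per-eye CDR drawn from two regimes: normal eyes with
    CDR ~ U(0.30, 0.45) and glaucomatous eyes with CDR ~ U(0.55, 0.80).

    ``view="fundus"`` emulates a whole fundus photograph (disc vertical
    semi-axis ~12% of the image, background > 90% of pixels).
    ``view="roi"`` emulates a disc-centred crop as used by region-of-
    interest segmentation pipelines (disc filling most of the frame).
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * glaucoma_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    out = []
    if view == "fundus":
        scale = size / 512.0        # disc geometry follows the field of view
        base = SyntheticConfig(size=size,
                               disc_semi_axes=(55.0 * scale, 60.0 * scale),
                               cup_semi_axes=(22.0 * scale, 24.0 * scale),
                               center_jitter=20.0 * scale)
    elif view == "roi":
        base = SyntheticConfig(size=size,
                               disc_semi_axes=(0.43 * size, 0.47 * size),
                               cup_semi_axes=(0.17 * size, 0.19 * size),
                               center_jitter=0.16 * size)
    else:
        raise ConfigurationError(f"unknown view {view!r}")
    for i, lab in enumerate(labels):
        ratio = rng.uniform(0.55, 0.80) if lab else rng.uniform(0.30, 0.45)
        b_d = base.disc_semi_axes[1] * rng.uniform(0.9, 1.1)
        a_d = b_d * rng.uniform(0.85, 1.0)
        cfg = replace(base,
                      disc_semi_axes=(a_d, b_d),
                      cup_semi_axes=(a_d * ratio, b_d * ratio),
                      seed=int(rng.integers(0, 2 ** 31 - 1)))
        image, mask, true_cdr = generate_synthetic(cfg)
        out.append(SyntheticSample(image, mask, true_cdr, int(lab)))
    return out


def write_synthetic_dataset(samples, out_dir) -> Path:
    """Write images, masks and a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_path", "mask_path", "glaucoma_label", "true_cdr"])
        for i, s in enumerate(samples):
            ip = out_dir / "images" / f"fundus_{i:04d}.png"
            mp = out_dir / "masks" / f"fundus_{i:04d}.png"
            save_image(ip, s.image)
            save_mask(mp, s.mask)
            w.writerow([str(ip), str(mp), s.glaucomatous, f"{s.true_cdr:.6f}"])
    return manifest


def read_manifest(path):
    """Rows of (image_path, mask_path, label or None)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row.get("glaucoma_label")
            rows.append((row["image_path"], row["mask_path"],
                         int(label) if label not in (None, "") else None))
    return rows


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(items, fractions, seed: int = 0, labels=None):
    """Random (train, val, test) split, stratified when labels are given.

    ``fractions`` must sum to 1; splits are disjoint and exhaustive and
    deterministic per seed.
    """
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ConfigurationError("fractions must be three values summing to 1")
    items = list(items)
    n = len(items)
    rng = np.random.default_rng(seed)
    if labels is None:
        strata = {None: list(range(n))}
    else:
        labels = list(labels)
        if len(labels) != n:
            raise ShapeError("labels length must match items")
        strata = {}
        for i, lab in enumerate(labels):
            strata.setdefault(lab, []).append(i)
        if any(len(v) == 0 for v in strata.values()):
            raise ConfigurationError("empty stratum")
    parts = ([], [], [])
    for lab in sorted(strata, key=str):
        idx = np.array(strata[lab])
        rng.shuffle(idx)
        n_s = len(idx)
        n_train = int(round(fractions[0] * n_s))
        n_val = int(round(fractions[1] * n_s))
        n_val = min(n_val, n_s - n_train)
        cuts = (idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:])
        for p, c in zip(parts, cuts):
            p.extend(int(i) for i in c)
    return tuple([items[i] for i in sorted(p)] for p in parts)


def heldout_test_split(items, labels, n_test_positive: int = 10,
                       n_test_negative: int = 30, seed: int = 0):
    """Draw a fixed-size stratified test set (n positive + n negative) and
    return (rest, test) — the scheme used to carve a screening test set out
    of a training pool."""
    items, labels = list(items), list(labels)
    if len(items) != len(labels):
        raise ShapeError("labels length must match items")
    rng = np.random.default_rng(seed)
    pos = [i for i, l in enumerate(labels) if l]
    neg = [i for i, l in enumerate(labels) if not l]
    if len(pos) < n_test_positive or len(neg) < n_test_negative:
        raise ConfigurationError("not enough items in a stratum for the test draw")
    test = set(rng.choice(pos, n_test_positive, replace=False).tolist()
               + rng.choice(neg, n_test_negative, replace=False).tolist())
    rest = [items[i] for i in range(len(items)) if i not in test]
    test_items = [items[i] for i in sorted(test)]
    return rest, test_items
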