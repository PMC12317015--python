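"""Synthetic HPA-like cell scenes, preprocessing, corruption and scene I/O.

The simulator emulates the structure of Human Protein Atlas confocal data at
desk scale: four fluorescent channels (protein of interest, nucleus,
microtubules, endoplasmic reticulum), 19 multi-label localization classes
with realistic class imbalance (up to 21:1), organelle masks with controlled
volume fractions, and missing-pixel corruption as produced by photobleaching.

Scenes are the universal sample type of the package: every loss, constraint
and training routine consumes :class:`CellScene` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure, transform
import tifffile

CHANNEL_NAMES = ("protein", "nucleus", "microtubule", "er")

#: organelle label codes used throughout the package
LABEL_BACKGROUND = 0
LABEL_NUCLEUS = 1
LABEL_MITOCHONDRIA = 2
LABEL_ER = 3
LABEL_OTHER = 4

ORGANELLE_NAMES = {1: "nucleus", 2: "mitochondria", 3: "er", 4: "other"}

N_CLASSES = 19

#: localization class id -> painter family.  Painting per family (rather than
#: 19 bespoke painters) is sufficient to exercise every loss term.
CLASS_FAMILIES = {
    0: "nuclear", 1: "nuclear", 2: "nuclear", 3: "nuclear", 4: "nuclear",
    5: "nuclear", 11: "nuclear",
    6: "er", 14: "mito",
    7: "punctate", 12: "punctate", 15: "punctate", 17: "punctate",
    8: "cytosolic", 9: "cytosolic", 10: "cytosolic", 16: "cytosolic",
    13: "membrane",
    18: "negative",
}

#: published class percentages of the 19 localization classes, by class id.
#: The dataset is multi-label, so the column sums to 110.0 rather than 100;
#: ClassFrequencyTable normalizes to probabilities.
CLASS_PERCENTAGES = {
    0: 27.4, 1: 2.9, 2: 3.7, 3: 1.4, 4: 2.1, 5: 1.6, 6: 9.4, 7: 4.1,
    8: 1.4, 9: 1.9, 10: 1.8, 11: 1.3, 12: 1.5, 13: 8.6, 14: 12.8,
    15: 1.3, 16: 19.2, 17: 6.3, 18: 1.3,
}


@dataclass
class CellScene:
    """A single synthetic cell sample.

    Attributes
    ----------
    image : (4, H, W) float array in [0, 1]
        Channel order (protein, nucleus, microtubule, ER).
    organelle_labels : (H, W) int array
        Codes: 0 background, 1 nucleus, 2 mitochondria, 3 ER, 4 other.
    cell_mask : (H, W) bool array
        Footprint of the cell.
    class_labels : (19,) binary vector
        Multi-label localization annotation.
    missing_mask : (H, W) bool array
        Pixels zeroed by corruption (all False if uncorrupted).
    """

    image: np.ndarray
    organelle_labels: np.ndarray
    cell_mask: np.ndarray
    class_labels: np.ndarray
    missing_mask: np.ndarray

    def validate(self) -> None:
        if not np.all(np.isfinite(self.image)):
            raise ValueError("scene image contains non-finite values")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("scene image values outside [0, 1]")
        h, w = self.image.shape[1:]
        for name in ("organelle_labels", "cell_mask", "missing_mask"):
            if getattr(self, name).shape != (h, w):
                raise ValueError(f"{name} shape does not match image")
        if np.any((self.organelle_labels != 0) & ~self.cell_mask):
            raise ValueError("organelle labels present outside the cell mask")
        if self.class_labels.shape != (N_CLASSES,):
            raise ValueError("class_labels must have length 19")
        if self.class_labels.sum() < 1 and self.class_labels[18] == 0:
            raise ValueError("class_labels needs >=1 positive entry unless Negative")


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 64
    width: int = 64
    target_volume_fractions: dict = field(
        default_factory=lambda: {"nucleus": 0.175, "mitochondria": 0.125, "er": 0.10}
    )
    target_aspect_ratio: float = 1.8
    localization_class: int = 0
    missing_rate: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if sum(self.target_volume_fractions.values()) >= 1:
            raise ValueError("organelle volume fractions must sum to < 1")
        if self.target_aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1")
        if not 0 <= self.localization_class < N_CLASSES:
            raise ValueError("localization_class must be in 0..18")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class ClassFrequencyTable:
    """Sampling probabilities for the 19 localization classes.

    Defaults to the published class percentages normalized to sum to one.
    """

    probabilities: np.ndarray = field(
        default_factory=lambda: _default_probabilities()
    )

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (N_CLASSES,):
            raise ValueError("need one probability per class (19)")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    def sample(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.choice(N_CLASSES, size=n, p=self.probabilities)


def _default_probabilities() -> np.ndarray:
    p = np.array([CLASS_PERCENTAGES[i] for i in range(N_CLASSES)], dtype=float)
    return p / p.sum()


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _top_n_mask(score: np.ndarray, allowed: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the ``n`` highest-scoring pixels within ``allowed``.

    Ranking a smooth random field gives organic shapes while hitting the pixel
    count exactly, so achieved volume fractions match their targets.
    """
    mask = np.zeros(score.shape, dtype=bool)
    if n <= 0:
        return mask
    flat = np.where(allowed.ravel())[0]
    order = np.argsort(score.ravel()[flat], kind="stable")[::-1]
    mask.ravel()[flat[order[:n]]] = True
    return mask


def generate_scene(spec: SceneSpec) -> CellScene:
    """Render one synthetic 4-channel cell scene.

    Deterministic given ``spec.seed``.  The nucleus is an ellipse, mitochondria
    are blob clusters, and the ER is a reticular (level-set) network; achieved
    organelle area fractions equal their targets exactly by construction.  The
    protein channel is painted per the localization class family, Gaussian
    noise of ``noise_sd`` is added, and the result is clipped to [0, 1].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w].astype(float)

    # cell footprint: tilted ellipse with the target aspect ratio
    theta = rng.uniform(0, np.pi)
    cy = h / 2 + rng.uniform(-h * 0.04, h * 0.04)
    cx = w / 2 + rng.uniform(-w * 0.04, w * 0.04)
    area_target = 0.55 * h * w
    ar = spec.target_aspect_ratio
    b = np.sqrt(area_target / (np.pi * ar))  # minor semi-axis
    a = ar * b
    limit = 0.48 * max(h, w)
    if a > limit:  # shrink isotropically so the target aspect ratio is kept
        b *= limit / a
        a = limit
    dy, dx = rr - cy, cc - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    cell_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cell_area = int(cell_mask.sum())
    if cell_area < 16:
        raise ValueError("image too small to render a cell footprint")

    labels = np.zeros((h, w), dtype=np.int32)

    def _pixels(name, available):
        frac = spec.target_volume_fractions.get(name, 0.0)
        n = int(round(frac * cell_area))
        if frac > 0 and (n < 4 or n > available):
            raise ValueError(f"{name} fraction infeasible for image size")
        return n

    # nucleus: elliptical region grown to the exact pixel count
    n_nuc = _pixels("nucleus", cell_area)
    if n_nuc > 0:
        ny = cy + rng.uniform(-0.15, 0.15) * b
        nx = cx + rng.uniform(-0.15, 0.15) * b
        ndy, ndx = rr - ny, cc - nx
        nu = ndy * np.cos(theta) + ndx * np.sin(theta)
        nv = -ndy * np.sin(theta) + ndx * np.cos(theta)
        nuc_score = -((nu / 1.4) ** 2 + nv ** 2)  # mildly elongated ellipse
        nucleus = _top_n_mask(nuc_score, cell_mask, n_nuc)
        labels[nucleus] = LABEL_NUCLEUS

    cytoplasm = cell_mask & (labels == 0)

    # mitochondria: thresholded smooth noise -> blob clusters, exact count
    n_mito = _pixels("mitochondria", int(cytoplasm.sum()))
    blob_field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    mito = _top_n_mask(blob_field, cytoplasm, n_mito)
    labels[mito] = LABEL_MITOCHONDRIA
    cytoplasm &= labels == 0

    # ER: near-zero level set of a smooth field -> thin reticular network
    n_er = _pixels("er", int(cytoplasm.sum()))
    net_field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    er = _top_n_mask(-np.abs(net_field - np.median(net_field[cell_mask])), cytoplasm, n_er)
    labels[er] = LABEL_ER
    cytoplasm &= labels == 0

    # a small 'other organelle' blob (golgi-like) used by punctate painters
    n_other = int(round(0.03 * cell_area))
    other_field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=2.5)
    other = _top_n_mask(other_field, cytoplasm, min(n_other, int(cytoplasm.sum())))
    labels[other] = LABEL_OTHER

    nucleus = labels == LABEL_NUCLEUS
    texture = 0.5 + 0.5 * (ndimage.gaussian_filter(rng.random((h, w)), 1.0))

    image = np.zeros((4, h, w), dtype=np.float64)
    # nucleus channel (DAPI-like)
    image[1] = 0.75 * nucleus * texture + 0.05 * cell_mask
    # microtubule channel: cytoplasmic filament-like texture
    fil = np.abs(ndimage.gaussian_filter(rng.standard_normal((h, w)), (0.8, 2.5)))
    fil = fil / max(fil.max(), 1e-12)
    image[2] = (0.15 + 0.5 * fil) * (cell_mask & ~nucleus)
    # ER channel
    image[3] = 0.7 * er * texture + 0.08 * (cell_mask & ~nucleus)

    # protein channel per class family
    family = CLASS_FAMILIES[spec.localization_class]
    prot = np.zeros((h, w))
    cyto_all = cell_mask & ~nucleus
    if family == "nuclear":
        prot = 0.7 * nucleus * texture
    elif family == "er":
        prot = 0.7 * er * texture + 0.05 * cyto_all
    elif family == "mito":
        prot = 0.7 * mito * texture + 0.05 * cyto_all
    elif family == "cytosolic":
        prot = 0.5 * cyto_all * texture
    elif family == "membrane":
        ring = cell_mask & ~ndimage.binary_erosion(cell_mask, iterations=2)
        prot = 0.75 * ring + 0.08 * cyto_all
    elif family == "punctate":
        dots = np.zeros((h, w), dtype=bool)
        idx = np.where(cyto_all.ravel())[0]
        if idx.size:
            pick = rng.choice(idx, size=min(max(cell_area // 40, 3), idx.size), replace=False)
            dots.ravel()[pick] = True
            dots = ndimage.binary_dilation(dots, iterations=1)
        prot = 0.8 * (dots & cell_mask) + 0.06 * cyto_all
    elif family == "negative":
        prot = 0.02 * cell_mask

    image[0] = prot
    image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    class_labels = np.zeros(N_CLASSES, dtype=np.int8)
    class_labels[spec.localization_class] = 1

    image, missing = corrupt_missing(image, spec.missing_rate, seed=spec.seed + 1)

    scene = CellScene(
        image=image,
        organelle_labels=labels,
        cell_mask=cell_mask,
        class_labels=class_labels,
        missing_mask=missing,
    )
    scene.validate()
    return scene


def generate_dataset(
    n: int,
    seed: int,
    height: int = 64,
    width: int = 64,
    table: ClassFrequencyTable | None = None,
    missing_rate: float = 0.0,
    noise_sd: float = 0.02,
    base_spec: SceneSpec | None = None,
) -> list[CellScene]:
    """Generate ``n`` scenes with classes drawn from a frequency table."""
    table = table or ClassFrequencyTable()
    classes = table.sample(n, seed)
    base = base_spec or SceneSpec(height=height, width=width,
                                  missing_rate=missing_rate, noise_sd=noise_sd)
    scenes = []
    for i, c in enumerate(classes):
        spec = replace(base, localization_class=int(c), seed=seed + 1000 + i)
        scenes.append(generate_scene(spec))
    return scenes


# ---------------------------------------------------------------------------
# corruption and preprocessing
# ---------------------------------------------------------------------------

def corrupt_missing(image: np.ndarray, rate: float, seed: int):
    """Zero exactly ``round(rate*H*W)`` pixel positions across all channels.

    Models photobleaching-style missing pixels.  Returns the corrupted image
    and the boolean missing mask.
    """
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    img = np.array(image, dtype=float, copy=True)
    h, w = img.shape[-2:]
    mask = np.zeros((h, w), dtype=bool)
    n = int(round(rate * h * w))
    if n > 0:
        rng = np.random.default_rng(seed)
        pick = rng.choice(h * w, size=n, replace=False)
        mask.ravel()[pick] = True
        img[..., mask] = 0.0
    return img, mask


def clahe_enhance(channel: np.ndarray, clip_limit: float = 2.0, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one channel.

    ``clip_limit`` follows the OpenCV convention (multiple of the uniform
    histogram bin height); it is converted to scikit-image's normalized
    convention internally.  Input and output are in [0, 1].
    """
    channel = np.asarray(channel, dtype=float)
    if channel.min() < 0 or channel.max() > 1:
        raise ValueError("channel must be in [0, 1]")
    if np.ptp(channel) < 1e-12:
        return channel.copy()  # degenerate histogram: identity
    nbins = 256
    ksize = (max(channel.shape[0] // tiles, 1), max(channel.shape[1] // tiles, 1))
    out = exposure.equalize_adapthist(
        channel, kernel_size=ksize, clip_limit=clip_limit / nbins, nbins=nbins
    )
    return np.clip(out, 0.0, 1.0)


def extract_patches(image: np.ndarray, size: int = 256, stride: int = 128,
                    boundary: str = "reflect"):
    """Extract a covering grid of square patches.

    Patches start at 0-based (row, col) offsets ``0, stride, 2*stride, ...``
    and the grid extends until the image is covered; content beyond the image
    border is filled by reflection (mirror without edge repetition).  Returns
    ``(patches, offsets)`` with offsets in the original image frame.
    """
    if size < stride:
        raise ValueError("patch size must be >= stride")
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    c, h, w = img.shape

    def starts(n):
        if n <= size:
            return [0]
        k = int(np.ceil((n - size) / stride)) + 1
        return [i * stride for i in range(k)]

    rows, cols = starts(h), starts(w)
    need_h = max(rows[-1] + size - h, 0)
    need_w = max(cols[-1] + size - w, 0)
    padded = np.pad(img, ((0, 0), (0, need_h), (0, need_w)), mode=boundary)

    patches, offsets = [], []
    for r in rows:
        for cpos in cols:
            p = padded[:, r:r + size, cpos:cpos + size]
            patches.append(p[0] if squeeze else p)
            offsets.append((r, cpos))
    return patches, offsets


def reassemble_center(patches, offsets, shape, size: int, stride: int) -> np.ndarray:
    """Reassemble an image from patch centers (interior reconstruction)."""
    first = np.asarray(patches[0])
    squeeze = first.ndim == 2
    c = 1 if squeeze else first.shape[0]
    out = np.zeros((c,) + tuple(shape))
    weight = np.zeros(shape)
    for p, (r, cpos) in zip(patches, offsets):
        p = np.asarray(p, dtype=float)
        if squeeze:
            p = p[None]
        h = min(size, shape[0] - r)
        w = min(size, shape[1] - cpos)
        out[:, r:r + h, cpos:cpos + w] += p[:, :h, :w]
        weight[r:r + h, cpos:cpos + w] += 1
    out /= np.maximum(weight, 1)
    return out[0] if squeeze else out


def augment(image: np.ndarray, seed: int | None = None, rotation_deg: float | None = None,
            flip_h: bool | None = None, flip_v: bool | None = None,
            zoom: float | None = None,
            rotation_range: float = 20.0, zoom_range=(0.8, 1.2)) -> np.ndarray:
    """Geometric augmentation: rotation (±20°), flips, and zoom (0.8–1.2).

    Unspecified parameters are sampled (deterministically from ``seed``);
    explicit parameters are validated against the allowed ranges.  Output
    shape equals input shape (center crop / reflect pad after zoom).
    """
    rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = rng.uniform(-rotation_range, rotation_range)
    if flip_h is None:
        flip_h = bool(rng.random() < 0.5)
    if flip_v is None:
        flip_v = bool(rng.random() < 0.5)
    if zoom is None:
        zoom = rng.uniform(*zoom_range)
    if abs(rotation_deg) > rotation_range + 1e-9:
        raise ValueError(f"rotation {rotation_deg} outside ±{rotation_range}")
    if not zoom_range[0] - 1e-9 <= zoom <= zoom_range[1] + 1e-9:
        raise ValueError(f"zoom {zoom} outside {zoom_range}")

    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    out = []
    for ch in img:
        x = ch
        if flip_h:
            x = x[:, ::-1]
        if flip_v:
            x = x[::-1, :]
        if rotation_deg != 0:
            x = transform.rotate(x, rotation_deg, mode="reflect", preserve_range=True)
        if zoom != 1.0:
            x = _zoom_keep_shape(x, zoom)
        out.append(x)
    res = np.stack(out)
    return res[0] if squeeze else res


def _zoom_keep_shape(ch: np.ndarray, zoom: float) -> np.ndarray:
    h, w = ch.shape
    z = transform.rescale(ch, zoom, preserve_range=True, anti_aliasing=zoom < 1)
    zh, zw = z.shape
    if zoom >= 1.0:  # center crop
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        return z[r0:r0 + h, c0:c0 + w]
    pr, pc = h - zh, w - zw
    top, left = pr // 2, pc // 2
    return np.pad(z, ((top, pr - top), (left, pc - left)), mode="reflect")


# ---------------------------------------------------------------------------
# I/O: float32 multi-page TIFF + JSON sidecar (masks as PNG)
# ---------------------------------------------------------------------------

def write_scene(scene: CellScene, path, lossy_png: bool = False) -> None:
    """Write a scene as ``<path>.tif`` + ``<path>.json`` (+ PNG masks).

    Lossless round trip at float32 precision; ``lossy_png=True`` additionally
    exports an 8-bit PNG of the image, flagged lossy in the sidecar metadata.
    """
    import pathlib

    base = pathlib.Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(base.with_suffix(".tif")), scene.image.astype(np.float32),
                     photometric="minisblack")
    Image.fromarray(scene.organelle_labels.astype(np.uint8)).save(base.parent / (base.stem + "_labels.png"))
    Image.fromarray((scene.cell_mask * 255).astype(np.uint8)).save(base.parent / (base.stem + "_cell.png"))
    Image.fromarray((scene.missing_mask * 255).astype(np.uint8)).save(base.parent / (base.stem + "_missing.png"))
    meta = {
        "class_labels": scene.class_labels.astype(int).tolist(),
        "channels": list(CHANNEL_NAMES),
        "files": {
            "image": base.stem + ".tif",
            "organelle_labels": base.stem + "_labels.png",
            "cell_mask": base.stem + "_cell.png",
            "missing_mask": base.stem + "_missing.png",
        },
        "lossless": True,
    }
    if lossy_png:
        arr = np.clip(scene.image * 255, 0, 255).astype(np.uint8)
        Image.fromarray(np.moveaxis(arr[:3], 0, -1)).save(base.parent / (base.stem + "_preview.png"))
        meta["files"]["preview_png"] = base.stem + "_preview.png"
        meta["preview_lossless"] = False
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_scene(path) -> CellScene:
    """Read a scene written by :func:`write_scene`.

    Raises ``ValueError`` naming the missing sidecar field if malformed.
    """
    import pathlib

    base = pathlib.Path(path)
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    for key in ("class_labels", "files"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field '{key}'")
    for key in ("image", "organelle_labels", "cell_mask", "missing_mask"):
        if key not in meta["files"]:
            raise ValueError(f"sidecar 'files' missing entry '{key}'")
    d = base.parent
    image = tifffile.imread(str(d / meta["files"]["image"])).astype(np.float64)
    labels = np.asarray(Image.open(d / meta["files"]["organelle_labels"]), dtype=np.int32)
    cell = np.asarray(Image.open(d / meta["files"]["cell_mask"])) > 127
    missing = np.asarray(Image.open(d / meta["files"]["missing_mask"])) > 127
    scene = CellScene(
        image=image,
        organelle_labels=labels,
        cell_mask=cell,
        class_labels=np.asarray(meta["class_labels"], dtype=np.int8),
        missing_mask=missing,
    )
    scene.validate()
    return scene
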