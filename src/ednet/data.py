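"""Synthetic seven-class eye-image generation, folder loading and batching.

The generator emulates the class structure of a small ophthalmic photo
collection: seven categories with heavily imbalanced per-class counts
(default 3,451 training and 1,149 test images; e.g. only 24 Bulging_Eyes but
823 Diabetic_retinopathy training images).  Each class gets a distinct
procedural motif drawn on a stylised eye:

* Bulging_Eyes        — enlarged, highly eccentric sclera ellipse
* Cataracts           — pale opacity over the lens/pupil
* Crossed_Eyes        — iris/pupil displaced toward the corner
* Diabetic_retinopathy— scattered small bright lesions on a fundus-like field
* Glaucoma            — enlarged pale inner disc (cupping)
* Uveitis             — inflamed red ring around the iris
* Normal              — clean eye, no motif

A separability knob ``s`` blends each motif with the class-neutral base image
(s=1: full motif contrast; s=0: all classes identical up to noise), and a
noise knob ``sigma`` adds i.i.d. Gaussian pixel noise.  Generation is fully
deterministic given the seed.  These images are synthetic test scaffolding:
they share the *statistical* shape of the task (7 classes, imbalance, RGB
photos), not any clinical appearance.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "ClassLabel",
    "TRAIN_COUNTS",
    "TEST_COUNTS",
    "SyntheticSpec",
    "DatasetManifest",
    "render_eye",
    "generate_synthetic_dataset",
    "load_image_folder",
    "preprocess",
    "batch_iterator",
]

#: fixed project-wide class order
CLASS_NAMES: tuple[str, ...] = (
    "Bulging_Eyes",
    "Cataracts",
    "Crossed_Eyes",
    "Diabetic_retinopathy",
    "Glaucoma",
    "Uveitis",
    "Normal",
)

#: default per-class counts of the emulated dataset (train / test splits)
TRAIN_COUNTS: tuple[int, ...] = (24, 813, 131, 823, 815, 40, 805)
TEST_COUNTS: tuple[int, ...] = (6, 272, 43, 275, 274, 10, 269)


@dataclass(frozen=True)
class ClassLabel:
    """Bijective name <-> index mapping over the fixed seven-class order."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index < len(CLASS_NAMES):
            raise ValueError(f"class index out of range: {self.index}")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.index]

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls(CLASS_NAMES.index(name))
        except ValueError:
            raise ValueError(
                f"unknown class name {name!r}; expected one of {CLASS_NAMES}"
            ) from None


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset.

    Defaults reproduce the emulated collection's per-class train/test counts
    exactly.  ``noise`` is the std-dev of additive Gaussian pixel noise in
    [0,1] units; ``separability`` scales the contrast of each class motif.
    """

    train_counts: tuple[int, ...] = TRAIN_COUNTS
    test_counts: tuple[int, ...] = TEST_COUNTS
    image_size: int = 224
    noise: float = 0.1
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.train_counts = tuple(int(c) for c in self.train_counts)
        self.test_counts = tuple(int(c) for c in self.test_counts)
        if len(self.train_counts) != 7 or len(self.test_counts) != 7:
            raise ValueError("per-class counts must have length 7")
        if any(c < 0 for c in self.train_counts + self.test_counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0,1]")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0,1]")


@dataclass
class DatasetManifest:
    """Records of (path, label, split) with a provenance tag."""

    records: list[tuple[str, ClassLabel, str]] = field(default_factory=list)
    source: str = "synthetic"

    def __len__(self) -> int:
        return len(self.records)

    def split(self, tag: str) -> "DatasetManifest":
        return DatasetManifest(
            [r for r in self.records if r[2] == tag], source=self.source
        )

    def labels(self) -> np.ndarray:
        return np.array([lbl.index for _, lbl, _ in self.records], dtype=np.int64)

    def class_counts(self, tag: str | None = None) -> np.ndarray:
        counts = np.zeros(len(CLASS_NAMES), dtype=np.int64)
        for _, lbl, split in self.records:
            if tag is None or split == tag:
                counts[lbl.index] += 1
        return counts

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(p, lbl.name, s) for p, lbl, s in self.records],
            columns=["path", "label", "split"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str = "folder") -> "DatasetManifest":
        df = pd.read_csv(path)
        records = [
            (row.path, ClassLabel.from_name(row.label), row.split)
            for row in df.itertuples()
        ]
        return cls(records, source=source)

    def validate_files(self) -> None:
        missing = [p for p, _, _ in self.records if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing[:5]}")


# ---------------------------------------------------------------------------
# procedural rendering


def _disc(xx, yy, cx, cy, r, softness=0.02):
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return np.clip((r - d) / softness, 0.0, 1.0)


def _ellipse(xx, yy, cx, cy, rx, ry, softness=0.02):
    d = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    return np.clip((1.0 - d) * (min(rx, ry) / softness), 0.0, 1.0)


def _paint(img, mask, color):
    for c in range(3):
        img[c] = img[c] * (1.0 - mask) + color[c] * mask


def _base_eye(size: int, rng: np.random.Generator) -> np.ndarray:
    """Class-neutral stylised eye on normalized [0,1]^2 coordinates."""
    xx, yy = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size))
    img = np.empty((3, size, size))
    skin = (0.76, 0.60, 0.49)
    for c in range(3):
        img[c] = skin[c] + 0.03 * (yy - 0.5)
    cx = 0.5 + rng.uniform(-0.03, 0.03)
    cy = 0.5 + rng.uniform(-0.03, 0.03)
    _paint(img, _ellipse(xx, yy, cx, cy, 0.34, 0.20), (0.93, 0.92, 0.90))
    _paint(img, _disc(xx, yy, cx, cy, 0.11), (0.35, 0.45, 0.55))
    _paint(img, _disc(xx, yy, cx, cy, 0.045), (0.08, 0.08, 0.08))
    return img, (xx, yy, cx, cy)


def render_eye(
    class_index: int,
    size: int = 224,
    separability: float = 1.0,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one synthetic eye image as a (3, size, size) array in [0,1].

    The class motif is blended with the neutral base with weight
    ``separability``; Gaussian pixel noise of std ``noise`` is added last.
    """
    rng = rng or np.random.default_rng(0)
    base, (xx, yy, cx, cy) = _base_eye(size, rng)
    motif = base.copy()
    name = CLASS_NAMES[class_index]
    if name == "Bulging_Eyes":
        _paint(motif, _ellipse(xx, yy, cx, cy, 0.46, 0.34), (0.95, 0.94, 0.92))
        _paint(motif, _disc(xx, yy, cx, cy, 0.13), (0.35, 0.45, 0.55))
        _paint(motif, _disc(xx, yy, cx, cy, 0.05), (0.08, 0.08, 0.08))
    elif name == "Cataracts":
        _paint(motif, _disc(xx, yy, cx, cy, 0.085, softness=0.05), (0.82, 0.84, 0.85))
    elif name == "Crossed_Eyes":
        dx = 0.14 if rng.random() < 0.5 else -0.14
        _paint(motif, _ellipse(xx, yy, cx, cy, 0.34, 0.20), (0.93, 0.92, 0.90))
        _paint(motif, _disc(xx, yy, cx + dx, cy, 0.11), (0.35, 0.45, 0.55))
        _paint(motif, _disc(xx, yy, cx + dx, cy, 0.045), (0.08, 0.08, 0.08))
    elif name == "Diabetic_retinopathy":
        # fundus-like orange field with small bright lesions
        _paint(motif, np.ones_like(xx) * 0.9, (0.72, 0.35, 0.12))
        _paint(motif, _disc(xx, yy, cx + 0.18, cy, 0.07), (0.95, 0.85, 0.55))
        for _ in range(12):
            lx = cx + rng.uniform(-0.3, 0.3)
            ly = cy + rng.uniform(-0.3, 0.3)
            _paint(motif, _disc(xx, yy, lx, ly, rng.uniform(0.01, 0.025)),
                   (0.95, 0.9, 0.4))
    elif name == "Glaucoma":
        _paint(motif, _disc(xx, yy, cx, cy, 0.10), (0.85, 0.80, 0.60))
        _paint(motif, _disc(xx, yy, cx, cy, 0.05), (0.95, 0.92, 0.75))
    elif name == "Uveitis":
        ring = _disc(xx, yy, cx, cy, 0.17) - _disc(xx, yy, cx, cy, 0.12)
        _paint(motif, np.clip(ring, 0, 1), (0.80, 0.15, 0.12))
    # Normal: motif stays the neutral base
    img = separability * motif + (1.0 - separability) * base
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0)


def _save_png(img: np.ndarray, path: Path) -> None:
    arr = np.round(img * 255.0).astype(np.uint8).transpose(1, 2, 0)
    Image.fromarray(arr, mode="RGB").save(path)


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir) -> DatasetManifest:
    """Write the synthetic dataset as PNGs under ``out_dir/{train,test}/<Class>/``.

    Byte-identical across runs with the same spec (one generator seeded with
    ``spec.seed`` drives everything in a fixed iteration order).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc
    rng = np.random.default_rng(spec.seed)
    records = []
    for split, counts in (("train", spec.train_counts), ("test", spec.test_counts)):
        for ci, count in enumerate(counts):
            cls_dir = out / split / CLASS_NAMES[ci]
            cls_dir.mkdir(parents=True, exist_ok=True)
            for i in range(count):
                img = render_eye(ci, spec.image_size, spec.separability,
                                 spec.noise, rng)
                path = cls_dir / f"{CLASS_NAMES[ci].lower()}_{i:04d}.png"
                _save_png(img, path)
                records.append((str(path), ClassLabel(ci), split))
    return DatasetManifest(records, source="synthetic")


IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def load_image_folder(root) -> DatasetManifest:
    """Manifest a ``root/{train,test}/<ClassName>/*.png|jpg`` directory tree."""
    root = Path(root)
    records = []
    unknown: list[str] = []
    for split in ("train", "test"):
        split_dir = root / split
        if not split_dir.is_dir():
            raise FileNotFoundError(f"expected directory {split_dir}")
        for cls_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
            if cls_dir.name not in CLASS_NAMES:
                unknown.append(str(cls_dir))
                continue
            label = ClassLabel.from_name(cls_dir.name)
            files = sorted(
                p for p in cls_dir.iterdir()
                if p.suffix.lower() in IMAGE_EXTENSIONS
            )
            if not files:
                warnings.warn(f"empty class directory: {cls_dir}", stacklevel=2)
            records.extend((str(p), label, split) for p in files)
    if unknown:
        raise ValueError(f"unknown class directories: {unknown}")
    return DatasetManifest(records, source="folder")


def preprocess(image_file, size: int = 224) -> np.ndarray:
    """Decode, bilinearly resize to ``size`` x ``size``, scale to [0,1] RGB.

    Returns a (3, size, size) float array in channel-first order.
    """
    try:
        with Image.open(image_file) as im:
            im = im.convert("RGB").resize((size, size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot decode image file {image_file}: {exc}") from exc
    return arr.transpose(2, 0, 1)


def batch_iterator(
    manifest: DatasetManifest,
    batch_size: int,
    shuffle_seed: int = 0,
    epoch: int = 0,
    image_size: int = 224,
    cache: dict | None = None,
):
    """Yield (images, labels) minibatches covering every record exactly once.

    The visiting order is a permutation drawn deterministically from
    ``(shuffle_seed, epoch)``; the final short batch is emitted.  ``cache``
    (path -> array) avoids re-decoding files across epochs when provided.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    order = np.random.default_rng((shuffle_seed, epoch)).permutation(len(manifest))
    labels = manifest.labels()
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        imgs = []
        for i in idx:
            path = manifest.records[i][0]
            if cache is not None and path in cache:
                imgs.append(cache[path])
            else:
                arr = preprocess(path, size=image_size).astype(np.float32)
                if cache is not None:
                    cache[path] = arr
                imgs.append(arr)
        yield np.stack(imgs), labels[idx]
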