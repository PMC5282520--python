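"""Synthetic slit-lamp lens ROI generator.

The clinical material this benchmark targets — rectangular crops of the lens
from slit-lamp photographs of children with and without cataract — is not
publicly available. This module generates a labeled stand-in with the two
statistical properties the benchmark exercises:

* controls (negatives) are mutually similar: a smooth elliptical radial
  gradient "lens" on a dark background with a small specular highlight,
  a gentle illumination ramp and low-amplitude sensor noise; their base
  parameters (peak/edge brightness, axes, highlight) jitter across samples
  so no single global statistic separates the classes trivially;
* cataractous lenses (positives) share that base but carry heterogeneous
  opacity: a central nuclear core, radial cortical spokes, signed clouding
  blobs and band-limited noise inside the lens. These raise local intensity
  variance and texture energy and impose spatial structure, while their
  parameters vary more across samples than the negatives' do — mild,
  near-clean cases occur by construction.

``severity`` scales every positive-only component, so ``severity=0`` makes
the two class distributions identical (a chance-level control condition),
while ``severity=1`` gives a clearly separable but noisy task.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["GeneratorConfig", "LabeledImageSet", "generate_dataset", "write_dataset", "read_dataset"]

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the generator.

    Defaults mirror the clinical dataset the benchmark emulates: 476
    cataract-positive and 410 control lens crops. ``severity`` in [0, 1]
    controls class separation; ``positive_heterogeneity`` multiplies the
    across-sample spread of the positive-only opacity parameters.
    """

    n_positive: int = 476
    n_negative: int = 410
    image_height: int = 60
    image_width: int = 90
    severity: float = 1.0
    positive_heterogeneity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("sample counts must be non-negative")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image dimensions must be at least 16x16")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.positive_heterogeneity < 0:
            raise ValueError("positive_heterogeneity must be non-negative")


@dataclass
class LabeledImageSet:
    """RGB images with binary labels (positive=1, negative=0) and stable ids."""

    images: list[np.ndarray]
    labels: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.ids:
            self.ids = [f"sample_{i:04d}" for i in range(len(self.images))]
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValueError("images, labels and ids must have equal length")
        for img in self.images:
            if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
                raise ValueError("images must be HxWx3 uint8 arrays")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            [self.images[i] for i in idx],
            self.labels[idx],
            [self.ids[i] for i in idx],
        )


def _sample_rng(seed: int, label: int, index: int) -> np.random.Generator:
    # one stream per (class, counter): reproducible regardless of generation order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(label, index)))


def _render_sample(cfg: GeneratorConfig, label: int, index: int) -> np.ndarray:
    rng = _sample_rng(cfg.seed, label, index)
    h, w = cfg.image_height, cfg.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # --- base lens, identical distribution for both classes -----------------
    background = rng.normal(18.0, 3.0)
    cy = h / 2 + rng.normal(0.0, 0.02 * h)
    cx = w / 2 + rng.normal(0.0, 0.02 * w)
    ay = rng.uniform(0.28, 0.40) * h
    ax = rng.uniform(0.30, 0.44) * w
    peak = rng.uniform(110.0, 150.0)
    edge = rng.uniform(40.0, 70.0)

    r2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    inside = r2 < 1.0
    rho = np.sqrt(r2)
    profile = np.zeros((h, w))
    profile[inside] = edge + (peak - edge) * (1.0 - r2[inside]) ** 0.7

    img = np.full((h, w), max(background, 0.0))
    img[inside] = profile[inside]

    # gentle illumination ramp across the frame (beam falloff)
    gy, gx = rng.normal(0.0, 4.0), rng.normal(0.0, 4.0)
    img += gy * (yy - h / 2) / h + gx * (xx - w / 2) / w

    # opacity grade: zero for controls; for patients it varies strongly
    # across samples (mild, near-clean cases occur by construction) and is
    # scaled by severity; positive_heterogeneity widens the across-sample
    # spread without shifting the control distribution
    if label == POSITIVE:
        grade = cfg.severity * max(
            0.0, rng.normal(1.0, 0.45 * cfg.positive_heterogeneity)
        )
    else:
        grade = 0.0

    # retroillumination detail: radial iris/fundus striations show through a
    # clear lens and disappear behind dense opacity
    stri_profile = gaussian_filter(rng.normal(size=1440), 8.0, mode="wrap")
    stri_profile /= stri_profile.std()
    angle = np.arctan2((yy - cy) / ay, (xx - cx) / ax)
    idx = ((angle + np.pi) / (2 * np.pi) * 1440).astype(int) % 1440
    striation = stri_profile[idx] * np.clip(rho, 0.15, 1.0)
    visibility = max(0.0, 1.0 - grade)
    img += inside * rng.uniform(8.0, 20.0) * visibility * striation

    # slit beam: a clear lens shows a narrow crisp band; a turbid lens
    # scatters it into a wide dim glow (roughly energy conserving)
    xb = cx + rng.normal(0.0, 3.0)
    beam_width = rng.uniform(5.0, 9.0)
    beam_energy = rng.uniform(300.0, 500.0)
    beam_width *= 1.0 + grade * rng.uniform(2.0, 3.0)
    band = np.exp(-0.5 * ((xx - xb) / beam_width) ** 2)
    img += (inside * 1.0 + (~inside) * 0.25) * (beam_energy / beam_width) * band

    # specular highlight near the lens centre
    sy = cy + rng.normal(0.0, 3.0)
    sx = cx + rng.normal(0.0, 3.0)
    samp = rng.uniform(20.0, 60.0)
    ssig = rng.uniform(1.5, 3.5)
    img += samp * np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * ssig**2))

    # --- positive-only opacity, all components scale with grade -------------
    if label == POSITIVE and grade > 0:
        # veiling glare across the whole pupil
        img += inside * grade * rng.uniform(8.0, 16.0)

        # nuclear core: dense bright clouding at the lens centre
        core_amp = grade * rng.uniform(0.6, 1.4) * 40.0
        core_frac = rng.uniform(0.30, 0.50)
        core_r2 = ((yy - cy) / (core_frac * ay)) ** 2 + ((xx - cx) / (core_frac * ax)) ** 2
        img += core_amp * np.exp(-0.5 * core_r2)

        # signed clouding blobs: local bright/dark patches
        for _ in range(int(rng.integers(3, 9))):
            theta = rng.uniform(0.0, 2 * np.pi)
            brho = 0.8 * np.sqrt(rng.uniform())
            by = cy + brho * ay * np.sin(theta)
            bx = cx + brho * ax * np.cos(theta)
            bamp = grade * rng.uniform(10.0, 25.0) * rng.choice([-1.0, 1.0])
            bsig = rng.uniform(4.0, 8.0)
            img += inside * bamp * np.exp(
                -((yy - by) ** 2 + (xx - bx) ** 2) / (2 * bsig**2)
            )

        # band-limited zero-mean clouding noise
        noise_sd = grade * rng.uniform(8.0, 14.0)
        cloud = gaussian_filter(rng.normal(size=(h, w)), 3.0)
        sd = cloud.std()
        if sd > 0:
            img += inside * cloud * (noise_sd / sd)

        # multiplicative speckle: scattered light modulates the glow
        speckle = gaussian_filter(rng.normal(size=(h, w)), rng.uniform(1.0, 2.0))
        speckle /= speckle.std()
        modulation = np.clip(1.0 + min(1.0, grade) * 0.4 * speckle, 0.05, None)
        img = np.where(inside, img * modulation, img)

    img = gaussian_filter(img, 1.0)
    img += rng.normal(0.0, 2.5, size=(h, w))

    # faint warm tint so the three channels are not redundant
    gains = np.array([1.0, 0.97, 0.90]) + rng.normal(0.0, 0.01, size=3)
    rgb = np.clip(img[..., None] * gains[None, None, :], 0, 255)
    return np.rint(rgb).astype(np.uint8)


def generate_dataset(config: GeneratorConfig) -> LabeledImageSet:
    """Generate a labeled image set; deterministic given ``config`` (incl. seed)."""
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    for i in range(config.n_negative):
        images.append(_render_sample(config, NEGATIVE, i))
        labels.append(NEGATIVE)
        ids.append(f"neg_{i:04d}")
    for i in range(config.n_positive):
        images.append(_render_sample(config, POSITIVE, i))
        labels.append(POSITIVE)
        ids.append(f"pos_{i:04d}")
    return LabeledImageSet(images, np.array(labels, dtype=int), ids)


def write_dataset(image_set: LabeledImageSet, directory: str | Path) -> Path:
    """Write one PNG per image plus a ``manifest.csv`` (id,label,filename).

    Returns the manifest path. PNG is lossless, so a write/read round trip
    reproduces pixel arrays exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    try:
        with manifest.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "label", "filename"])
            for img, label, sample_id in zip(image_set.images, image_set.labels, image_set.ids):
                filename = f"{sample_id}.png"
                Image.fromarray(img, mode="RGB").save(directory / filename)
                writer.writerow([sample_id, int(label), filename])
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return manifest


def read_dataset(directory: str | Path) -> LabeledImageSet:
    """Load a dataset previously written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    images, labels, ids = [], [], []
    with manifest.open(newline="") as fh:
        for row in csv.DictReader(fh):
            with Image.open(directory / row["filename"]) as im:
                images.append(np.asarray(im.convert("RGB"), dtype=np.uint8))
            labels.append(int(row["label"]))
            ids.append(row["id"])
    return LabeledImageSet(images, np.array(labels, dtype=int), ids)
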