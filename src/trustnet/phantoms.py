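"""Synthetic head-phantom generation, persistence, and loading.

The phantoms stand in for axial non-contrast head CT slices: a bright
skull annulus surrounds textured parenchyma, and the stroke class carries a
single smooth-edged hypodense blob (the CT appearance of an ischemic
infarct).  Lesion contrast, size, texture, and noise are configurable so a
generated dataset contains both obvious and genuinely ambiguous cases —
which is what gives the downstream uncertainty and explainability stages
something to do.

Images are float arrays in [0, 1].  Datasets are persisted as 8-bit PNG
files plus a lossless ``arrays.npz`` bundle (bit-exact round trips), with a
CSV manifest and a JSON sidecar of generation parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import DataError, IntegrityError, ParameterError

STROKE = "stroke"
NORMAL = "normal"
LABELS = (STROKE, NORMAL)  # stroke is class index 0, the positive class
SPLITS = ("train", "validation", "test")

_MANIFEST_NAME = "manifest.csv"
_PARAMS_NAME = "params.json"
_ARRAYS_NAME = "arrays.npz"


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for a single phantom.

    Parameters
    ----------
    image_size:
        Pixels per side (square image).  224 matches the sizing the
        architecture was designed around; smaller values (e.g. 96 or 48)
        are fine because the network pools adaptively.
    lesion_contrast:
        Intensity decrement of the hypodense lesion, in [0.02, 0.3].
        Values near 0.2 are obvious; values near 0.03 are near the noise
        floor and produce ambiguous cases.
    lesion_radius_frac:
        Lesion radius as a fraction of the brain radius, in (0, 0.5].
    noise_sigma:
        Std of additive Gaussian pixel noise, in [0, 0.1].
    texture_scale:
        Smoothing length (pixels) of the parenchymal random field.
    seed:
        RNG seed; identical params + seed give bit-identical phantoms.
    """

    image_size: int = 224
    lesion_contrast: float = 0.2
    lesion_radius_frac: float = 0.25
    noise_sigma: float = 0.03
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ParameterError(f"image_size must be >= 16, got {self.image_size}")
        if not 0.02 <= self.lesion_contrast <= 0.3:
            raise ParameterError(
                f"lesion_contrast must be in [0.02, 0.3], got {self.lesion_contrast}"
            )
        if not 0.0 < self.lesion_radius_frac <= 0.5:
            raise ParameterError(
                f"lesion_radius_frac must be in (0, 0.5], got {self.lesion_radius_frac}"
            )
        if not 0.0 <= self.noise_sigma <= 0.1:
            raise ParameterError(
                f"noise_sigma must be in [0, 0.1], got {self.noise_sigma}"
            )
        if self.texture_scale <= 0:
            raise ParameterError("texture_scale must be positive")


@dataclass
class LabeledImage:
    """A grayscale image in [0, 1] with its label and (synthetic) lesion mask."""

    pixels: np.ndarray
    label: str
    lesion_mask: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ParameterError("pixels must lie in [0, 1]")
        if self.label == NORMAL and self.lesion_mask.any():
            raise ParameterError("normal images must carry an all-zero lesion mask")


@dataclass(frozen=True)
class DifficultyLevel:
    """One component of the difficulty mix: a weight and a contrast range."""

    weight: float
    contrast_range: tuple[float, float]
    name: str = ""


#: 60% easy (obvious lesions), 40% hard (near the noise floor) — guarantees
#: both confident and uncertain predictions so the rejection and flip rules
#: are exercised.
DEFAULT_DIFFICULTY_MIX = (
    DifficultyLevel(weight=0.6, contrast_range=(0.15, 0.25), name="easy"),
    DifficultyLevel(weight=0.4, contrast_range=(0.03, 0.08), name="hard"),
)

EASY_ONLY_MIX = (DifficultyLevel(weight=1.0, contrast_range=(0.15, 0.25), name="easy"),)


@dataclass
class DatasetManifest:
    """Rows of (source_id, path, label, split) plus generation provenance."""

    frame: pd.DataFrame
    params: dict
    seed: int

    def __post_init__(self) -> None:
        required = {"source_id", "path", "label", "split"}
        if not required.issubset(self.frame.columns):
            raise DataError(f"manifest frame must have columns {sorted(required)}")
        if self.frame["path"].duplicated().any():
            raise DataError("manifest paths must be unique")

    def split_ids(self, split: str) -> list[str]:
        return self.frame.loc[self.frame["split"] == split, "source_id"].tolist()

    def label_counts(self) -> pd.DataFrame:
        return self.frame.groupby(["split", "label"]).size().unstack(fill_value=0)


@dataclass
class PhantomDataset:
    """A manifest together with its in-memory images."""

    manifest: DatasetManifest
    images: dict[str, LabeledImage]

    def split(self, name: str) -> list[LabeledImage]:
        return [self.images[sid] for sid in self.manifest.split_ids(name)]


def _head_geometry(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Radial coordinate grid plus brain / skull masks for a centred head."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy - c, xx - c)
    brain_r = 0.40 * size
    brain = rr <= brain_r
    skull = (rr > brain_r) & (rr <= brain_r + 0.06 * size)
    return rr, brain, skull, brain_r


def generate_phantom(params: PhantomParams, label: str) -> LabeledImage:
    """Generate one synthetic head phantom.

    The same ``(params, label)`` pair is bit-reproducible.  A stroke phantom
    and a normal phantom generated from the *same* params share every draw
    (texture, lesion geometry, noise); they differ only by the lesion
    subtraction, so they form a matched pair for contrast checks.
    """
    if label not in LABELS:
        raise ParameterError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    rr, brain, skull, brain_r = _head_geometry(size)

    img = np.full((size, size), 0.05, dtype=np.float64)  # air background
    img[skull] = 0.95
    base = 0.5
    texture = gaussian_filter(rng.standard_normal((size, size)), params.texture_scale)
    std = texture.std()
    if std > 0:
        texture *= 0.03 / std
    img[brain] = np.clip(base + texture[brain], 0.4, 0.6)

    # Lesion geometry is drawn unconditionally so the RNG stream is label
    # independent (matched stroke/normal pairs share every other draw).
    lesion_r = params.lesion_radius_frac * brain_r
    edge_sigma = max(1.0, 0.15 * lesion_r)
    margin = lesion_r + 2.0 * edge_sigma + 2.0
    theta = rng.uniform(0.0, 2.0 * np.pi)
    max_d = max(brain_r - margin, 0.0)
    d = rng.uniform(0.0, max_d)
    c = (size - 1) / 2.0
    ly, lx = c + d * np.sin(theta), c + d * np.cos(theta)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - ly, xx - lx)
    mask = (dist <= lesion_r).astype(np.uint8)

    if label == STROKE:
        # Dilate the disk by 2*sigma before blurring so that inside the
        # binary mask the soft profile is ~1: the mean decrement within the
        # mask then matches lesion_contrast to within ~1%.
        soft = gaussian_filter((dist <= lesion_r + 2.0 * edge_sigma).astype(np.float64),
                               edge_sigma)
        m = soft.max()
        if m > 0:
            soft /= m
        img -= params.lesion_contrast * soft * brain
    else:
        mask = np.zeros_like(mask)

    if params.noise_sigma > 0:
        img += params.noise_sigma * rng.standard_normal((size, size))
    img = np.clip(img, 0.0, 1.0)

    source_id = f"phantom-s{params.seed}-{label}"
    return LabeledImage(pixels=img, label=label, lesion_mask=mask, source_id=source_id)


def _allocate_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to fractions summing to 1."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # biggest deficit first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def generate_dataset(
    n: int,
    stroke_fraction: float = 0.5,
    difficulty_mix: Sequence[DifficultyLevel] = DEFAULT_DIFFICULTY_MIX,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    image_size: int = 96,
    noise_sigma: float = 0.03,
    lesion_radius_frac: float = 0.25,
    texture_scale: float = 4.0,
) -> PhantomDataset:
    """Generate a labelled, split phantom dataset.

    Exactly ``round(n * stroke_fraction)`` images are stroke; splits are
    disjoint and stratified by label.  Everything is reproducible from
    ``seed``.
    """
    if n < 4:
        raise DataError(f"need n >= 4 to populate every split, got {n}")
    if not 0 < stroke_fraction < 1:
        raise ParameterError("stroke_fraction must be in (0, 1)")
    if len(split_fractions) != 3 or any(not 0 < f < 1 for f in split_fractions):
        raise ParameterError("split_fractions must be three values in (0, 1)")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ParameterError("split_fractions must sum to 1")
    weights = np.array([lvl.weight for lvl in difficulty_mix], dtype=float)
    if weights.sum() <= 0:
        raise ParameterError("difficulty mix weights must sum to a positive value")
    weights = weights / weights.sum()

    n_stroke = int(round(n * stroke_fraction))
    labels = [STROKE] * n_stroke + [NORMAL] * (n - n_stroke)

    rng = np.random.default_rng(seed)
    rows = []
    images: dict[str, LabeledImage] = {}
    # Split sizes follow the fractions globally (largest remainder); within
    # that, labels are spread across splits as evenly as the counts allow.
    global_counts = _allocate_counts(n, split_fractions)
    if any(c == 0 for c in global_counts):
        raise DataError(f"n={n} too small to populate every split {SPLITS}")
    idx_stroke = [i for i, l in enumerate(labels) if l == STROKE]
    idx_normal = [i for i, l in enumerate(labels) if l == NORMAL]
    rng.shuffle(idx_stroke)
    rng.shuffle(idx_normal)
    counts_stroke = _allocate_counts(len(idx_stroke), split_fractions)
    counts_normal = [g - s for g, s in zip(global_counts, counts_stroke)]
    # Repair any negative slot by borrowing from the largest surplus split.
    for k, c in enumerate(counts_normal):
        while counts_normal[k] < 0:
            j = int(np.argmax(counts_normal))
            counts_normal[j] -= 1
            counts_stroke[j] += 1
            counts_stroke[k] -= 1
            counts_normal[k] += 1
    split_assignment: dict[int, str] = {}
    for idx, counts in ((idx_stroke, counts_stroke), (idx_normal, counts_normal)):
        pos = 0
        for split_name, cnt in zip(SPLITS, counts):
            for i in idx[pos:pos + cnt]:
                split_assignment[i] = split_name
            pos += cnt

    for i, lab in enumerate(labels):
        level = difficulty_mix[int(rng.choice(len(difficulty_mix), p=weights))]
        lo, hi = level.contrast_range
        contrast = float(rng.uniform(lo, hi))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = PhantomParams(
            image_size=image_size,
            lesion_contrast=contrast,
            lesion_radius_frac=lesion_radius_frac,
            noise_sigma=noise_sigma,
            texture_scale=texture_scale,
            seed=sub_seed,
        )
        img = generate_phantom(params, lab)
        img.source_id = f"phantom-{i:05d}-{lab}"
        rows.append(
            {
                "source_id": img.source_id,
                "path": f"images/{img.source_id}.png",
                "label": lab,
                "split": split_assignment[i],
            }
        )
        images[img.source_id] = img

    params_record = {
        "n": n,
        "stroke_fraction": stroke_fraction,
        "difficulty_mix": [dataclasses.asdict(lvl) for lvl in difficulty_mix],
        "split_fractions": list(split_fractions),
        "image_size": image_size,
        "noise_sigma": noise_sigma,
        "lesion_radius_frac": lesion_radius_frac,
        "texture_scale": texture_scale,
        "seed": seed,
    }
    manifest = DatasetManifest(frame=pd.DataFrame(rows), params=params_record, seed=seed)
    return PhantomDataset(manifest=manifest, images=images)


def persist_dataset(dataset: PhantomDataset, directory: str | Path) -> Path:
    """Write manifest CSV, params JSON, 8-bit PNGs, and a lossless npz bundle."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest
    manifest.frame.to_csv(directory / _MANIFEST_NAME, index=False)
    with open(directory / _PARAMS_NAME, "w") as fh:
        json.dump(manifest.params, fh, indent=2)
    arrays: dict[str, np.ndarray] = {}
    for sid, img in dataset.images.items():
        png = Image.fromarray(np.round(img.pixels * 255).astype(np.uint8))
        png.save(directory / "images" / f"{sid}.png")
        arrays[f"pixels/{sid}"] = img.pixels
        arrays[f"mask/{sid}"] = img.lesion_mask
    np.savez_compressed(directory / _ARRAYS_NAME, **arrays)
    return directory


def load_dataset(directory: str | Path) -> PhantomDataset:
    """Round-trip loader; prefers the lossless npz bundle over the PNGs."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    frame = pd.read_csv(manifest_path)
    with open(directory / _PARAMS_NAME) as fh:
        params = json.load(fh)
    manifest = DatasetManifest(frame=frame, params=params, seed=int(params["seed"]))

    bundle = None
    if (directory / _ARRAYS_NAME).exists():
        bundle = np.load(directory / _ARRAYS_NAME)
    images: dict[str, LabeledImage] = {}
    for row in frame.itertuples():
        png_path = directory / row.path
        if not png_path.exists():
            raise IntegrityError(f"image file missing for manifest row: {row.path}")
        if bundle is not None and f"pixels/{row.source_id}" in bundle:
            pixels = bundle[f"pixels/{row.source_id}"]
            mask = bundle[f"mask/{row.source_id}"]
        else:
            pixels = np.asarray(Image.open(png_path), dtype=np.float64) / 255.0
            mask = np.zeros_like(pixels, dtype=np.uint8)
        images[row.source_id] = LabeledImage(
            pixels=pixels, label=row.label, lesion_mask=mask, source_id=row.source_id
        )
    return PhantomDataset(manifest=manifest, images=images)
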