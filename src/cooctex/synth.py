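"""Seeded synthetic texture generator.

Emulates the contrasts that separate tissue classes in B-mode ultrasound
patches: echogenicity (mean grey level), granularity (spatial correlation
length) and regularity (periodic structure vs smooth correlated fields vs
high-entropy chaotic textures with bright/dark spots).  An optional
multiplicative log-normal factor imitates speckle.  Everything is
deterministic under a fixed seed, so every stage of the pipeline is testable
without external data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ValidationError
from .image_prep import MANIFEST_COLUMNS

__all__ = ["TextureRecipe", "generate_roi", "generate_dataset", "default_recipes"]

_REGULARITIES = ("periodic", "smooth", "chaotic")

#: Amplitude of the sinusoidal grating for periodic recipes (grey levels).
PERIODIC_AMPLITUDE = 40.0
#: Grey-level offset applied by a chaotic bright/dark spot.
SPOT_AMPLITUDE = 80.0
#: Log-sigma of the multiplicative speckle factor.
SPECKLE_SIGMA = 0.1


@dataclasses.dataclass(frozen=True)
class TextureRecipe:
    """Parameters of one texture class.

    ``correlation_length`` is the grating period (periodic) or the Gaussian
    smoothing length (smooth) in pixels; ``spot_rate`` is bright/dark spots
    per 1000 pixels (chaotic only); ``noise_sigma`` the additive noise level
    in grey levels.
    """

    class_name: str
    mean_level: float = 120.0
    correlation_length: float = 6.0
    regularity: str = "smooth"
    spot_rate: float = 0.0
    noise_sigma: float = 10.0
    speckle: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.mean_level <= 255:
            raise ValidationError(f"mean_level {self.mean_level} outside [0, 255]")
        if self.regularity not in _REGULARITIES:
            raise ValidationError(
                f"regularity {self.regularity!r} not in {_REGULARITIES}"
            )
        if self.correlation_length <= 0:
            raise ValidationError("correlation_length must be positive")
        if self.spot_rate < 0 or self.noise_sigma < 0:
            raise ValidationError("spot_rate and noise_sigma must be >= 0")
        if not self.class_name:
            raise ValidationError("class_name must be nonempty")


def generate_roi(recipe: TextureRecipe, size: int = 50) -> np.ndarray:
    """Generate one ``size`` x ``size`` 8-bit ROI from a recipe (seeded)."""
    recipe.validate()
    if size < 16:
        raise ValidationError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng(recipe.seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    if recipe.regularity == "periodic":
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        period = max(2.0, recipe.correlation_length)
        wave = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / period + phase)
        base = recipe.mean_level + PERIODIC_AMPLITUDE * wave
        base += rng.normal(0.0, recipe.noise_sigma, (size, size))
    elif recipe.regularity == "smooth":
        field = rng.normal(0.0, 1.0, (size, size))
        field = ndimage.gaussian_filter(field, recipe.correlation_length, mode="reflect")
        field -= field.mean()  # keep echogenicity at mean_level
        sd = field.std()
        if sd > 0:
            field /= sd
        base = recipe.mean_level + recipe.noise_sigma * field
    else:  # chaotic: i.i.d. noise plus random bright/dark spots
        base = recipe.mean_level + rng.normal(0.0, recipe.noise_sigma, (size, size))
        n_spots = int(round(recipe.spot_rate * size * size / 1000.0))
        for _ in range(n_spots):
            y = int(rng.integers(0, size - 1))
            x = int(rng.integers(0, size - 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            base[y : y + 2, x : x + 2] += sign * SPOT_AMPLITUDE

    if recipe.speckle:
        # unit-mean log-normal factor so echogenicity is preserved
        factor = rng.lognormal(0.0, SPECKLE_SIGMA, (size, size))
        base = base * factor / np.exp(SPECKLE_SIGMA**2 / 2)

    return np.clip(np.rint(base), 0, 255).astype(np.uint8)


def default_recipes() -> list[TextureRecipe]:
    """The two stock texture classes used by the demonstration pipeline.

    A darker regular (periodic) texture versus a brighter chaotic one:
    well-separated in echogenicity (mean difference 60 grey levels) and in
    regularity, with speckle enabled on both.
    """
    return [
        TextureRecipe(
            class_name="regular",
            mean_level=90.0,
            correlation_length=8.0,
            regularity="periodic",
            spot_rate=0.0,
            noise_sigma=5.0,
            speckle=True,
        ),
        TextureRecipe(
            class_name="chaotic",
            mean_level=150.0,
            correlation_length=1.0,
            regularity="chaotic",
            spot_rate=8.0,
            noise_sigma=40.0,
            speckle=True,
        ),
    ]


def generate_dataset(
    recipes,
    n_per_class: int,
    size: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Generate a balanced labelled ROI collection, optionally written to disk.

    Per-image seeds are derived deterministically from the master seed via a
    numpy SeedSequence, so the dataset is byte-identical across runs.  Returns
    ``(images, labels, manifest)`` where the manifest is a DataFrame in the
    standard ROI-manifest layout; when ``out_dir`` is given the PNGs and
    ``manifest.csv`` are written there.
    """
    recipes = list(recipes)
    if len(recipes) < 2:
        raise ValidationError("need at least 2 recipes")
    if n_per_class < 2:
        raise ValidationError("n_per_class must be >= 2")
    for r in recipes:
        r.validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(recipes) * n_per_class)

    images: list[np.ndarray] = []
    labels: list[str] = []
    rows = []
    idx = 0
    for recipe in recipes:
        for i in range(n_per_class):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            roi = generate_roi(dataclasses.replace(recipe, seed=child_seed), size=size)
            images.append(roi)
            labels.append(recipe.class_name)
            rows.append(
                {
                    "image_path": f"{recipe.class_name}_{i:04d}.png",
                    "x0": 0,
                    "y0": 0,
                    "width": size,
                    "height": size,
                    "class_label": recipe.class_name,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, manifest.itertuples(index=False)):
            Image.fromarray(img, mode="L").save(out_dir / row.image_path)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, labels, manifest
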