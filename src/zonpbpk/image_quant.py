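"""Stained-area quantification of liver lobule images.

Immunostaining sections contain three visually separable pixel classes:
stained tissue, unstained tissue and vessel lumen (no tissue).  Pixels are
labelled by explicit per-image intensity thresholds (an audit record of the
thresholds used is kept on every label image), and the expressed-area
percentage of an enzyme is the arithmetic mean over images of the stained
fraction of tissue pixels:

    p_e = (1/M_e) * sum_i  n_i_stained / (n_i_stained + n_i_unstained)

H&E sections are quantified identically with classes dead / viable / lumen,
yielding the dead-area fraction d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabelImage",
    "ExpressionQuant",
    "DEFAULT_THRESHOLDS",
    "classify_pixels",
    "quantify_expression",
    "quantify_dead_area",
]

#: Intensity conventions of the bundled synthetic images: dark = chromogen /
#: eosinophilic dead tissue, mid = unstained viable tissue, bright = lumen.
DEFAULT_THRESHOLDS: dict[str, float] = {"stain_max": 110.0, "lumen_min": 220.0}

# label codes
STAINED, UNSTAINED, NO_TISSUE = 0, 1, 2


@dataclass
class LabelImage:
    """Per-pixel three-class labelling with its audit record."""

    labels: np.ndarray  # int8 array of {0: stained/dead, 1: unstained/viable, 2: no tissue}
    source: str
    thresholds: dict[str, float]
    class_names: tuple[str, str, str] = ("stained_tissue", "unstained_tissue", "no_tissue")

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.isin(lab, (STAINED, UNSTAINED, NO_TISSUE)).all():
            raise ValueError("labels must be a 2-D array of class codes {0, 1, 2}")
        self.labels = lab.astype(np.int8)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in enumerate(self.class_names)
        }

    @property
    def tissue_pixels(self) -> int:
        return int(np.count_nonzero(self.labels != NO_TISSUE))

    @property
    def stained_fraction(self) -> float:
        """Stained share of tissue pixels; NaN for tissue-free images."""
        tissue = self.tissue_pixels
        if tissue == 0:
            return float("nan")
        return float(np.count_nonzero(self.labels == STAINED) / tissue)


@dataclass
class ExpressionQuant:
    """Eq.-style expressed-area summary for one enzyme."""

    enzyme: str
    per_image_fraction: tuple[float, ...]
    p_e: float
    sd: float
    n_images: int
    n_excluded: int = 0


def classify_pixels(
    image: np.ndarray | str | Path,
    thresholds: Mapping[str, float] | None = None,
    channel: int | None = None,
) -> LabelImage:
    """Deterministic three-class labelling of a raster image.

    ``thresholds`` must provide ``stain_max`` (chromogen intensity at or
    below which tissue counts as stained) and ``lumen_min`` (intensity at or
    above which a pixel is vessel lumen).  Multi-channel images are reduced
    to the configured ``channel`` (required for colour input).
    """
    source = "<array>"
    if isinstance(image, (str, Path)):
        source = str(image)
        try:
            import imageio.v3 as iio

            image = iio.imread(image)
        except FileNotFoundError:
            raise FileNotFoundError(f"unreadable image file: {source}") from None
        except Exception as exc:
            raise ValueError(f"unreadable image file: {source}: {exc}") from exc
    arr = np.asarray(image)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(f"{source}: colour image needs an explicit channel")
        arr = arr[..., channel]
    if arr.ndim != 2:
        raise ValueError(f"{source}: expected a 2-D image, got shape {arr.shape}")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update({k: float(v) for k, v in thresholds.items()})
    if th["stain_max"] >= th["lumen_min"]:
        raise ValueError("stain_max must lie below lumen_min")
    arr = arr.astype(float)
    labels = np.full(arr.shape, UNSTAINED, dtype=np.int8)
    labels[arr <= th["stain_max"]] = STAINED
    labels[arr >= th["lumen_min"]] = NO_TISSUE
    return LabelImage(labels=labels, source=source, thresholds=th)


def _mean_fraction(labels: Sequence[LabelImage], what: str) -> tuple[list[float], int]:
    if not labels:
        raise ValueError("need at least one label image")
    fractions = []
    excluded = 0
    for img in labels:
        f = img.stained_fraction
        if np.isnan(f):
            warnings.warn(f"{img.source}: no tissue pixels; image excluded from {what}",
                          stacklevel=3)
            excluded += 1
        else:
            fractions.append(f)
    if not fractions:
        raise ValueError(f"all images excluded from {what}: no tissue pixels anywhere")
    return fractions, excluded


def quantify_expression(labels: Sequence[LabelImage], enzyme: str) -> ExpressionQuant:
    """Mean expressed-area fraction p_e over the images of one enzyme."""
    fractions, excluded = _mean_fraction(labels, f"expression of {enzyme}")
    arr = np.asarray(fractions)
    return ExpressionQuant(
        enzyme=enzyme,
        per_image_fraction=tuple(fractions),
        p_e=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_images=len(fractions),
        n_excluded=excluded,
    )


def quantify_dead_area(he_labels: Sequence[LabelImage]) -> float:
    """Mean dead fraction d = dead/(dead+viable) over H&E label images."""
    fractions, _ = _mean_fraction(he_labels, "dead-area quantification")
    return float(np.mean(fractions))
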