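"""Synthetic study data: three-site PK datasets and lobule staining images.

The PK generator emulates the cocktail study design: concentrations at the
right heart chamber, portal vein and hepatic vein, sampled destructively at
2, 15, 30, 60 and 120 min with three animals per time point, corrupted by
multiplicative log-normal noise of a chosen coefficient of variation
(median-unbiased: the noise factor is exp(sigma * Z) with
sigma^2 = ln(1 + CV^2)).

The image generator draws idealized lobule sections: a bright central-vein
lumen, a dark stained (or, in H&E mode, dead) region growing concentrically
around it - mirroring the pericentral geometry of both CYP expression and
the CCl4 lesion - and mid-grey unstained tissue elsewhere.  Ground-truth
pixel counts accompany every image, and the realized stained fraction of
each image set stays within one percentage point of the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundModel, dose_in_amount
from .fitting import DESIGN_TIMES, PKDataset, _design_grid
from .image_quant import NO_TISSUE, STAINED, UNSTAINED, DEFAULT_THRESHOLDS, LabelImage
from .physiology import MousePhysiology, build_default_physiology
from .simulator import SITES, DoseEvent, sample_site, simulate

__all__ = [
    "PKGeneratorSpec",
    "StainGeneratorSpec",
    "generate_pk_dataset",
    "generate_stain_images",
]


@dataclass
class PKGeneratorSpec:
    """Ground-truth model plus the sampling design and noise level."""

    models: Sequence[CompoundModel]
    physiology: MousePhysiology = field(default_factory=build_default_physiology)
    times: tuple[float, ...] = DESIGN_TIMES
    sites: tuple[str, ...] = SITES
    replicates: int = 3
    cv: float = 0.2  # assay + animal coefficient of variation
    lloq: dict[str, float] = field(default_factory=dict)
    destructive_sampling: bool = True  # each replicate is an independent animal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_pk_dataset(spec: PKGeneratorSpec, damage: float = 0.0) -> PKDataset:
    """Simulate the (possibly damaged) model and draw noisy observations.

    ``damage`` multiplies every hepatic enzyme/transporter abundance of the
    family by (1 - damage) before simulating.  The ground truth (damage, CV,
    seed, noiseless curves) is bundled in the dataset metadata so recovery
    experiments can close the loop.
    """
    models = [m.with_liver_damage(damage) for m in spec.models]
    doses = [
        DoseEvent(m.name, 0.0, dose_in_amount(m, spec.physiology.body_weight))
        for m in models
        if m.dose_per_kg is not None
    ]
    res = simulate(
        spec.physiology,
        models,
        doses,
        horizon=max(spec.times),
        grid=_design_grid(spec.times),
    )
    t_index = {t: int(np.argmin(np.abs(res.times - t))) for t in spec.times}
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    rows = []
    truth = {}
    for name in res.species:
        for site in spec.sites:
            series = sample_site(res, site, name)
            for t in spec.times:
                value = float(series[t_index[t]])
                truth[(name, site, float(t))] = value
                noise = rng.standard_normal(spec.replicates) if spec.cv > 0 else np.zeros(spec.replicates)
                for r in range(spec.replicates):
                    rows.append(
                        {
                            "compound": name,
                            "site": site,
                            "time_min": float(t),
                            "replicate": r,
                            "conc_umol_per_L": value * float(np.exp(sigma * noise[r])),
                        }
                    )
    records = pd.DataFrame(rows)
    return PKDataset(
        records=records,
        lloq=dict(spec.lloq),
        metadata={
            "true_damage": damage,
            "cv": spec.cv,
            "seed": spec.seed,
            "destructive_sampling": spec.destructive_sampling,
            "true_cells": truth,
        },
    )


@dataclass
class StainGeneratorSpec:
    """Geometry, targets and noise of the synthetic lobule images."""

    target_stained_fraction: float  # stained (IHC) or dead (H&E) share of tissue
    image_size: int = 128
    lumen_radius_fraction: float = 0.10  # central-vein radius relative to image size
    target_jitter: float = 0.005  # per-image SD of the realized target fraction
    intensity_noise: float = 8.0  # grey-level SD within a class band
    mode: str = "ihc"  # "ihc" (stained/unstained) or "he" (dead/viable)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_stained_fraction <= 1:
            raise ValueError("target fraction must lie in [0, 1]")
        if self.mode not in ("ihc", "he"):
            raise ValueError("mode must be 'ihc' or 'he'")
        if self.image_size < 16:
            raise ValueError("image too small for the lobule geometry")


_CLASS_NAMES = {
    "ihc": ("stained_tissue", "unstained_tissue", "no_tissue"),
    "he": ("dead_tissue", "viable_tissue", "no_tissue"),
}


def generate_stain_images(
    spec: StainGeneratorSpec, n: int
) -> tuple[list[np.ndarray], list[dict]]:
    """Draw ``n`` synthetic lobule images plus exact ground-truth counts.

    Returns 8-bit grayscale images (dark = stained/dead, mid = unstained
    viable tissue, bright = lumen) and, per image, the ground-truth class
    mask and pixel counts.  The stained region is the set of tissue pixels
    nearest the central vein, so any target fraction in [0, 1] is feasible
    to within a single pixel.
    """
    if n < 1:
        raise ValueError("need n >= 1 images")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    center = (size - 1) / 2.0
    dist = np.hypot(yy - center, xx - center)
    lumen = dist <= spec.lumen_radius_fraction * size
    tissue_order = np.argsort(dist[~lumen].ravel(), kind="stable")
    flat_tissue_idx = np.flatnonzero(~lumen.ravel())[tissue_order]

    images, truths = [], []
    for _ in range(n):
        target = float(np.clip(
            spec.target_stained_fraction + rng.normal(0.0, spec.target_jitter),
            0.0, 1.0,
        ))
        n_tissue = flat_tissue_idx.size
        k = int(round(target * n_tissue))
        labels = np.full(size * size, UNSTAINED, dtype=np.int8)
        labels[lumen.ravel()] = NO_TISSUE
        labels[flat_tissue_idx[:k]] = STAINED
        labels = labels.reshape(size, size)

        img = np.empty((size, size), dtype=float)
        img[labels == STAINED] = 70.0
        img[labels == UNSTAINED] = 165.0
        img[labels == NO_TISSUE] = 240.0
        img += rng.normal(0.0, spec.intensity_noise, img.shape)
        # keep the class bands separable by the default thresholds
        img[labels == STAINED] = np.clip(
            img[labels == STAINED], 20.0, DEFAULT_THRESHOLDS["stain_max"] - 1.0
        )
        img[labels == UNSTAINED] = np.clip(
            img[labels == UNSTAINED],
            DEFAULT_THRESHOLDS["stain_max"] + 1.0,
            DEFAULT_THRESHOLDS["lumen_min"] - 1.0,
        )
        img[labels == NO_TISSUE] = np.clip(
            img[labels == NO_TISSUE], DEFAULT_THRESHOLDS["lumen_min"] + 1.0, 255.0
        )
        images.append(np.round(img).astype(np.uint8))
        truths.append(
            {
                "mask": LabelImage(
                    labels=labels,
                    source="<synthetic>",
                    thresholds=dict(DEFAULT_THRESHOLDS),
                    class_names=_CLASS_NAMES[spec.mode],
                ),
                "counts": {
                    _CLASS_NAMES[spec.mode][0]: int(k),
                    _CLASS_NAMES[spec.mode][1]: int(n_tissue - k),
                    "no_tissue": int(lumen.sum()),
                },
                "target_fraction": target,
            }
        )
    return images, truths
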