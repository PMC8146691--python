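"""Synthetic tumour phantoms with controlled local-skewness heterogeneity.

Real T2w cohorts of this kind are private, so the pipeline is exercised on
phantoms that reproduce the statistical structure the analysis targets:

* a *responder-like* phantom partitions its circular ROI into Voronoi cells
  whose intensity distributions share mean and standard deviation but differ
  in skewness (shape drawn per cell from Uniform(-spread, +spread)) — a
  spatially heterogeneous local-skewness field;
* a *non-responder-like* phantom uses spread 0, i.e. every cell is the same
  Gaussian — a spatially uniform (near-zero) local-skewness field.

Cell deviates are standardized skew-normal draws mapped to
``base_intensity + noise_sd * z``, so every cell has population mean
``base_intensity`` and standard deviation ``noise_sd`` exactly: the groups
differ in the heterogeneity of local *asymmetry*, not in their first-order
intensity statistics.  Background outside the ROI is Gaussian around half
the base intensity, so the in-mask window criterion is actually exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import skewnorm

from .io import RoiImageStack

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]

from .global_features import GROUP_LABELS


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of one synthetic tumour stack."""

    image_size_px: int = 96
    roi_radius_px: int = 32
    n_slices: int = 3
    pixel_spacing_mm: float = 0.5
    n_subregions: int = 8
    skew_shape_spread: float = 6.0  # 0.0 for the non-responder-like phantom
    base_intensity: float = 400.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_radius_px * 2 >= self.image_size_px:
            raise ValueError("ROI does not fit inside the image")
        if self.n_subregions < 1:
            raise ValueError("n_subregions must be >= 1")
        if self.skew_shape_spread < 0:
            raise ValueError("skew_shape_spread must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortSpec:
    """A synthetic two-group cohort (responder-like vs non-responder-like)."""

    n_responders: int = 15
    n_nonresponders: int = 25
    responder_template: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(skew_shape_spread=6.0)
    )
    nonresponder_template: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(skew_shape_spread=0.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ValueError("each group needs at least 2 patients")


def _standardized_skewnorm(a: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Skew-normal deviates with population mean 0 and sd 1 at shape ``a``."""
    z = skewnorm.rvs(a, size=size, random_state=rng)
    delta = a / np.sqrt(1.0 + a * a)
    mu = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - mu * mu)
    return (z - mu) / sd


def generate_phantom(spec: PhantomSpec) -> RoiImageStack:
    """Generate one deterministic phantom stack from its spec.

    Per slice: a centred circular ROI is partitioned into ``n_subregions``
    Voronoi cells around RNG-placed seed pixels (random placement avoids
    aliasing between the cell grid and the sliding window); each cell's
    pixels are standardized skew-normal with a per-cell shape from
    Uniform(-spread, +spread).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= spec.roi_radius_px**2
    roi_coords = np.argwhere(mask)
    slices, masks = [], []
    for _ in range(spec.n_slices):
        img = spec.base_intensity / 2.0 + rng.normal(0.0, spec.noise_sd, (n, n))
        seeds = roi_coords[rng.choice(roi_coords.shape[0], spec.n_subregions, replace=False)]
        d2 = ((roi_coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        cell_of = d2.argmin(axis=1)
        shapes = rng.uniform(-spec.skew_shape_spread, spec.skew_shape_spread, spec.n_subregions)
        for k in range(spec.n_subregions):
            px = roi_coords[cell_of == k]
            if px.size == 0:
                continue
            z = _standardized_skewnorm(shapes[k], px.shape[0], rng)
            img[px[:, 0], px[:, 1]] = spec.base_intensity + spec.noise_sd * z
        slices.append(img)
        masks.append(mask.copy())
    return RoiImageStack(
        patient_id=f"phantom-{spec.seed}",
        slices=slices,
        masks=masks,
        pixel_spacing_mm=spec.pixel_spacing_mm,
    )


def generate_cohort(cohort: CohortSpec) -> tuple[list[RoiImageStack], list[str]]:
    """Generate the two-group phantom cohort with deterministic seed lineage.

    Child seeds are derived from the cohort seed through an integer
    ``SeedSequence`` expansion, so the cohort is bit-reproducible across
    platforms.
    """
    n_total = cohort.n_responders + cohort.n_nonresponders
    child_seeds = np.random.SeedSequence(cohort.seed).generate_state(n_total)
    stacks: list[RoiImageStack] = []
    labels: list[str] = []
    for i in range(n_total):
        responder = i < cohort.n_responders
        template = cohort.responder_template if responder else cohort.nonresponder_template
        label = GROUP_LABELS[0] if responder else GROUP_LABELS[1]
        spec = replace(template, seed=int(child_seeds[i]))
        stack = generate_phantom(spec)
        stack.patient_id = f"{'R' if responder else 'N'}{i + 1:03d}"
        stacks.append(stack)
        labels.append(label)
    return stacks, labels
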