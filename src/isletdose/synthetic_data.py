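"""Synthetic inputs with known ground truth.

Three generators emulate the data streams the dosimetry pipeline
consumes, each with explicit seeding (same seed, bit-identical output)
and a ground-truth record that no pipeline stage reads:

* kidney time-activity curves: fraction of injected activity following
  1-2 exponential biological clearance components times physical decay,
  sampled at scintigraphy time points, with optional multiplicative
  noise; the true TIAC is available in closed form;
* autoradiography sections: a tissue ellipse at a uniform exocrine
  activity level with non-overlapping circular islets at ``r`` times the
  exocrine concentration, plus background, blurred by a Gaussian PSF
  (the plate spill-over) and degraded by scaled-Poisson noise; paired
  histology masks are the unblurred geometry, optionally mis-registered
  by a known (scale, rotation);
* rat biodistribution tables: per-animal injected activity and pancreas
  uptake fraction from truncated normal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .autoradiography import MaskSet, SectionImage, _similarity, _warp_nearest
from .decay_data import decay_constant, load_spectrum
from .tiac import TimeActivityCurve

__all__ = [
    "TacModel",
    "SectionModel",
    "SectionGroundTruth",
    "PAPER_SAMPLE_TIMES_H",
    "gen_kidney_tac",
    "gen_kidney_cohort",
    "gen_section",
    "gen_rat_biodistribution",
]

#: serial planar-scintigraphy acquisition times (hours post injection)
PAPER_SAMPLE_TIMES_H = (0.0, 4.0, 24.0, 48.0, 96.0, 168.0)


# ---------------------------------------------------------------------------
# kidney time-activity curves


@dataclass(frozen=True)
class TacModel:
    """Kinetic ground truth for one subject's kidney curve.

    Defaults describe near-complete metabolic trapping of
    radiometal-labelled exendin in the kidneys: roughly a third of the
    injected activity retained with a very slow (2000 h) biological
    half-time.  With In-111 decay this yields a kidney TIAC of ~30
    MBq.h/MBq and, after rescaling to Ga-68, ~0.5 MBq.h/MBq --
    reproducing the published volunteer-average inputs, whose In/Ga
    ratio sits at the pure half-life ratio and therefore rules out fast
    biological clearance.
    """

    uptake_fraction: float = 0.32
    biological_half_times_h: tuple[float, ...] = (2000.0,)
    weights: tuple[float, ...] = (1.0,)
    nuclide_id: str = "In-111"
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.uptake_fraction <= 1.0:
            raise ValueError("uptake fraction must lie in (0, 1]")
        if len(self.weights) != len(self.biological_half_times_h):
            raise ValueError("one weight per biological component")
        if any(t <= 0 for t in self.biological_half_times_h):
            raise ValueError("biological half-times must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def _bio_lambdas(model: TacModel) -> np.ndarray:
    return np.log(2.0) / np.asarray(model.biological_half_times_h)


def gen_kidney_tac(
    model: TacModel, sample_times_h=PAPER_SAMPLE_TIMES_H
) -> tuple[TimeActivityCurve, float]:
    """Sampled decay-included kidney curve plus its analytic true TIAC.

    A(t) = uptake * sum_i w_i exp(-lambda_bio,i t) * exp(-lambda_phys t),
    with multiplicative Gaussian noise of the stated CV; the true TIAC is
    uptake * sum_i w_i / (lambda_bio,i + lambda_phys).
    """
    t = np.asarray(sample_times_h, dtype=float)
    lam_phys = decay_constant(load_spectrum(model.nuclide_id))
    lam_bio = _bio_lambdas(model)
    w = np.asarray(model.weights)
    clean = model.uptake_fraction * (w[None, :] * np.exp(-lam_bio[None, :] * t[:, None])).sum(
        axis=1
    ) * np.exp(-lam_phys * t)
    if model.noise_cv > 0:
        rng = np.random.default_rng(model.seed)
        clean = clean * (1.0 + model.noise_cv * rng.standard_normal(t.size))
    tau_true = float(model.uptake_fraction * (w / (lam_bio + lam_phys)).sum())
    return TimeActivityCurve(t, np.clip(clean, 0.0, 1.0), True), tau_true


def gen_kidney_cohort(
    uptake_fractions, model: TacModel = TacModel(), sample_times_h=PAPER_SAMPLE_TIMES_H
) -> list[tuple[TimeActivityCurve, float]]:
    """One curve per subject, varying only the uptake fraction."""
    out = []
    for i, u in enumerate(uptake_fractions):
        m = TacModel(
            uptake_fraction=float(u),
            biological_half_times_h=model.biological_half_times_h,
            weights=model.weights,
            nuclide_id=model.nuclide_id,
            noise_cv=model.noise_cv,
            seed=model.seed + i,
        )
        out.append(gen_kidney_tac(m, sample_times_h))
    return out


# ---------------------------------------------------------------------------
# autoradiography sections


@dataclass(frozen=True)
class SectionModel:
    """Scene parameters for one synthetic autoradiography section.

    Defaults give ~2% islet area fraction, a 100-fold islet:exocrine
    concentration ratio, a 40 um PSF and exocrine SNR ~10 -- the regime
    the quantification pipeline is designed for.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 20.0
    islet_count: int = 40
    diameter_median_um: float = 170.0
    diameter_sigma_log: float = 0.35
    fixed_diameter_um: float | None = None
    uptake_ratio_true: float = 100.0
    exocrine_level: float = 20.0
    background_level: float = 5.0
    psf_sigma_um: float = 40.0
    noise_scale: float = 5.0  # Poisson quanta per intensity unit; 0 = noiseless
    transform: tuple[float, float] = (1.0, 0.0)  # (scale, rotation_deg) on the masks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_ratio_true <= 0:
            raise ValueError("uptake ratio must be positive")
        if self.exocrine_level <= 0 or self.background_level < 0:
            raise ValueError("invalid intensity levels")
        if self.psf_sigma_um < 0 or self.noise_scale < 0:
            raise ValueError("PSF sigma and noise scale must be non-negative")
        if self.transform[0] <= 0:
            raise ValueError("mask transform scale must be positive")


@dataclass(frozen=True)
class SectionGroundTruth:
    uptake_ratio: float
    islet_fraction: float
    background_level: float
    exocrine_level: float
    psf_sigma_um: float
    transform: tuple[float, float]
    diameters_um: np.ndarray = field(default_factory=lambda: np.empty(0))


def _draw_diameters(model: SectionModel, rng: np.random.Generator) -> np.ndarray:
    if model.fixed_diameter_um is not None:
        return np.full(model.islet_count, float(model.fixed_diameter_um))
    d = np.empty(model.islet_count)
    for i in range(model.islet_count):
        # truncated log-normal over the physiological 50-400 um span
        while True:
            x = np.exp(np.log(model.diameter_median_um) + model.diameter_sigma_log * rng.standard_normal())
            if 50.0 <= x <= 400.0:
                d[i] = x
                break
    return d


def gen_section(model: SectionModel) -> tuple[SectionImage, MaskSet, SectionGroundTruth]:
    """Generate one section image with paired masks and ground truth.

    Islet pixels carry ``r`` times the exocrine activity concentration
    (replacing, not adding to, the exocrine level); the noiseless scene
    is blurred with the Gaussian PSF and scaled-Poisson noise is applied.
    Masks are the unblurred geometry, warped by the model's
    (scale, rotation) to exercise registration.  Raises ``RuntimeError``
    if the requested islet count cannot be placed without overlap.
    """
    rng = np.random.default_rng(model.seed)
    ny, nx = model.image_size
    yy, xx = np.mgrid[0:ny, 0:nx]

    # tissue: centred anisotropic ellipse (real sections are elongated,
    # and the anisotropy makes rotational registration identifiable),
    # leaving clear corners for the background regions
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = 0.42 * ny, 0.34 * nx
    tissue = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    diameters = _draw_diameters(model, rng)
    radii_px = diameters / 2.0 / model.pixel_size_um
    clearance_px = 3.0 * model.psf_sigma_um / model.pixel_size_um  # keep rings separable

    labels = np.zeros((ny, nx), dtype=np.int32)
    centers: list[tuple[float, float, float]] = []
    for i, r_px in enumerate(radii_px):
        placed = False
        for _ in range(2000):
            y = rng.uniform(r_px, ny - r_px)
            x = rng.uniform(r_px, nx - r_px)
            # islet (and its spill margin) fully inside tissue ellipse
            margin = r_px + clearance_px
            if ((y - cy) / (ay - margin)) ** 2 + ((x - cx) / (ax - margin)) ** 2 > 1.0:
                continue
            if any(
                np.hypot(y - yc, x - xc) < r_px + rc + 2.0 * clearance_px
                for yc, xc, rc in centers
            ):
                continue
            labels[(yy - y) ** 2 + (xx - x) ** 2 <= r_px**2] = i + 1
            centers.append((y, x, r_px))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place islet {i + 1}/{model.islet_count} without overlap; "
                "reduce islet_count or diameters"
            )

    islets = labels > 0
    scene = (
        model.background_level
        + model.exocrine_level * (tissue & ~islets)
        + model.uptake_ratio_true * model.exocrine_level * islets
    ).astype(float)
    if model.psf_sigma_um > 0:
        scene = gaussian_filter(scene, sigma=model.psf_sigma_um / model.pixel_size_um)
    if model.noise_scale > 0:
        scene = rng.poisson(scene * model.noise_scale) / model.noise_scale
    image = SectionImage(scene, model.pixel_size_um)

    # three background regions in corners untouched by the tissue ellipse
    k = max(ny, nx) // 16
    regions = []
    for sl in ((slice(0, k), slice(0, k)), (slice(0, k), slice(nx - k, nx)), (slice(ny - k, ny), slice(0, k))):
        reg = np.zeros((ny, nx), dtype=bool)
        reg[sl] = True
        regions.append(reg)

    # histology masks may be mis-registered; the background regions are
    # picked on the autoradiograph and therefore stay on the image grid
    scale, rot = model.transform
    if (scale, rot) != (1.0, 0.0):
        tform = _similarity((ny, nx), scale, rot)
        tissue_m = _warp_nearest(tissue, tform, (ny, nx))
        labels_m = _warp_nearest(labels, tform, (ny, nx))
        regions_m = [r & ~tissue_m for r in regions]
    else:
        tissue_m, labels_m, regions_m = tissue, labels, regions

    masks = MaskSet(
        tissue_mask=tissue_m,
        islet_labels=labels_m,
        background_regions=tuple(regions_m),
        transform=(scale, rot),
    )
    truth = SectionGroundTruth(
        uptake_ratio=model.uptake_ratio_true,
        islet_fraction=float(islets.sum() / tissue.sum()),
        background_level=model.background_level,
        exocrine_level=model.exocrine_level,
        psf_sigma_um=model.psf_sigma_um,
        transform=(scale, rot),
        diameters_um=diameters,
    )
    return image, masks, truth


# ---------------------------------------------------------------------------
# rat biodistribution


def gen_rat_biodistribution(
    n_rats: int = 9,
    injected_mbq: tuple[float, float] = (18.5, 1.78),
    pancreas_uptake_fraction: tuple[float, float] = (0.005, 0.001),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-rat injected activity and pancreas uptake fraction.

    Both quantities are drawn from normal distributions truncated at
    zero, with (mean, sd) as given.  Feeds the rat-to-human TIAC
    translation and the pancreas partition.
    """
    if n_rats < 1:
        raise ValueError("need at least one rat")
    rng = np.random.default_rng(seed)

    def trunc_normal(mean: float, sd: float, n: int) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        out = np.empty(n)
        for i in range(n):
            while True:
                x = rng.normal(mean, sd)
                if x > 0:
                    out[i] = x
                    break
        return out

    return pd.DataFrame(
        {
            "rat_id": np.arange(1, n_rats + 1),
            "injected_MBq": trunc_normal(*injected_mbq, n_rats),
            "pancreas_fraction": trunc_normal(*pancreas_uptake_fraction, n_rats),
        }
    )
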