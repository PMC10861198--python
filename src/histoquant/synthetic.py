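"""Synthetic tissue-section generators with known ground truth.

Three generators back the test pyramid of every downstream stage:

* :func:`generate_nuclei_scene` — a nuclear-stain channel containing two
  populations of textured elliptical nuclei with controllable morphology,
  chromatin texture, boundary irregularity and axial orientation spread;
* :func:`generate_fiber_field` — additively superposed oriented line
  segments emulating an ECM fiber channel;
* :func:`generate_point_pattern` — isotropic Gaussian centroid clouds for
  distance-matrix and dispersion tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .axial import sample_axial_angles, wrap_axial

log = logging.getLogger(__name__)

__all__ = [
    "PopulationParams",
    "SyntheticScene",
    "SceneTooCrowdedError",
    "generate_nuclei_scene",
    "generate_fiber_field",
    "generate_point_pattern",
    "write_scene",
]


class SceneTooCrowdedError(RuntimeError):
    """Raised when non-overlapping nucleus placement exhausts its retry budget."""


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth statistics of one nucleus population.

    Parameters
    ----------
    mean_area:
        Mean nuclear area in square micrometres.
    area_cv:
        Coefficient of variation of the area distribution (lognormal).
    mean_aspect_ratio:
        Mean major/minor axis ratio (>= 1).
    texture_granularity:
        Length scale of chromatin texture blobs, micrometres.
    texture_contrast:
        Multiplicative texture amplitude in [0, 1]; 0 renders flat nuclei.
    boundary_irregularity:
        RMS amplitude of the low-order Fourier boundary perturbation (>= 0).
    orientation_concentration:
        Axial von Mises concentration of the nuclear long-axis angles;
        0 means uniform orientations.
    mean_orientation:
        Axial mean of the long-axis angles, degrees in (-90, 90].
    """

    mean_area: float = 70.0
    area_cv: float = 0.15
    mean_aspect_ratio: float = 1.6
    texture_granularity: float = 1.0
    texture_contrast: float = 0.3
    boundary_irregularity: float = 0.02
    orientation_concentration: float = 0.0
    mean_orientation: float = 0.0

    def __post_init__(self):
        if self.mean_area <= 0 or self.texture_granularity <= 0:
            raise ValueError("scale parameters must be > 0")
        if self.mean_aspect_ratio < 1.0:
            raise ValueError("mean_aspect_ratio must be >= 1")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.boundary_irregularity < 0 or self.orientation_concentration < 0:
            raise ValueError("boundary_irregularity and orientation_concentration must be >= 0")
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")


@dataclass
class SyntheticScene:
    """A rendered nuclear channel plus its ground truth."""

    image: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame  # nucleus_id, population, x_um, y_um, area_um2, aspect_ratio, orientation_deg
    pixel_size: float
    params: dict
    seed: int

    @property
    def n_nuclei(self) -> int:
        return len(self.truth)


def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _boundary_profile(psi: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-order Fourier radial perturbation; ``coeffs`` has shape (order, 2)."""
    out = np.zeros_like(psi)
    for k, (ck, sk) in enumerate(coeffs, start=2):
        out += ck * np.cos(k * psi) + sk * np.sin(k * psi)
    return out


def _render_nucleus(rng, a_px, b_px, theta_deg, irregularity, granularity_px, contrast):
    """Render one textured, irregular ellipse in a local patch.

    Returns ``(mask, intensity, half)`` where ``half`` is the patch
    half-width in pixels and intensity is a multiplicative texture factor
    (mean ~1) defined on the mask.
    """
    pad = 3.0 + 3.0 * irregularity * a_px
    half = int(np.ceil(a_px + pad))
    n = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    # Cartesian y-up in the local frame.
    y = -yy.astype(float)
    x = xx.astype(float)
    th = np.deg2rad(theta_deg)
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y
    u = xr / a_px
    v = yr / b_px
    r = np.hypot(u, v)
    if irregularity > 0:
        raw = rng.normal(size=(4, 2))
        norm = np.sqrt(np.sum(raw**2) / 2.0)
        coeffs = irregularity * raw / max(norm, 1e-12)
        psi = np.arctan2(v, u)
        boundary = 1.0 + _boundary_profile(psi, coeffs)
    else:
        boundary = 1.0
    mask = r <= boundary
    if contrast > 0:
        noise = rng.normal(size=(n, n))
        sigma_lo = max(granularity_px / 2.0, 0.5)
        band = gaussian_filter(noise, sigma_lo) - gaussian_filter(noise, 2.0 * sigma_lo)
        sd = band[mask].std() if mask.sum() > 1 else 0.0
        if sd > 0:
            band = band / sd
        texture = np.clip(1.0 + contrast * band, 0.0, 2.0)
    else:
        texture = np.ones((n, n))
    return mask, texture, half


def generate_nuclei_scene(
    params_a: PopulationParams,
    params_b: PopulationParams,
    n_per_pop: int,
    dispersion: float,
    image_size: int = 512,
    pixel_size: float = 0.5,
    seed: int = 0,
    snr: float = 10.0,
    foreground: float = 1000.0,
    background: float = 100.0,
) -> SyntheticScene:
    """Render ``2 * n_per_pop`` non-overlapping nuclei from two populations.

    Centroids are drawn from an isotropic Gaussian of standard deviation
    ``dispersion`` (micrometres) around the image centre, rejecting
    placements that overlap previously accepted nuclei or fall outside the
    frame.  The retry budget is ``100 * 2 * n_per_pop`` draws overall.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = 2 * n_per_pop
    populations = ["a"] * n_per_pop + ["b"] * n_per_pop

    # Sample per-nucleus geometry first so that the draw sequence (and hence
    # the centroid offsets below) does not depend on placement outcomes.
    areas = np.empty(n_total)
    aspects = np.empty(n_total)
    orientations = np.empty(n_total)
    for i, p in enumerate((params_a, params_b)):
        sl = slice(i * n_per_pop, (i + 1) * n_per_pop)
        areas[sl] = _lognormal(rng, p.mean_area, p.area_cv, n_per_pop)
        aspects[sl] = np.maximum(_lognormal(rng, p.mean_aspect_ratio, 0.05, n_per_pop), 1.02)
        orientations[sl] = sample_axial_angles(
            p.mean_orientation, p.orientation_concentration, n_per_pop, rng
        )

    a_um = np.sqrt(areas * aspects / np.pi)
    b_um = np.sqrt(areas / (aspects * np.pi))
    a_px = a_um / pixel_size
    radius_px = a_px + 2.0  # bounding circle used for overlap rejection

    centre = (image_size - 1) / 2.0
    budget = 100 * n_total
    attempts = 0
    placed_xy = np.empty((n_total, 2))  # pixel coordinates (col, row)
    for i in range(n_total):
        ok = False
        while attempts < budget:
            attempts += 1
            off = rng.normal(0.0, 1.0, size=2) * (dispersion / pixel_size)
            col = centre + off[0]
            row = centre - off[1]  # y-up convention
            r_i = radius_px[i]
            if not (r_i <= col <= image_size - 1 - r_i and r_i <= row <= image_size - 1 - r_i):
                continue
            if i > 0:
                d = np.hypot(placed_xy[:i, 0] - col, placed_xy[:i, 1] - row)
                if np.any(d < radius_px[:i] + r_i):
                    continue
            placed_xy[i] = (col, row)
            ok = True
            break
        if not ok:
            area_covered = np.pi * np.sum((radius_px[:i] * pixel_size) ** 2)
            disc_area = np.pi * (3 * dispersion) ** 2 if dispersion > 0 else (image_size * pixel_size) ** 2
            raise SceneTooCrowdedError(
                f"scene too crowded: placed {i}/{n_total} nuclei within the retry "
                f"budget ({budget} draws); ~{area_covered / max(disc_area, 1e-9):.0%} of the "
                f"placement disc is already covered — reduce n_per_pop or raise dispersion"
            )

    image = np.full((image_size, image_size), background, dtype=float)
    labels = np.zeros((image_size, image_size), dtype=np.int32)
    rows = []
    for i in range(n_total):
        p = params_a if i < n_per_pop else params_b
        mask, texture, half = _render_nucleus(
            rng,
            a_px[i],
            b_um[i] / pixel_size,
            orientations[i],
            p.boundary_irregularity,
            p.texture_granularity / pixel_size,
            p.texture_contrast,
        )
        col, row = placed_xy[i]
        r0, c0 = int(round(row)) - half, int(round(col)) - half
        r1, c1 = r0 + mask.shape[0], c0 + mask.shape[1]
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, image_size), min(c1, image_size)
        sub = mask[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        tex = texture[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        patch = image[rr0:rr1, cc0:cc1]
        patch[sub] = background + (foreground - background) * tex[sub]
        labels[rr0:rr1, cc0:cc1][sub] = i + 1
        rows.append(
            {
                "nucleus_id": i + 1,
                "population": populations[i],
                "x_um": col * pixel_size,
                "y_um": (image_size - 1 - row) * pixel_size,
                "area_um2": areas[i],
                "aspect_ratio": aspects[i],
                "orientation_deg": orientations[i],
            }
        )

    noise_sd = (foreground - background) / snr if snr > 0 else 0.0
    image += rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    params = {
        "params_a": dataclasses.asdict(params_a),
        "params_b": dataclasses.asdict(params_b),
        "n_per_pop": n_per_pop,
        "dispersion": dispersion,
        "image_size": image_size,
        "pixel_size": pixel_size,
        "snr": snr,
        "foreground": foreground,
        "background": background,
    }
    truth = pd.DataFrame(rows)
    log.info("generated scene: %d nuclei in %d attempts", n_total, attempts)
    return SyntheticScene(image, labels, truth, pixel_size, params, seed)


def generate_fiber_field(
    mean_angle: float,
    concentration: float,
    image_size: int = 512,
    seed: int = 0,
    n_segments: int | None = None,
    segment_length: float = 40.0,
    blur_sigma: float = 1.0,
    return_angles: bool = False,
):
    """Render additively superposed oriented line segments.

    Segment axial angles follow a doubled-angle von Mises law with the
    given mean and concentration (0 = uniform).  Returns the image, or
    ``(image, angles)`` when ``return_angles`` is set.
    """
    if not -90.0 < mean_angle <= 90.0:
        raise ValueError("mean_angle must be in (-90, 90]")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    if n_segments is None:
        n_segments = max(int(0.002 * image_size**2), 50)
    angles = sample_axial_angles(mean_angle, concentration, n_segments, rng)
    centers = rng.uniform(0, image_size, size=(n_segments, 2))
    image = np.zeros((image_size, image_size), dtype=float)
    half = segment_length / 2.0
    for (cx, cy), ang in zip(centers, angles):
        th = np.deg2rad(ang)
        dx, dy = np.cos(th) * half, np.sin(th) * half
        # y-up: increasing y is decreasing row
        r0 = int(round(cy + dy))
        c0 = int(round(cx + dx))
        r1 = int(round(cy - dy))
        c1 = int(round(cx - dx))
        r0, r1 = np.clip([image_size - 1 - r0, image_size - 1 - r1], 0, image_size - 1)
        c0, c1 = np.clip([c0, c1], 0, image_size - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        image[rr, cc] += val
    if blur_sigma > 0:
        image = gaussian_filter(image, blur_sigma)
    if return_angles:
        return image, angles
    return image


def generate_point_pattern(n: int, dispersion: float, seed: int = 0) -> np.ndarray:
    """Draw ``n`` centroids (micrometres) from an isotropic bivariate normal.

    The standard deviation along each axis equals ``dispersion``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=(n, 2)) * dispersion


def write_scene(scene: SyntheticScene, prefix) -> None:
    """Write the rendered channel, label image and ground-truth CSV."""
    prefix = str(prefix)
    tifffile.imwrite(prefix + "_image.tif", np.clip(scene.image, 0, 65535).astype(np.uint16))
    tifffile.imwrite(prefix + "_labels.tif", scene.labels.astype(np.uint16))
    scene.truth.to_csv(prefix + "_truth.csv", index=False)
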