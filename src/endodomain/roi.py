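"""Circular-geometry primitives on which all image metrics operate.

Conventions
-----------
* Coordinates are 0-based and pixel-centered; ``center`` is ``(x, y)`` in
  pixels with the row index (y) increasing downward.
* Angles are in degrees, measured counter-clockwise from the +x image axis,
  i.e. ``angle = atan2(center_y - y, x - center_x)`` reduced to [0, 360).
* Physical lengths carry a ``_um`` suffix; conversion to pixels uses the
  image's ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PixelImage",
    "DiscROI",
    "RingROI",
    "AnnulusROI",
    "AngularProfile",
    "disc_mask",
    "annulus_mask",
    "ring_mask",
    "circle_profile",
    "split_equal_area",
    "place_measurement_discs",
    "otsu_threshold",
    "default_n_samples",
    "pixel_angles_deg",
]


@dataclass(frozen=True)
class PixelImage:
    """Single-channel 2D intensity grid with a physical pixel size."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {values.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um


@dataclass(frozen=True)
class DiscROI:
    """Filled circular region: ``center=(x, y)`` in pixels, radius in microns."""

    center: tuple[float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius_um must be positive")


@dataclass(frozen=True)
class RingROI:
    """Annular band of width ``width_um`` centered on the circle of ``radius_um``."""

    center: tuple[float, float]
    radius_um: float
    width_um: float

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")
        if not self.radius_um > self.width_um / 2:
            raise ValueError("radius_um must exceed width_um/2")

    @property
    def outer_radius_um(self) -> float:
        return self.radius_um + self.width_um / 2

    @property
    def inner_radius_um(self) -> float:
        return self.radius_um - self.width_um / 2


@dataclass(frozen=True)
class AnnulusROI:
    """Region between two concentric circles (inner excluded, outer included)."""

    center: tuple[float, float]
    inner_radius_um: float
    outer_radius_um: float

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius_um < self.outer_radius_um:
            raise ValueError("need 0 <= inner_radius_um < outer_radius_um")


@dataclass(frozen=True)
class AngularProfile:
    """Circumferential line scan: equally spaced angles in [0, 360) + intensities."""

    angles_deg: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if angles.shape != intens.shape or angles.ndim != 1:
            raise ValueError("angles and intensities must be 1D of equal length")
        if angles.size >= 2:
            steps = np.diff(angles)
            if not np.allclose(steps, steps[0]):
                raise ValueError("angles must be equally spaced")
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "intensities", intens)

    @property
    def n_samples(self) -> int:
        return self.angles_deg.size


def _radius_grid_px(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cx, cy = center
    return np.hypot(cols - cx, rows - cy)


def pixel_angles_deg(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Angle of every pixel center from ``center``, degrees CCW from +x, in [0, 360)."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cx, cy = center
    ang = np.degrees(np.arctan2(cy - rows, cols - cx))
    return np.mod(ang, 360.0) + np.zeros(shape)


def disc_mask(image: PixelImage, roi: DiscROI) -> np.ndarray:
    """Boolean mask: True where the pixel center lies within the disc.

    Raises ``ValueError`` if the disc does not cover any pixel center.
    """
    r_px = image.um_to_px(roi.radius_um)
    mask = _radius_grid_px(image.shape, roi.center) <= r_px
    if not mask.any():
        raise ValueError(
            f"disc at {roi.center} (radius {roi.radius_um} um) lies outside the image"
        )
    return mask


def annulus_mask(image: PixelImage, roi: AnnulusROI) -> np.ndarray:
    """Boolean mask of the annulus; inner boundary excluded, outer included."""
    r = _radius_grid_px(image.shape, roi.center)
    inner = image.um_to_px(roi.inner_radius_um)
    outer = image.um_to_px(roi.outer_radius_um)
    return (r > inner) & (r <= outer)


def ring_mask(image: PixelImage, roi: RingROI) -> np.ndarray:
    """Boolean mask of a ring band: ``|dist - radius| <= width/2``."""
    r = _radius_grid_px(image.shape, roi.center)
    return np.abs(r - image.um_to_px(roi.radius_um)) <= image.um_to_px(roi.width_um) / 2


def default_n_samples(image: PixelImage, roi: RingROI) -> int:
    """~1 sample per circumference pixel: ``ceil(2*pi*radius_px)``."""
    return int(np.ceil(2 * np.pi * image.um_to_px(roi.radius_um)))


def circle_profile(
    image: PixelImage,
    roi: RingROI,
    n_samples: int | None = None,
    *,
    width_averaged: bool = False,
    n_radial: int = 5,
) -> AngularProfile:
    """Circumferential line scan around a ring.

    Samples the bilinear interpolation of the image at ``n_samples`` equally
    spaced angles on the circle of the ring's nominal radius.  With
    ``width_averaged=True`` each angular sample is instead the mean over
    ``n_radial`` radii spanning the ring width.

    Raises ``ValueError`` if any sample point falls outside the image or if
    ``n_samples < 8``.
    """
    if n_samples is None:
        n_samples = default_n_samples(image, roi)
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    cx, cy = roi.center
    r_px = image.um_to_px(roi.radius_um)
    outer_px = image.um_to_px(roi.outer_radius_um) if width_averaged else r_px
    nrow, ncol = image.shape
    if (
        cx - outer_px < 0
        or cy - outer_px < 0
        or cx + outer_px > ncol - 1
        or cy + outer_px > nrow - 1
    ):
        raise ValueError("ring extends outside the image; cannot take a line scan")

    angles = np.arange(n_samples) * (360.0 / n_samples)
    theta = np.radians(angles)
    if width_averaged:
        radii = np.linspace(
            image.um_to_px(roi.inner_radius_um), outer_px, n_radial
        )[:, None]
    else:
        radii = np.array([[r_px]])
    xs = cx + radii * np.cos(theta)[None, :]
    ys = cy - radii * np.sin(theta)[None, :]
    sampled = ndimage.map_coordinates(image.values, [ys, xs], order=1, mode="nearest")
    return AngularProfile(angles_deg=angles, intensities=sampled.mean(axis=0))


def split_equal_area(cell: DiscROI) -> tuple[DiscROI, AnnulusROI]:
    """Split a disc into an interior disc and a peripheral annulus of equal area.

    The interior radius is ``cell.radius_um / sqrt(2)`` so each region carries
    exactly half the disc's analytic area.
    """
    inner = cell.radius_um / np.sqrt(2.0)
    interior = DiscROI(center=cell.center, radius_um=inner)
    peripheral = AnnulusROI(
        center=cell.center, inner_radius_um=inner, outer_radius_um=cell.radius_um
    )
    return interior, peripheral


def place_measurement_discs(
    image: PixelImage,
    endosomes: list[RingROI],
    n_on: int,
    n_off: int,
    disc_diameter_um: float,
    seed: int,
    *,
    cell: DiscROI | None = None,
    max_tries: int = 10_000,
) -> tuple[list[DiscROI], list[DiscROI]]:
    """Place measurement discs on endosomes and on endosome-free positions.

    Each of the ``n_on`` on-discs is centered on a distinct endosome.  The
    ``n_off`` off-discs are drawn by seeded rejection sampling so that they
    avoid every endosome ring, every other measurement disc, and (when
    ``cell`` is given) stay inside the cell disc.

    Raises ``ValueError`` when ``n_on`` exceeds the number of endosomes or
    when no valid off-disc position is found within ``max_tries`` draws.
    """
    if n_on > len(endosomes):
        raise ValueError(
            f"requested {n_on} on-discs but only {len(endosomes)} endosomes supplied"
        )
    disc_radius = disc_diameter_um / 2
    on_discs = [
        DiscROI(center=e.center, radius_um=disc_radius) for e in endosomes[:n_on]
    ]

    rng = np.random.default_rng(seed)
    nrow, ncol = image.shape
    if cell is not None:
        ccx, ccy = cell.center
        max_r = image.um_to_px(cell.radius_um - disc_radius)
        if max_r <= 0:
            raise ValueError("cell too small to contain a measurement disc")

    off_discs: list[DiscROI] = []
    placed = list(on_discs)
    for k in range(n_off):
        for _ in range(max_tries):
            if cell is not None:
                # uniform over the admissible disc of centers
                rr = max_r * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                x, y = ccx + rr * np.cos(th), ccy - rr * np.sin(th)
            else:
                margin = image.um_to_px(disc_radius)
                x = rng.uniform(margin, ncol - 1 - margin)
                y = rng.uniform(margin, nrow - 1 - margin)
            candidate = DiscROI(center=(x, y), radius_um=disc_radius)
            if _off_disc_ok(image, candidate, endosomes, placed):
                off_discs.append(candidate)
                placed.append(candidate)
                break
        else:
            raise ValueError(
                f"could not place off-disc {k + 1}/{n_off}: no position avoiding "
                "endosome rings and existing discs found"
            )
    return on_discs, off_discs


def _off_disc_ok(
    image: PixelImage,
    candidate: DiscROI,
    endosomes: list[RingROI],
    placed: list[DiscROI],
) -> bool:
    cx, cy = candidate.center
    r = candidate.radius_um
    for e in endosomes:
        d_um = np.hypot(cx - e.center[0], cy - e.center[1]) * image.pixel_size_um
        # disc must not touch the ring band [inner, outer]
        if d_um - r <= e.outer_radius_um and d_um + r >= e.inner_radius_um:
            return False
    for d in placed:
        d_um = np.hypot(cx - d.center[0], cy - d.center[1]) * image.pixel_size_um
        if d_um < r + d.radius_um:
            return False
    return True


def otsu_threshold(
    image: PixelImage, mask: np.ndarray | None = None, nbins: int = 256
) -> float:
    """Between-class-variance-maximizing threshold over the (masked) histogram.

    Raises ``ValueError`` when the region is constant.
    """
    values = image.values if mask is None else image.values[mask]
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty region")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("cannot threshold a constant region")
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    # between-class variance for a cut after bin i
    w0 = cum_w[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, cum_mu[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum_mu[-1] - cum_mu[:-1]) / np.maximum(w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(sigma_b))
    return float(centers[best : best + 2].mean())
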