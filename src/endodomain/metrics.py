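"""Image statistics for endosomal microdomains.

All "above threshold" comparisons are strict (``>``).  Ratios are reported
together with their log2 so two-fold differences read as +/-1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _label
from skimage.morphology import skeletonize as _skeletonize

from endodomain.roi import (
    AngularProfile,
    AnnulusROI,
    DiscROI,
    PixelImage,
    annulus_mask,
    disc_mask,
    split_equal_area,
)

__all__ = [
    "RatioResult",
    "SpreadResult",
    "ColocResult",
    "IntensityResult",
    "membrane_cytoplasm_ratio",
    "microdomain_spread",
    "interior_peripheral_ratio",
    "thresholded_pearson",
    "mean_intensity_above_threshold",
    "cell_area",
    "fiber_length",
]


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    log2_ratio: float
    numerator_mean: float
    denominator_mean: float
    n_regions_used: int

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")
        if not np.isclose(self.log2_ratio, np.log2(self.ratio)):
            raise ValueError("log2_ratio inconsistent with ratio")


@dataclass(frozen=True)
class SpreadResult:
    fraction_above: float
    threshold: float
    n_samples: int
    n_endosomes_averaged: int

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_above <= 1:
            raise ValueError("fraction_above must lie in [0, 1]")


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    n_pixels: int
    threshold_ch1: float
    threshold_ch2: float

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.pearson_r <= 1 + 1e-12:
            raise ValueError("pearson_r must lie in [-1, 1]")
        if self.n_pixels < 2:
            raise ValueError("need at least 2 pixels")


@dataclass(frozen=True)
class IntensityResult:
    """Mean of strictly-above-threshold pixels; ``mean is None`` flags an empty set."""

    mean: float | None
    n_pixels: int

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


def membrane_cytoplasm_ratio(
    image: PixelImage, on_discs: list[DiscROI], off_discs: list[DiscROI]
) -> RatioResult:
    """Mean of per-on-disc means over mean of per-off-disc means.

    On-discs encompass an endosome, off-discs encompass endosome-free
    cytoplasm (defaults elsewhere: three of each, 3 um diameter).
    """
    if not on_discs or not off_discs:
        raise ValueError("need at least one on-disc and one off-disc")
    on_mean = float(
        np.mean([image.values[disc_mask(image, d)].mean() for d in on_discs])
    )
    off_mean = float(
        np.mean([image.values[disc_mask(image, d)].mean() for d in off_discs])
    )
    if off_mean == 0:
        raise ValueError("off-disc mean intensity is zero; ratio undefined")
    ratio = on_mean / off_mean
    return RatioResult(
        ratio=ratio,
        log2_ratio=float(np.log2(ratio)),
        numerator_mean=on_mean,
        denominator_mean=off_mean,
        n_regions_used=len(on_discs) + len(off_discs),
    )


def microdomain_spread(
    profiles: list[AngularProfile], threshold: float
) -> SpreadResult:
    """Fraction of each circumference scan strictly above the threshold, averaged.

    The per-profile fraction measures the relative size of the microdomain on
    that endosome; the result averages over endosomes (at least one required).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    fractions = []
    for p in profiles:
        if p.n_samples == 0:
            raise ValueError("empty profile")
        fractions.append(float(np.mean(p.intensities > threshold)))
    return SpreadResult(
        fraction_above=float(np.mean(fractions)),
        threshold=float(threshold),
        n_samples=profiles[0].n_samples,
        n_endosomes_averaged=len(profiles),
    )


def interior_peripheral_ratio(
    image: PixelImage,
    cell: DiscROI,
    threshold: float,
    *,
    use_mean: bool = False,
) -> RatioResult:
    """Interior over peripheral above-threshold intensity on a log2 scale.

    The cell disc is split into two equal-area regions (interior disc of
    radius R/sqrt(2) and the peripheral annulus).  The default statistic is
    the INTEGRATED intensity of strictly-above-threshold pixels in each
    region; ``use_mean=True`` switches to the above-threshold mean.  A
    two-fold interior excess gives log2 = 1.0, equality 0.0, a two-fold
    peripheral excess -1.0.
    """
    interior, peripheral = split_equal_area(cell)
    vals = image.values
    int_mask = disc_mask(image, interior)
    per_mask = annulus_mask(image, peripheral)

    def _stat(mask: np.ndarray) -> tuple[float, int]:
        sel = vals[mask]
        above = sel[sel > threshold]
        if above.size == 0:
            return 0.0, 0
        return float(above.mean() if use_mean else above.sum()), int(above.size)

    num, n_num = _stat(int_mask)
    den, n_den = _stat(per_mask)
    if num == 0 or den == 0:
        raise ValueError(
            "a region has zero above-threshold intensity "
            f"(interior n={n_num}, peripheral n={n_den}); ratio undefined"
        )
    ratio = num / den
    return RatioResult(
        ratio=ratio,
        log2_ratio=float(np.log2(ratio)),
        numerator_mean=num,
        denominator_mean=den,
        n_regions_used=2,
    )


def thresholded_pearson(
    ch1: PixelImage,
    ch2: PixelImage,
    region: np.ndarray | None,
    t1: float,
    t2: float,
    include: str = "union",
) -> ColocResult:
    """Pearson correlation of two channels over thresholded pixels.

    ``include`` selects the pixel set inside ``region``: ``"union"`` (above
    threshold in either channel, the default), ``"intersection"`` (above in
    both), or ``"all"`` (every region pixel).
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    a, b = ch1.values, ch2.values
    if region is None:
        region = np.ones(a.shape, dtype=bool)
    if include == "union":
        sel = region & ((a > t1) | (b > t2))
    elif include == "intersection":
        sel = region & (a > t1) & (b > t2)
    elif include == "all":
        sel = np.asarray(region, dtype=bool)
    else:
        raise ValueError(f"unknown inclusion rule {include!r}")
    x, y = a[sel], b[sel]
    if x.size < 2:
        raise ValueError("fewer than 2 included pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an included channel")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    return ColocResult(
        pearson_r=r, n_pixels=int(x.size), threshold_ch1=float(t1), threshold_ch2=float(t2)
    )


def mean_intensity_above_threshold(
    image: PixelImage, region: np.ndarray, threshold: float
) -> IntensityResult:
    """Mean over strictly-above-threshold pixels inside ``region``.

    An empty above-threshold set is a valid outcome and yields
    ``IntensityResult(mean=None, n_pixels=0)``, never a NaN.
    """
    sel = image.values[np.asarray(region, dtype=bool)]
    if sel.size == 0:
        raise ValueError("empty region")
    above = sel[sel > threshold]
    if above.size == 0:
        return IntensityResult(mean=None, n_pixels=0)
    return IntensityResult(mean=float(above.mean()), n_pixels=int(above.size))


def cell_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """True-pixel count times the pixel area, in square microns."""
    return float(np.count_nonzero(mask) * pixel_size_um**2)


def fiber_length(mask: np.ndarray, pixel_size_um: float) -> list[float]:
    """Skeleton path length of each connected component, in microns.

    Each component of the binary mask is skeletonized; its length is the sum
    over adjacent skeleton-pixel pairs of the step length (1 for orthogonal,
    sqrt(2) for diagonal neighbors) scaled by the pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels = _label(mask, connectivity=2)
    lengths = []
    for lab in range(1, labels.max() + 1):
        skel = _skeletonize(labels == lab)
        lengths.append(_skeleton_path_length(skel) * pixel_size_um)
    return lengths


# offsets covering each unordered neighbor pair exactly once
_STEPS = (((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), np.sqrt(2)), ((1, -1), np.sqrt(2)))


def _skeleton_path_length(skel: np.ndarray) -> float:
    total = 0.0
    padded = np.pad(skel, 1)
    nrow, ncol = skel.shape
    for (dr, dc), w in _STEPS:
        shifted = padded[1 + dr : 1 + dr + nrow, 1 + dc : 1 + dc + ncol]
        total += w * np.count_nonzero(skel & shifted)
    return total
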