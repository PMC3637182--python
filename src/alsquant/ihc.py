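"""Automated DAB-IHC quantification.

Implements the image-analysis chain used in preclinical spinal-cord
histology: tissue masking by RGB color detection, motor-neuron soma
detection by a three-stage procedure (global color thresholds +
morphological opening; close-open with reconstruction; regional-minima
detection and watershed, followed by dilation and size filtering),
positive-pixel brown detection with a minimum cluster-size cutoff
(default 180 um^2), percent-area normalization against tissue area, and
automated-vs-manual count calibration.

All thresholds live in :class:`QuantConfig`. The algorithm structure is the
contract; the default constants were tuned once against the synthetic
palette of :mod:`alsquant.histology` and are instrument-specific, not
universal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from scipy.stats import linregress

ChannelRule = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass
class BrownRule:
    """Brown pixels have a low normalized-blue ratio B/(R+G+B) and are darker
    than the white slide background. Zero-sum (black) pixels are non-brown."""

    blue_ratio_max: float = 0.28
    intensity_max: float = 220.0


@dataclass
class QuantConfig:
    um_per_pixel: float = 0.65
    # tissue vs background: per-channel (lo, hi) inclusive intervals
    tissue_rule: ChannelRule = ((0, 235), (0, 235), (0, 245))
    # stained-soma color gate (dark DAB brown; excludes lighter diffuse stain)
    cell_rule: ChannelRule = ((70, 180), (20, 130), (0, 62))
    open_radius_um: float = 2.0
    reconstruct_radius_um: float = 3.0
    min_cell_area_um2: float = 100.0
    max_cell_area_um2: float = 1800.0
    dilate_radius_um: float = 1.0
    erode_margin_um: float = 5.0
    brown_rule: BrownRule = field(default_factory=BrownRule)
    min_cluster_area_um2: float = 180.0
    # watershed marker detection
    smooth_sigma_um: float = 1.3
    marker_prominence_um: float = 0.65  # h-extrema depth for regional minima
    marker_source: str = "distance"  # or "intensity"
    # tissue-mask cleanup
    tissue_close_radius_um: float = 2.0
    tissue_min_region_um2: float = 500.0

    def validate(self) -> None:
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")
        if self.min_cell_area_um2 >= self.max_cell_area_um2:
            raise ValueError("min_cell_area_um2 must be < max_cell_area_um2")
        if self.min_cluster_area_um2 < 0:
            raise ValueError("min_cluster_area_um2 must be >= 0")
        for r in (
            self.open_radius_um,
            self.reconstruct_radius_um,
            self.dilate_radius_um,
            self.erode_margin_um,
        ):
            if r < 0:
                raise ValueError("radii must be >= 0")


@dataclass
class TissueMask:
    mask: np.ndarray
    area_um2: float
    um_per_pixel: float


@dataclass
class CellDetectionResult:
    label_mask: np.ndarray
    count: int
    centroids: list[tuple[float, float]]
    areas_um2: list[float]


@dataclass
class StainQuant:
    positive_mask: np.ndarray
    positive_area_um2: float
    tissue_area_um2: float
    percent_area: float


@dataclass
class CountCalibration:
    slope: float
    intercept: float
    r_squared: float
    mean_bias_fraction: float


def _require_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an RGB image (rows, cols, 3); got {rgb.shape}")
    return rgb.astype(float)


def _channel_rule_mask(rgb: np.ndarray, rule: ChannelRule) -> np.ndarray:
    out = np.ones(rgb.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate(rule):
        out &= (rgb[..., ch] >= lo) & (rgb[..., ch] <= hi)
    return out


def _disk(radius_um: float, um_per_pixel: float) -> np.ndarray | None:
    r = int(round(radius_um / um_per_pixel))
    return morphology.disk(r) if r > 0 else None


def compute_tissue_mask(rgb: np.ndarray, config: QuantConfig) -> TissueMask:
    """RGB color detection + closing/opening cleanup; small debris dropped.

    An empty mask is a valid (area-0) result, not an error.
    """
    config.validate()
    rgb = _require_rgb(rgb)
    mask = _channel_rule_mask(rgb, config.tissue_rule)
    selem = _disk(config.tissue_close_radius_um, config.um_per_pixel)
    if selem is not None:
        mask = morphology.closing(mask, selem)
        mask = morphology.opening(mask, selem)
    mask = ndi.binary_fill_holes(mask)
    mask = filter_by_min_area(mask, config.tissue_min_region_um2, config.um_per_pixel)
    area = float(mask.sum()) * config.um_per_pixel**2
    return TissueMask(mask=mask, area_um2=area, um_per_pixel=config.um_per_pixel)


def erode_tissue_mask(tissue: TissueMask, margin_um: float) -> TissueMask:
    """Shrink the mask by ``margin_um`` to avoid section-edge artifacts."""
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    selem = _disk(margin_um, tissue.um_per_pixel)
    mask = tissue.mask if selem is None else morphology.erosion(tissue.mask, selem)
    return TissueMask(
        mask=mask,
        area_um2=float(mask.sum()) * tissue.um_per_pixel**2,
        um_per_pixel=tissue.um_per_pixel,
    )


def _reconstructive_close_open(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    # closing by reconstruction (fills interior holes without moving edges) ...
    dil = morphology.dilation(mask, selem)
    closed = morphology.reconstruction(dil, mask | dil, method="erosion").astype(bool)
    # ... then opening by reconstruction (drops specks, keeps marker geometry)
    ero = morphology.erosion(closed, selem)
    return morphology.reconstruction(ero, closed, method="dilation").astype(bool)


def detect_motor_neurons(
    rgb: np.ndarray, tissue: TissueMask, config: QuantConfig
) -> CellDetectionResult:
    """Three-stage soma detection.

    a) global per-channel color thresholds for strongly stained somata,
       restricted to tissue, then morphological opening;
    b) close-open with reconstruction to regularize blobs while preserving
       their geometry;
    c) regional-minima detection on the (smoothed, negated) distance
       landscape, watershed to split touching somata, dilation, and
       inclusive size filtering to [min_cell_area_um2, max_cell_area_um2].
    """
    config.validate()
    rgb = _require_rgb(rgb)
    scale = config.um_per_pixel

    # (a) color gate + opening
    mask = _channel_rule_mask(rgb, config.cell_rule) & tissue.mask
    selem = _disk(config.open_radius_um, scale)
    if selem is not None:
        mask = morphology.opening(mask, selem)

    # (b) close-open with reconstruction
    selem_r = _disk(config.reconstruct_radius_um, scale)
    if selem_r is not None and mask.any():
        mask = _reconstructive_close_open(mask, selem_r)

    if not mask.any():
        return CellDetectionResult(
            label_mask=np.zeros(rgb.shape[:2], dtype=np.int32),
            count=0,
            centroids=[],
            areas_um2=[],
        )

    # (c) marker landscape: negated distance transform (default) or the
    # smoothed stain intensity itself
    sigma_px = config.smooth_sigma_um / scale
    if config.marker_source == "distance":
        landscape = -ndi.gaussian_filter(ndi.distance_transform_edt(mask), sigma_px)
    elif config.marker_source == "intensity":
        landscape = ndi.gaussian_filter(rgb.mean(axis=2), sigma_px)
    else:
        raise ValueError(f"unknown marker_source {config.marker_source!r}")

    # regional minima of the landscape, suppressing minima shallower than the
    # configured prominence (one connected marker per soma, robust to ridge
    # shifts when neighbouring blobs get bridged)
    h = max(config.marker_prominence_um / scale, 1e-3)
    minima = morphology.h_minima(landscape, h) > 0
    markers, _ = ndi.label(minima & mask)
    labels = segmentation.watershed(landscape, markers, mask=mask)

    dil_px = config.dilate_radius_um / scale
    if dil_px > 0:
        labels = segmentation.expand_labels(labels, distance=dil_px)
        labels[~tissue.mask] = 0

    # inclusive size filter, areas in um^2
    px_area = scale**2
    out = np.zeros_like(labels)
    centroids, areas = [], []
    k = 0
    for region in measure.regionprops(labels):
        a = region.area * px_area
        if config.min_cell_area_um2 <= a <= config.max_cell_area_um2:
            k += 1
            out[labels == region.label] = k
            centroids.append(tuple(map(float, region.centroid)))
            areas.append(float(a))
    return CellDetectionResult(label_mask=out, count=k, centroids=centroids, areas_um2=areas)


def detect_brown_positive(
    rgb: np.ndarray, tissue: TissueMask, config: QuantConfig
) -> np.ndarray:
    """DAB-positive pixel mask inside tissue.

    A pixel is positive iff its normalized blue B/(R+G+B) is below the rule
    threshold AND its mean intensity is below the rule maximum (excluding
    white background); neighbouring positives are then filtered and merged
    by morphological opening-closing.
    """
    config.validate()
    rgb = _require_rgb(rgb)
    total = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        blue_ratio = np.where(total > 0, rgb[..., 2] / np.where(total > 0, total, 1), 1.0)
    positive = (
        (blue_ratio < config.brown_rule.blue_ratio_max)
        & (rgb.mean(axis=2) < config.brown_rule.intensity_max)
        & (total > 0)
        & tissue.mask
    )
    selem = _disk(config.open_radius_um, config.um_per_pixel)
    if selem is not None and positive.any():
        positive = morphology.opening(positive, selem)
        positive = morphology.closing(positive, selem)
        positive &= tissue.mask
    return positive


def filter_by_min_area(
    positive: np.ndarray, min_cluster_area_um2: float, um_per_pixel: float
) -> np.ndarray:
    """Drop connected components (8-connectivity) smaller than the cutoff."""
    if min_cluster_area_um2 < 0:
        raise ValueError("min_cluster_area_um2 must be >= 0")
    if min_cluster_area_um2 == 0 or not positive.any():
        return positive.copy()
    labels = measure.label(positive, connectivity=2)
    px_area = um_per_pixel**2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in measure.regionprops(labels):
        keep[region.label] = region.area * px_area >= min_cluster_area_um2
    return keep[labels]


def percent_area_stained(positive: np.ndarray, tissue: TissueMask) -> StainQuant:
    """Percent of tissue area that is stain-positive."""
    if tissue.area_um2 <= 0:
        raise ZeroDivisionError("tissue area is zero; percent area undefined")
    px_area = tissue.um_per_pixel**2
    inter = positive & tissue.mask
    pos_area = float(inter.sum()) * px_area
    return StainQuant(
        positive_mask=inter,
        positive_area_um2=pos_area,
        tissue_area_um2=tissue.area_um2,
        percent_area=100.0 * pos_area / tissue.area_um2,
    )


def calibrate_automated_counts(
    pairs: list[tuple[float, float]],
) -> CountCalibration:
    """OLS line automated ~ manual, plus the mean fractional undercount.

    ``mean_bias_fraction`` is mean((manual - automated) / manual): ~0.25 when
    the automated method systematically undercounts by a quarter.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (manual, automated) pairs")
    manual = np.asarray([p[0] for p in pairs], dtype=float)
    auto = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(manual <= 0):
        raise ValueError("manual counts must be > 0")
    if np.allclose(manual, manual[0]):
        raise ValueError("all manual counts identical; calibration fit degenerate")
    fit = linregress(manual, auto)
    return CountCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mean_bias_fraction=float(np.mean((manual - auto) / manual)),
    )
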