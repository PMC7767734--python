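"""Nucleus detection and the connected "nuclei map" seed image.

The detector is a standard reproducible chain: Gaussian smoothing,
global threshold (Otsu by default), watershed from intensity maxima, and
an area filter.  The nuclei map connects nuclei in close proximity by
morphological closing with a disc whose radius defaults to 1.5x the
median nearest-neighbour spacing of the detected nuclei, fills enclosed
holes, and removes small clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import feature, filters, measure, morphology, segmentation

from .io import AnalysisConfig, MultiChannelImage

logger = logging.getLogger("epicyto")


@dataclass
class NucleiSet:
    """Labelled nuclei with centroids, areas and mean intensities."""

    labels: np.ndarray           # int label image, 0 = background
    df: pd.DataFrame             # nucleus_id, row, col, area_um2, mean_intensity
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centroids(self) -> np.ndarray:
        return self.df[["row", "col"]].to_numpy()

    def median_radius_um(self) -> float:
        if len(self.df) == 0:
            return 0.0
        return float(np.median(np.sqrt(self.df["area_um2"] / np.pi)))

    def median_nn_spacing_um(self) -> float:
        """Median centroid nearest-neighbour distance in µm."""
        if len(self.df) < 2:
            return 0.0
        d, _ = cKDTree(self.centroids).query(self.centroids, k=2)
        return float(np.median(d[:, 1])) * self.pixel_size_um


def _threshold(img: np.ndarray, rule) -> float:
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule == "otsu":
        return float(filters.threshold_otsu(img))
    raise ValueError(f"unsupported threshold rule {rule!r}")


def detect_nuclei(image: MultiChannelImage, config: AnalysisConfig) -> NucleiSet:
    """Segment nuclei in the nuclei channel.

    Touching nuclei are split by a watershed seeded at smoothed-intensity
    local maxima (one per blob at the configured minimum peak distance).
    Objects smaller than ``nuclei_min_area_um2`` are discarded.
    """
    plane = image.channel("nuclei").astype(float)
    sigma = config.px(config.nuclei_smooth_sigma_um)
    smooth = ndi.gaussian_filter(plane, sigma)
    if np.ptp(smooth) == 0:  # blank plane: nothing to segment
        mask = np.zeros(plane.shape, dtype=bool)
    else:
        thr = _threshold(smooth, config.nuclei_threshold)
        mask = smooth > thr
    if not mask.any():
        return NucleiSet(
            labels=np.zeros(plane.shape, dtype=np.int32),
            df=_empty_df(),
            pixel_size_um=image.pixel_size_um,
        )
    min_area_px = max(1, int(round(config.px_area(config.nuclei_min_area_um2))))
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    min_dist = max(1, int(round(config.px(config.nuclei_peak_min_distance_um))))
    peaks = feature.peak_local_max(
        smooth, min_distance=min_dist, threshold_abs=thr, labels=measure.label(mask)
    )
    markers = np.zeros(plane.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-smooth, markers, mask=mask)
    # area filter after splitting, then relabel consecutively
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]
    df = _regionprops_df(labels, plane, image.pixel_size_um)
    logger.info("detect_nuclei: %d nuclei (sigma=%.2f um, thr=%.3g)",
                len(df), config.nuclei_smooth_sigma_um, thr)
    return NucleiSet(labels=labels, df=df, pixel_size_um=image.pixel_size_um)


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame(
        {"nucleus_id": pd.Series(dtype=int), "row": pd.Series(dtype=float),
         "col": pd.Series(dtype=float), "area_um2": pd.Series(dtype=float),
         "mean_intensity": pd.Series(dtype=float)}
    )


def _regionprops_df(labels: np.ndarray, intensity: np.ndarray,
                    pixel_size_um: float) -> pd.DataFrame:
    if labels.max() == 0:
        return _empty_df()
    props = measure.regionprops_table(
        labels, intensity_image=intensity,
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    return pd.DataFrame({
        "nucleus_id": props["label"].astype(int),
        "row": props["centroid-0"],
        "col": props["centroid-1"],
        "area_um2": props["area"] * pixel_size_um**2,
        "mean_intensity": props["intensity_mean"],
    })


def nuclei_set_from_labels(labels: np.ndarray, intensity: np.ndarray,
                           pixel_size_um: float) -> NucleiSet:
    """Build a NucleiSet from an existing label image (e.g. ground truth)."""
    return NucleiSet(labels=np.asarray(labels, dtype=np.int32),
                     df=_regionprops_df(labels, intensity, pixel_size_um),
                     pixel_size_um=pixel_size_um)


def build_nuclei_map(nuclei: NucleiSet, config: AnalysisConfig) -> np.ndarray:
    """Binary map connecting nuclei in close proximity.

    Nuclei whose gap is within the connect radius end up in one connected
    component (morphological closing); enclosed holes are filled and
    components below ``map_min_area_um2`` removed.  The result is always
    a superset of the nucleus pixels except for isolated nuclei smaller
    than the minimum component area.
    """
    mask = nuclei.labels > 0
    if not mask.any():
        return np.zeros_like(mask)
    if config.connect_radius_um is not None:
        radius_um = config.connect_radius_um
    else:
        radius_um = 1.5 * nuclei.median_nn_spacing_um()
        if radius_um <= 0:
            radius_um = 2 * nuclei.median_radius_um() + config.pixel_size_um
    radius_px = max(1, int(round(config.px(radius_um))))
    closed = morphology.closing(mask, morphology.disk(radius_px))
    filled = ndi.binary_fill_holes(closed)
    min_area_px = max(1, int(round(config.px_area(config.map_min_area_um2))))
    out = morphology.remove_small_objects(filled, max_size=min_area_px - 1)
    logger.info("build_nuclei_map: connect radius %.2f um", radius_um)
    return out


def nuclei_density_map(nuclei: NucleiSet, bandwidth_um: float) -> np.ndarray:
    """Gaussian kernel density of nucleus centroids, one unit mass each.

    The raster integral equals the nucleus count up to boundary
    truncation of the kernels.
    """
    if bandwidth_um <= 0:
        raise ValueError("bandwidth must be positive")
    out = np.zeros(nuclei.labels.shape, dtype=float)
    if len(nuclei) == 0:
        return out
    rows = np.clip(np.round(nuclei.df["row"]).astype(int), 0, out.shape[0] - 1)
    cols = np.clip(np.round(nuclei.df["col"]).astype(int), 0, out.shape[1] - 1)
    np.add.at(out, (rows, cols), 1.0)
    sigma = bandwidth_um / nuclei.pixel_size_um
    return ndi.gaussian_filter(out, sigma, mode="constant", truncate=4.0)
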