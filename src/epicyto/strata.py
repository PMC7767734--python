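"""Epidermis prediction and stratum partition.

The epidermis is predicted from two seed masks — the nuclei map and the
optically dense brightfield band — and then partitioned into basal, low
suprabasal, high suprabasal and stratum corneum.  The corneal side of
the band is the contour side with the higher area per nucleus; the
stratum corneum runs from that side to the border of the nucleated area
(the thresholded nuclei density map); the basal and low suprabasal
strata are distance bands from the basement edge whose depths adapt to
the sizes of the first and second nucleus layers.

The implementation assumes a simply connected, roughly horizontal band:
each image column intersects the epidermis in one run of pixels whose
extremes define the two contour sides.  Closed or branching contours
are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .io import AnalysisConfig, MultiChannelImage
from .nuclei import NucleiSet, nuclei_density_map

logger = logging.getLogger("epicyto")


@dataclass
class StrataMasks:
    """Disjoint pixel masks of the epidermis and its four strata.

    ``basal | low_suprabasal | high_suprabasal | stratum_corneum`` tiles
    ``epidermis`` exactly.  ``basement_edge`` is the ordered pixel path
    (row, col) along the nuclei-dense contour side; ``corneal_side`` is
    ``"top"`` or ``"bottom"``.
    """

    epidermis: np.ndarray
    basal: np.ndarray
    low_suprabasal: np.ndarray
    high_suprabasal: np.ndarray
    stratum_corneum: np.ndarray
    basement_edge: np.ndarray
    corneal_side: str

    @property
    def nucleated(self) -> np.ndarray:
        return self.basal | self.low_suprabasal | self.high_suprabasal

    def label_image(self) -> np.ndarray:
        """Codes 1=basal, 2=low, 3=high suprabasal, 4=corneum."""
        out = np.zeros(self.epidermis.shape, dtype=np.uint8)
        out[self.basal] = 1
        out[self.low_suprabasal] = 2
        out[self.high_suprabasal] = 3
        out[self.stratum_corneum] = 4
        return out

    def stratum_at(self, row: int, col: int) -> Optional[str]:
        for name in ("basal", "low_suprabasal", "high_suprabasal",
                     "stratum_corneum"):
            if getattr(self, name)[row, col]:
                return name
        return None

    def geometry_report(self, pixel_size_um: float) -> dict:
        rep = {}
        for name in ("basal", "low_suprabasal", "high_suprabasal",
                     "stratum_corneum", "epidermis"):
            mask = getattr(self, name)
            cols = mask.any(axis=0)
            thickness = mask.sum(axis=0)[cols] * pixel_size_um if cols.any() else []
            rep[name] = {
                "area_um2": float(mask.sum()) * pixel_size_um**2,
                "mean_thickness_um": float(np.mean(thickness)) if len(thickness) else 0.0,
            }
        return rep


def brightfield_area(image: MultiChannelImage, config: AnalysisConfig) -> np.ndarray:
    """Binary mask of the optically dense (inverted-brightfield-high) band."""
    bf = image.channel("brightfield").astype(float)
    inverted = bf.max() - bf
    smooth = ndi.gaussian_filter(inverted, config.px(config.bf_smooth_sigma_um))
    if np.ptp(smooth) == 0:  # featureless plane: no tissue
        return np.zeros(bf.shape, dtype=bool)
    rule = config.bf_threshold
    if isinstance(rule, (int, float)):
        thr = float(rule)
    elif rule == "otsu":
        thr = float(filters.threshold_otsu(smooth))
    else:
        raise ValueError(f"unsupported threshold rule {rule!r}")
    mask = smooth > thr
    if not mask.any():
        return mask
    mask = ndi.binary_fill_holes(mask)
    min_area_px = max(1, int(round(config.px_area(config.bf_min_area_um2))))
    return morphology.remove_small_objects(mask, max_size=min_area_px - 1)


def predict_epidermis(
    nuclei_map: np.ndarray,
    bf_area: np.ndarray,
    manual_add: Optional[np.ndarray] = None,
    manual_remove: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Grow the nuclei map seed over the brightfield area.

    Returns the union of ``bf_area`` connected components that contain
    seed pixels (geodesic growth of the seed inside the mask); dense
    dermal components without nuclei are excluded.  Optional manual
    correction masks are applied by set union/difference afterwards.
    """
    nuclei_map = np.asarray(nuclei_map, dtype=bool)
    bf_area = np.asarray(bf_area, dtype=bool)
    if nuclei_map.shape != bf_area.shape:
        raise ValueError(
            f"shape mismatch: nuclei map {nuclei_map.shape} vs brightfield "
            f"area {bf_area.shape}"
        )
    seed = nuclei_map & bf_area
    comp, n = ndi.label(bf_area)
    hit = np.unique(comp[seed])
    hit = hit[hit > 0]
    out = np.isin(comp, hit)
    if manual_add is not None:
        out |= np.asarray(manual_add, dtype=bool)
    if manual_remove is not None:
        out &= ~np.asarray(manual_remove, dtype=bool)
    return out


def _column_extent(epidermis: np.ndarray):
    """Per-column top/bottom rows of the band; -1 where the band is absent."""
    any_col = epidermis.any(axis=0)
    top = np.where(any_col, epidermis.argmax(axis=0), -1)
    bottom = np.where(any_col,
                      epidermis.shape[0] - 1 - epidermis[::-1].argmax(axis=0), -1)
    return any_col, top, bottom


def partition_strata(
    epidermis: np.ndarray,
    nuclei: NucleiSet,
    config: AnalysisConfig,
) -> StrataMasks:
    """Partition the epidermis into the four strata.

    Steps: (a) the contour side with the higher area per nucleus within a
    fixed-depth margin is the corneal side, the other the basement side;
    (b) the stratum corneum runs from the corneal side to the border of
    the nucleated area (density support); (c) the basal stratum is the
    distance band from the basement edge covering the first nucleus
    layer, (d) the low suprabasal stratum the band covering the second
    layer, and (e) the high suprabasal stratum the remainder.
    """
    epidermis = np.asarray(epidermis, dtype=bool)
    if not epidermis.any():
        raise ValueError("epidermis mask is empty")
    ncomp = ndi.label(epidermis)[1]
    if ncomp != 1:
        raise ValueError(
            f"epidermis must be a single simply connected band, got {ncomp} "
            "components"
        )
    H, W = epidermis.shape
    inside = np.zeros(len(nuclei), dtype=bool)
    rows = np.clip(np.round(nuclei.df["row"]).astype(int), 0, H - 1).to_numpy()
    cols = np.clip(np.round(nuclei.df["col"]).astype(int), 0, W - 1).to_numpy()
    inside = epidermis[rows, cols]
    if inside.sum() == 0:
        raise ValueError("no nucleus lies inside the epidermis")

    any_col, top, bottom = _column_extent(epidermis)
    rr = np.arange(H)[:, None]

    # (a) corneal side by area per nucleus within a margin of depth
    # side_margin_factor x median nucleus diameter along each side.
    diam_px = 2 * nuclei.median_radius_um() / config.pixel_size_um
    margin = max(2, int(round(config.side_margin_factor * diam_px)))
    top_margin = epidermis & (rr <= top[None, :] + margin) & any_col[None, :]
    bottom_margin = epidermis & (rr >= bottom[None, :] - margin) & any_col[None, :]
    n_top = int(np.sum(top_margin[rows[inside], cols[inside]]))
    n_bottom = int(np.sum(bottom_margin[rows[inside], cols[inside]]))
    app_top = top_margin.sum() / max(n_top, 1e-9)
    app_bottom = bottom_margin.sum() / max(n_bottom, 1e-9)
    corneal_side = "top" if app_top >= app_bottom else "bottom"
    logger.info("partition_strata: corneal side %s (area/nucleus top %.1f, "
                "bottom %.1f)", corneal_side, app_top, app_bottom)

    # (b) stratum corneum: corneal side of the nuclei-density support.
    # Only the support component connected to the basement side counts
    # as the nucleated area: isolated density blobs (e.g. retained
    # corneal nuclei in parakeratosis) must not drag the corneum
    # boundary outward.
    basement_rows = bottom if corneal_side == "top" else top
    density = nuclei_density_map(nuclei, config.density_bandwidth_um)
    support = density >= config.density_support_fraction * density.max()
    sup_epi = support & epidermis
    r_med_px = nuclei.median_radius_um() / config.pixel_size_um
    near_base = np.zeros_like(epidermis)
    cidx_all = np.flatnonzero(any_col)
    near_base[basement_rows[cidx_all], cidx_all] = True
    near_base = ndi.binary_dilation(
        near_base, iterations=max(2, int(round(r_med_px)) + 2))
    comp, _ = ndi.label(sup_epi)
    hit = np.unique(comp[near_base & sup_epi])
    main_sup = np.isin(comp, hit[hit > 0])
    has_main = main_sup.any(axis=0)
    if corneal_side == "top":
        edge_row = np.where(has_main, main_sup.argmax(axis=0), H)
        corneum = epidermis & (rr < edge_row[None, :])
    else:
        edge_row = np.where(has_main,
                            H - 1 - main_sup[::-1].argmax(axis=0), -1)
        corneum = epidermis & (rr > edge_row[None, :])

    # basement edge path and distance from it
    edge = np.zeros_like(epidermis)
    cidx = np.flatnonzero(any_col)
    edge[basement_rows[cidx], cidx] = True
    dist = ndi.distance_transform_edt(~edge)
    basement_edge = np.column_stack([basement_rows[cidx], cidx])

    # (c)-(d) nucleus layers by distance from the basement edge
    nucleated = epidermis & ~corneum
    r_med = nuclei.median_radius_um() / config.pixel_size_um
    d_cent = dist[rows, cols]
    eligible = inside & nucleated[rows, cols]
    d_el = d_cent[eligible]
    dmax = ndi.labeled_comprehension(
        dist, nuclei.labels, nuclei.df["nucleus_id"].to_numpy(), np.max, float, 0.0
    )
    first = eligible & (d_cent <= d_el.min() + 2 * r_med)
    if first.sum() == 0:
        warnings.warn("epidermis too thin to host one nucleus row; "
                      "returning basal-only partition")
        basal = nucleated
        low = np.zeros_like(basal)
        high = np.zeros_like(basal)
        return StrataMasks(epidermis, basal, low, high, corneum,
                           basement_edge, corneal_side)
    depth_b = float(np.percentile(dmax[first], 95)) + 1.0
    second = eligible & ~first & (d_cent <= depth_b + 2 * r_med + 1)
    if second.sum() == 0:
        # single nucleus row: the whole nucleated band is basal
        basal = nucleated
        low = np.zeros_like(basal)
        high = np.zeros_like(basal)
        return StrataMasks(epidermis, basal, low, high, corneum,
                           basement_edge, corneal_side)
    basal = nucleated & (dist <= depth_b)
    depth_l = float(np.percentile(dmax[second], 95)) + 1.0
    low = nucleated & (dist > depth_b) & (dist <= depth_l)
    high = nucleated & ~basal & ~low
    return StrataMasks(epidermis, basal, low, high, corneum,
                       basement_edge, corneal_side)
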