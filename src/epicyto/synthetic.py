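"""Synthetic epidermis sections with full ground truth.

The generator emulates the features of a skin cross-section that the
pipeline exploits: a single tight row of basal nuclei riding on a wavy
basement membrane, suprabasal nuclei of decreasing density, an anucleate
stratum corneum with strong brightfield contrast, and a
differentiation-dependent formazan gradient written into the brightfield
channel as attenuation (darker = more precipitate), so that the inverted
brightfield recovers per-cell enzymatic activity.  Immunofluorescence
channels follow per-stratum intensity distributions (K14-high basal,
K10-high suprabasal), with a configurable fraction of K14-negative
basal cells standing in for non-epithelial residents such as
melanocytes.

Geometry is organised per image column.  With ``B(c)`` the basement
membrane row of column ``c`` and ``d = B(c) - row`` the height above the
membrane (in pixels), the ground-truth strata are horizontal-in-``d``
bands whose depths follow from the nucleus geometry:

* basal: ``0 <= d < 2r+2`` (one nucleus layer sitting on the membrane),
* low suprabasal: the next ``row_spacing`` band (first suprabasal row),
* high suprabasal: everything up to the nucleated border plus a small
  gap,
* stratum corneum: an anucleate band of fixed thickness on top.

Every generated nucleus centroid lies inside its true stratum band, and
the bands tile the ground-truth epidermis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import MultiChannelImage

STRATA = ("basal", "low_suprabasal", "high_suprabasal")

#: reaction time (minutes) at which a cell's accumulated attenuation
#: equals its nominal activity value; sets the per-cell kinetic rate.
REFERENCE_TIME_MIN = 25.0


@dataclass
class SimulationParams:
    """All knobs of the generator, lengths in µm unless noted.

    Defaults describe a homeostatic section: an activity gradient that
    increases toward the granular (upper suprabasal) layer, 6 % of basal
    cells with background-level K14, and no UV, tracker or treatment
    effects.
    """

    # geometry
    width_px: int = 600
    height_px: int = 140
    pixel_size_um: float = 1.0
    bm_amplitude_um: float = 6.0
    bm_wavelength_um: float = 150.0
    bm_roughness_um: float = 1.0
    dermis_depth_um: float = 40.0

    # cell placement
    nucleus_radius_um: float = 3.0
    basal_spacing_um: float = 8.0
    n_suprabasal_rows: int = 4
    suprabasal_spacing_um: float = 9.5
    row_spacing_um: float = 9.0
    density_decay: float = 0.85       # keep-probability factor per extra row
    jitter_um: float = 1.0
    corneum_thickness_um: float = 15.0
    corneum_gap_um: float = 5.0       # anucleate gap below the corneum

    # activity (formazan attenuation, arbitrary units)
    activity_means: Dict[str, float] = field(
        default_factory=lambda: {
            "basal": 30.0, "low_suprabasal": 45.0, "high_suprabasal": 60.0
        }
    )
    activity_sd: float = 5.0
    activity_baseline: float = 2.0    # assay-independent background attenuation

    # marker intensity distributions (arbitrary units above IF background)
    k14_negative_basal_fraction: float = 0.06
    marker_pos_mean: float = 650.0
    marker_pos_sd: float = 60.0
    marker_neg_mean: float = 20.0
    marker_neg_sd: float = 8.0

    # gamma-H2AX (nuclear)
    gh2ax_pos_fraction: float = 0.0
    gh2ax_pos_mean: float = 600.0
    gh2ax_pos_sd: float = 150.0
    gh2ax_neg_mean: float = 25.0
    gh2ax_neg_sd: float = 8.0

    # perturbations
    activity_increment: Optional[Dict[str, float]] = None  # UV / drug effect
    gh2ax_coupling_slope: float = 0.0  # extra attenuation per gh2ax unit

    # labelled subpopulation (cell tracker)
    tracker_fraction: float = 0.0
    tracker_strata: Tuple[str, ...] = ("low_suprabasal", "high_suprabasal")
    tracker_activity_offset: float = 0.0
    tracker_pos_mean: float = 700.0
    tracker_pos_sd: float = 80.0

    # off-target nuclei
    corneal_nuclei_fraction: float = 0.0  # parakeratosis, fraction of basal count
    dermal_nuclei_per_mm: float = 10.0
    debris_blobs: int = 2
    debris_radius_um: float = 6.0

    # optics
    bf_background: float = 210.0
    bf_band_level: float = 165.0
    bf_corneum_level: float = 115.0
    nuclei_amplitude: float = 900.0
    nuclei_background: float = 40.0
    if_background: float = 15.0
    noise_sd: float = 6.0
    bf_noise_sd: float = 4.0
    inhibited_rate: float = 0.1       # attenuation/min under DHEA

    seed: int = 0

    def validate(self) -> None:
        px = self.pixel_size_um
        if px <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("k14_negative_basal_fraction", "gh2ax_pos_fraction",
                     "tracker_fraction", "corneal_nuclei_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(v < 0 for v in self.activity_means.values()):
            raise ValueError("activity means must be non-negative")
        if self.basal_spacing_um <= 0:
            raise ValueError("basal_spacing_um must be positive")
        if self.width_px < self.basal_spacing_um / px:
            raise ValueError("image too narrow for a single basal cell")
        # total epidermis thickness must fit above the dermis
        total = (self._nucleated_top_px() + self.corneum_gap_um / px
                 + self.corneum_thickness_um / px)
        if total + self.dermis_depth_um / px + self.bm_amplitude_um / px + 4 \
                > self.height_px:
            raise ValueError(
                "geometrically impossible parameters: epidermis plus dermis "
                "thicker than the image"
            )

    # -- derived band edges (pixels above the basement membrane) -----------
    def _r_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_size_um

    def _basal_depth_px(self) -> int:
        return int(round(2 * self._r_px() + 2))

    def _row_spacing_px(self) -> float:
        return self.row_spacing_um / self.pixel_size_um

    def _nucleated_top_px(self) -> float:
        """Maximum height above the membrane reached by any nucleus pixel."""
        d0 = self._r_px() + 1
        return d0 + self.n_suprabasal_rows * self._row_spacing_px() + self._r_px()

    def band_edges(self) -> Dict[str, Tuple[int, int]]:
        """Half-open ``d`` ranges ``[lo, hi)`` of the true strata bands."""
        db = self._basal_depth_px()
        rs = int(round(self._row_spacing_px()))
        gap = int(round(self.corneum_gap_um / self.pixel_size_um))
        ct = int(round(self.corneum_thickness_um / self.pixel_size_um))
        corneum_start = int(round(self._nucleated_top_px())) + gap
        edges = {}
        n = self.n_suprabasal_rows
        if n == 0:
            edges["basal"] = (0, corneum_start)
            edges["low_suprabasal"] = (corneum_start, corneum_start)
            edges["high_suprabasal"] = (corneum_start, corneum_start)
        elif n == 1:
            edges["basal"] = (0, db)
            edges["low_suprabasal"] = (db, corneum_start)
            edges["high_suprabasal"] = (corneum_start, corneum_start)
        else:
            edges["basal"] = (0, db)
            edges["low_suprabasal"] = (db, db + rs)
            edges["high_suprabasal"] = (db + rs, corneum_start)
        edges["stratum_corneum"] = (corneum_start, corneum_start + ct)
        return edges


@dataclass
class GroundTruth:
    """The generator's own record of what it drew."""

    cells: pd.DataFrame            # one row per nucleus (incl. dermal/corneal)
    masks: Dict[str, np.ndarray]   # epidermis + four strata, boolean
    basement_row: np.ndarray       # per-column basement membrane row
    nucleus_labels: np.ndarray     # label image of true nuclei
    stratum_activity: Dict[str, float]   # area-weighted painted activity
    stratum_rate: Optional[Dict[str, float]] = None  # for time courses
    params: Optional[SimulationParams] = None

    @property
    def epidermal_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["stratum"].isin(STRATA)]


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _basement_profile(p: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    x = np.arange(p.width_px)
    px = p.pixel_size_um
    base = p.height_px - p.dermis_depth_um / px
    phase = rng.uniform(0, 2 * np.pi)
    wave = (p.bm_amplitude_um / px) * np.sin(2 * np.pi * x * px / p.bm_wavelength_um + phase)
    rough = ndi.gaussian_filter1d(rng.normal(0, 1, p.width_px), 25) * (p.bm_roughness_um / px)
    prof = np.round(base + wave + rough).astype(int)
    return np.clip(prof, 0, p.height_px - 2)


def _place_cells(p: SimulationParams, rng: np.random.Generator,
                 bm: np.ndarray) -> pd.DataFrame:
    """Place nucleus centroids row by row and assign true strata."""
    px = p.pixel_size_um
    r = p._r_px()
    jit = p.jitter_um / px
    rows: List[dict] = []

    def _bm_at(c: float) -> float:
        return float(bm[int(np.clip(round(c), 0, p.width_px - 1))])

    # basal row: fixed arc-length (here: horizontal) spacing on the membrane
    step = p.basal_spacing_um / px
    xs = np.arange(step / 2, p.width_px - step / 4, step)
    for x in xs:
        c = x + rng.uniform(-jit, jit)
        d = (r + 1) + rng.uniform(-jit, jit)
        rows.append({"stratum": "basal", "col": c, "row": _bm_at(c) - d})

    # suprabasal rows with decaying density
    sstep = p.suprabasal_spacing_um / px
    for j in range(1, p.n_suprabasal_rows + 1):
        keep = p.density_decay ** (j - 1)
        offset = rng.uniform(0, sstep)
        xs = np.arange(offset, p.width_px, sstep)
        stratum = "low_suprabasal" if j == 1 else "high_suprabasal"
        for x in xs:
            if rng.uniform() > keep:
                continue
            c = x + rng.uniform(-jit, jit)
            d = (r + 1) + j * p._row_spacing_px() + rng.uniform(-jit, jit)
            rows.append({"stratum": stratum, "col": c, "row": _bm_at(c) - d})

    # parakeratosis: retained nuclei inside the corneum band
    if p.corneal_nuclei_fraction > 0:
        n_basal = sum(1 for rec in rows if rec["stratum"] == "basal")
        n_corneal = int(round(p.corneal_nuclei_fraction * n_basal))
        lo, hi = p.band_edges()["stratum_corneum"]
        for _ in range(n_corneal):
            c = rng.uniform(2, p.width_px - 2)
            d = rng.uniform((lo + hi) / 2 + 2, hi - r - 1)
            rows.append({"stratum": "corneal", "col": c, "row": _bm_at(c) - d})

    # sparse dermal nuclei well below the membrane
    n_dermal = int(round(p.dermal_nuclei_per_mm * p.width_px * px / 1000.0))
    depth_max = p.dermis_depth_um / px - r - 2
    for _ in range(n_dermal):
        if depth_max <= 4 * r:
            break
        c = rng.uniform(2, p.width_px - 2)
        d = -rng.uniform(4 * r, depth_max)  # below the membrane
        rows.append({"stratum": "dermal", "col": c, "row": _bm_at(c) - d})

    df = pd.DataFrame(rows)
    df["row"] = df["row"].clip(1, p.height_px - 2)
    df["col"] = df["col"].clip(1, p.width_px - 2)
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    return df


def _exact_count_subset(rng: np.random.Generator, eligible: np.ndarray,
                        fraction: float) -> np.ndarray:
    """Boolean mask selecting round(fraction * n_eligible) of the eligible."""
    idx = np.flatnonzero(eligible)
    k = int(round(fraction * idx.size))
    out = np.zeros(eligible.size, dtype=bool)
    if k > 0:
        out[rng.choice(idx, size=min(k, idx.size), replace=False)] = True
    return out


def _assign_phenotypes(p: SimulationParams, rng: np.random.Generator,
                       cells: pd.DataFrame) -> pd.DataFrame:
    n = len(cells)
    strat = cells["stratum"].to_numpy()
    is_basal = strat == "basal"
    is_supra = np.isin(strat, ("low_suprabasal", "high_suprabasal"))
    is_epi = is_basal | is_supra

    # K14: high in basal keratinocytes; a fixed fraction of basal cells is
    # K14-negative (melanocyte-like) and also K10-negative.
    k14_neg_basal = _exact_count_subset(rng, is_basal, p.k14_negative_basal_fraction)
    k14_pos = is_basal & ~k14_neg_basal
    k10_pos = is_supra
    cells["k14_pos"] = k14_pos
    cells["k10_pos"] = k10_pos

    def _draw(mask_pos, mean_pos, sd_pos):
        v = rng.normal(p.marker_neg_mean, p.marker_neg_sd, n)
        v[mask_pos] = rng.normal(mean_pos, sd_pos, int(mask_pos.sum()))
        v[~is_epi] = 0.0
        return np.clip(v, 0, None)

    cells["k14_value"] = _draw(k14_pos, p.marker_pos_mean, p.marker_pos_sd)
    cells["k10_value"] = _draw(k10_pos, p.marker_pos_mean, p.marker_pos_sd)

    # gamma-H2AX, nuclear
    gh_pos = _exact_count_subset(rng, is_epi, p.gh2ax_pos_fraction)
    gh = rng.normal(p.gh2ax_neg_mean, p.gh2ax_neg_sd, n)
    gh[gh_pos] = rng.normal(p.gh2ax_pos_mean, p.gh2ax_pos_sd, int(gh_pos.sum()))
    gh = np.clip(gh, 0, None)
    gh[~is_epi] = 0.0
    cells["gh2ax_pos"] = gh_pos
    cells["gh2ax_value"] = gh

    # tracker label, restricted to the allowed strata
    eligible = np.isin(strat, p.tracker_strata) if p.tracker_fraction > 0 else np.zeros(n, bool)
    n_target = int(round(p.tracker_fraction * int(is_epi.sum())))
    idx = np.flatnonzero(eligible)
    tracker = np.zeros(n, bool)
    if n_target > 0 and idx.size > 0:
        tracker[rng.choice(idx, size=min(n_target, idx.size), replace=False)] = True
    cells["tracker_pos"] = tracker
    tv = rng.normal(p.marker_neg_mean, p.marker_neg_sd, n)
    tv[tracker] = rng.normal(p.tracker_pos_mean, p.tracker_pos_sd, int(tracker.sum()))
    tv[~is_epi] = 0.0
    cells["tracker_value"] = np.clip(tv, 0, None)

    # activity = stratum mean + cell noise + perturbations
    act = np.zeros(n)
    for s in STRATA:
        m = strat == s
        act[m] = rng.normal(p.activity_means[s], p.activity_sd, int(m.sum()))
        if p.activity_increment:
            act[m] += p.activity_increment.get(s, 0.0)
    act += p.gh2ax_coupling_slope * gh
    act[tracker] += p.tracker_activity_offset
    act[~is_epi] = 0.0
    cells["activity"] = np.clip(act, 0, None)
    return cells


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _paint_nucleus_labels(p: SimulationParams, cells: pd.DataFrame) -> np.ndarray:
    labels = np.zeros((p.height_px, p.width_px), dtype=np.int32)
    r = p._r_px()
    yy, xx = np.mgrid[-int(np.ceil(r)):int(np.ceil(r)) + 1,
                      -int(np.ceil(r)):int(np.ceil(r)) + 1]
    disc = yy**2 + xx**2 <= r**2
    dy, dx = np.nonzero(disc)
    dy = dy - int(np.ceil(r))
    dx = dx - int(np.ceil(r))
    H, W = labels.shape
    for cid, row, col in zip(cells["cell_id"], cells["row"], cells["col"]):
        ys = np.clip(np.round(row + dy).astype(int), 0, H - 1)
        xs = np.clip(np.round(col + dx).astype(int), 0, W - 1)
        labels[ys, xs] = cid
    return labels


def _strata_masks(p: SimulationParams, bm: np.ndarray) -> Dict[str, np.ndarray]:
    rows = np.arange(p.height_px)[:, None]
    d = bm[None, :] - rows  # height above the membrane, per pixel
    edges = p.band_edges()
    masks = {}
    for name, (lo, hi) in edges.items():
        masks[name] = (d >= lo) & (d < hi)
    masks["epidermis"] = (d >= 0) & (d < edges["stratum_corneum"][1])
    return masks


def _voronoi_paint(seed_labels: np.ndarray, values: np.ndarray,
                   region: np.ndarray) -> np.ndarray:
    """Paint per-cell values over the nearest-nucleus partition of region.

    ``values`` is indexed by label id (index 0 unused).  The footprint of
    each cell is its Euclidean nearest-nucleus cell restricted to
    ``region``, which emulates confluent cytoplasm filling the tissue.
    """
    if not seed_labels.any():
        return np.zeros(seed_labels.shape, dtype=float)
    _, (iy, ix) = ndi.distance_transform_edt(seed_labels == 0, return_indices=True)
    nearest = seed_labels[iy, ix]
    out = np.zeros(seed_labels.shape, dtype=float)
    out[region] = values[nearest[region]]
    return out


@dataclass
class _Layout:
    params: SimulationParams
    cells: pd.DataFrame
    bm: np.ndarray
    masks: Dict[str, np.ndarray]
    nucleus_labels: np.ndarray      # all nuclei (incl. dermal/corneal)
    epi_labels: np.ndarray          # epidermal nuclei only, for painting
    nucleated_band: np.ndarray      # basal | low | high
    value_index: Dict[str, np.ndarray]


def _build_layout(p: SimulationParams, rng: np.random.Generator) -> _Layout:
    bm = _basement_profile(p, rng)
    cells = _place_cells(p, rng, bm)
    cells = _assign_phenotypes(p, rng, cells)
    masks = _strata_masks(p, bm)
    nucleus_labels = _paint_nucleus_labels(p, cells)
    epi = cells["stratum"].isin(STRATA).to_numpy()
    epi_cells = cells[epi]
    epi_labels = np.where(np.isin(nucleus_labels, epi_cells["cell_id"].to_numpy()),
                          nucleus_labels, 0)
    band = masks["basal"] | masks["low_suprabasal"] | masks["high_suprabasal"]
    n = len(cells)
    vindex = {}
    for colname in ("activity", "k14_value", "k10_value", "tracker_value",
                    "gh2ax_value"):
        v = np.zeros(n + 1)
        v[cells["cell_id"].to_numpy()] = cells[colname].to_numpy()
        vindex[colname] = v
    return _Layout(p, cells, bm, masks, nucleus_labels, epi_labels, band, vindex)


def _render_nuclei_channel(lay: _Layout, rng: np.random.Generator) -> np.ndarray:
    p = lay.params
    sigma = p._r_px() / 1.9
    img = np.zeros((p.height_px, p.width_px))
    half = int(np.ceil(4 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    H, W = img.shape
    for row, col in zip(lay.cells["row"], lay.cells["col"]):
        r0, c0 = int(round(row)), int(round(col))
        blob = p.nuclei_amplitude * np.exp(
            -(((yy + r0 - row) ** 2) + ((xx + c0 - col) ** 2)) / (2 * sigma**2)
        )
        ys = slice(max(r0 - half, 0), min(r0 + half + 1, H))
        xs = slice(max(c0 - half, 0), min(c0 + half + 1, W))
        by = slice(ys.start - (r0 - half), blob.shape[0] - ((r0 + half + 1) - ys.stop))
        bx = slice(xs.start - (c0 - half), blob.shape[1] - ((c0 + half + 1) - xs.stop))
        img[ys, xs] += blob[by, bx]
    img += p.nuclei_background
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, img.shape)
    return np.clip(img, 0, None)


def _render_brightfield(lay: _Layout, attenuation: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    p = lay.params
    bf = np.full((p.height_px, p.width_px), p.bf_background, dtype=float)
    bf[lay.masks["epidermis"]] = p.bf_band_level
    bf[lay.masks["stratum_corneum"]] = p.bf_corneum_level
    bf -= attenuation
    # dermal debris: optically dense specks with no nuclei nearby
    if p.debris_blobs > 0:
        rr = p.debris_radius_um / p.pixel_size_um
        yy, xx = np.mgrid[0:p.height_px, 0:p.width_px]
        for _ in range(p.debris_blobs):
            c = rng.uniform(rr + 2, p.width_px - rr - 2)
            bmr = lay.bm[int(round(c))]
            lo = bmr + 3 * rr
            hi = p.height_px - rr - 1
            if lo >= hi:
                continue
            r0 = rng.uniform(lo, hi)
            bf[(yy - r0) ** 2 + (xx - c) ** 2 <= rr**2] = 140.0
    if p.bf_noise_sd > 0:
        bf += rng.normal(0, p.bf_noise_sd, bf.shape)
    return np.clip(bf, 0, None)


def _render_if(lay: _Layout, value_key: str, nuclear: bool,
               rng: np.random.Generator) -> np.ndarray:
    p = lay.params
    values = lay.value_index[value_key]
    if nuclear:
        paint = np.zeros((p.height_px, p.width_px))
        m = lay.epi_labels > 0
        paint[m] = values[lay.epi_labels[m]]
    else:
        paint = _voronoi_paint(lay.epi_labels, values, lay.nucleated_band)
    img = paint + p.if_background
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, img.shape)
    return np.clip(img, 0, None)


def _painted_stratum_means(lay: _Layout, values: np.ndarray) -> Dict[str, float]:
    painted = _voronoi_paint(lay.epi_labels, values, lay.nucleated_band)
    out = {}
    for s in STRATA:
        m = lay.masks[s]
        out[s] = float(painted[m].mean()) if m.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_section(params: SimulationParams) -> Tuple[MultiChannelImage, GroundTruth]:
    """Generate one multichannel section plus its ground truth.

    The same ``params`` (including ``seed``) always produce bit-identical
    output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lay = _build_layout(params, rng)
    act_values = lay.value_index["activity"] + params.activity_baseline
    act_values[0] = 0.0
    attenuation = _voronoi_paint(lay.epi_labels, act_values, lay.nucleated_band)
    planes = {
        "nuclei": _render_nuclei_channel(lay, rng),
        "brightfield": _render_brightfield(lay, attenuation, rng),
        "k14": _render_if(lay, "k14_value", nuclear=False, rng=rng),
        "k10": _render_if(lay, "k10_value", nuclear=False, rng=rng),
        "gh2ax": _render_if(lay, "gh2ax_value", nuclear=True, rng=rng),
        "tracker": _render_if(lay, "tracker_value", nuclear=False, rng=rng),
    }
    image = MultiChannelImage(planes=planes, pixel_size_um=params.pixel_size_um)
    gt = GroundTruth(
        cells=lay.cells,
        masks={k: lay.masks[k] for k in
               ("epidermis", "basal", "low_suprabasal", "high_suprabasal",
                "stratum_corneum")},
        basement_row=lay.bm,
        nucleus_labels=lay.nucleus_labels,
        stratum_activity=_painted_stratum_means(lay, lay.value_index["activity"]),
        params=params,
    )
    return image, gt


def generate_timecourse(
    params: SimulationParams,
    timepoints: Sequence[float],
    inhibited: bool = False,
) -> Tuple[List[MultiChannelImage], GroundTruth]:
    """Emulate an enzymatic reaction time course on one section.

    Formazan attenuation accumulates linearly at each cell's rate
    ``rate = activity / REFERENCE_TIME_MIN``; with ``inhibited=True``
    (DHEA negative control) accumulation is clamped to a small constant
    background rate.  The cell layout and all static channels are shared
    across timepoints; brightfield noise is redrawn per timepoint.
    """
    params.validate()
    tp = np.asarray(list(timepoints), dtype=float)
    if tp.size == 0:
        raise ValueError("empty timepoint list")
    if np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if tp.min() < 0 or tp.max() > 60:
        raise ValueError("timepoints must lie within [0, 60] minutes")

    rng = np.random.default_rng(params.seed)
    lay = _build_layout(params, rng)
    nuclei_plane = _render_nuclei_channel(lay, rng)

    n = len(lay.cells)
    rates = np.zeros(n + 1)
    cid = lay.cells["cell_id"].to_numpy()
    if inhibited:
        epi = lay.cells["stratum"].isin(STRATA).to_numpy()
        rates[cid[epi]] = params.inhibited_rate
    else:
        rates[cid] = lay.cells["activity"].to_numpy() / REFERENCE_TIME_MIN
    cells = lay.cells.copy()
    cells["rate"] = rates[cid]

    images = []
    noise_rngs = rng.spawn(len(tp))
    for t, nrng in zip(tp, noise_rngs):
        att_values = params.activity_baseline + rates * t
        att_values[0] = 0.0
        attenuation = _voronoi_paint(lay.epi_labels, att_values, lay.nucleated_band)
        bf = _render_brightfield(lay, attenuation, nrng)
        images.append(MultiChannelImage(
            planes={"nuclei": nuclei_plane.copy(), "brightfield": bf},
            pixel_size_um=params.pixel_size_um,
        ))
    gt = GroundTruth(
        cells=cells,
        masks={k: lay.masks[k] for k in
               ("epidermis", "basal", "low_suprabasal", "high_suprabasal",
                "stratum_corneum")},
        basement_row=lay.bm,
        nucleus_labels=lay.nucleus_labels,
        stratum_activity=_painted_stratum_means(lay, lay.value_index["activity"]),
        stratum_rate=_painted_stratum_means(lay, rates[:]),
        params=params,
    )
    return images, gt


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_UV_INCREMENT = {"basal": 12.0, "low_suprabasal": 20.0, "high_suprabasal": 10.0}


def preset_params(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Named parameter sets for the study conditions.

    ``homeostatic``
        untreated section with the default activity gradient.
    ``uv``
        per-stratum activity increments (largest in the low suprabasal
        stratum), 40 % gamma-H2AX-positive cells, and a positive
        activity/gamma-H2AX coupling slope.
    ``prelabelled``
        20 % tracker-labelled, UV-pretreated cells restricted to the
        suprabasal strata with a negative activity offset.
    ``prelabelled_control``
        labelled but untreated cells (no activity offset, all strata).
    ``timecourse``
        homeostatic layout for :func:`generate_timecourse`.
    ``metformin``
        uniform activity increment across all strata (2-day treatment).
    ``metformin_7d``
        no activity increment, mild parakeratosis.
    """
    base = dict(seed=seed)
    if name == "homeostatic" or name == "timecourse":
        pass
    elif name == "uv":
        base.update(activity_increment=dict(_UV_INCREMENT),
                    gh2ax_pos_fraction=0.4,
                    gh2ax_coupling_slope=0.04)
    elif name == "prelabelled":
        base.update(tracker_fraction=0.2,
                    tracker_strata=("low_suprabasal", "high_suprabasal"),
                    tracker_activity_offset=-10.0)
    elif name == "prelabelled_control":
        base.update(tracker_fraction=0.2,
                    tracker_strata=STRATA,
                    tracker_activity_offset=0.0)
    elif name == "metformin":
        base.update(activity_increment={s: 25.0 for s in STRATA})
    elif name == "metformin_7d":
        base.update(corneal_nuclei_fraction=0.05, corneum_thickness_um=24.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return SimulationParams(**base)
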