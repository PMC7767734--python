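"""Flow-cytometry-style per-cell measurement, gating and summaries.

Every predicted cell yields per-channel means over its nuclear and
cytoplasmic pixel sets plus the formazan optical density
``activity_od`` — the cytoplasmic mean of the inverted brightfield,
anchored at the modal intensity of the non-tissue background so that OD
is comparable across sections.  Gating rules (absolute, Otsu on the
measured distribution, or background + k*sd of a control group) set
boolean flags; thresholds are recorded in the table metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from skimage import filters

from .cells import CellMasks
from .io import MultiChannelImage
from .nuclei import NucleiSet

logger = logging.getLogger("epicyto")

STRATA_ORDER = ("basal", "low_suprabasal", "high_suprabasal", "corneal")


def _label_means(labels: np.ndarray, plane: np.ndarray, n: int) -> np.ndarray:
    """Mean of ``plane`` per label 1..n; NaN for empty labels."""
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1).astype(float)
    sums = np.bincount(flat, weights=plane.ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means


def background_level(bf: np.ndarray, bf_area: Optional[np.ndarray] = None) -> float:
    """Modal brightfield intensity of the non-tissue background."""
    if bf_area is not None and (~bf_area).any():
        pool = bf[~np.asarray(bf_area, dtype=bool)]
    else:
        pool = bf.ravel()
    ints = np.round(pool).astype(np.int64)
    ints = ints - ints.min()
    return float(np.bincount(ints).argmax() + np.round(pool).astype(np.int64).min())


def measure_cells(
    cells: CellMasks,
    nuclei: NucleiSet,
    image: MultiChannelImage,
    bf_area: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Build the per-cell measurement table.

    Columns: ``cell_id``, ``stratum``, centroid, nucleus/cell areas, and
    for every channel the nuclear, cytoplasmic and whole-cell means
    (``<role>_nuc_mean`` / ``<role>_cyto_mean`` / ``<role>_cell_mean``).
    ``activity_od`` is the cytoplasmic mean of ``I_max - brightfield``
    floored at zero; cells whose nucleus fills the whole mask get NaN
    cytoplasmic means and ``cyto_missing=True``.
    """
    labels = cells.labels
    ids = cells.table["cell_id"].to_numpy()
    if len(ids) == 0:
        return _empty_table(image)
    n = int(max(labels.max(initial=0), nuclei.labels.max(initial=0)))
    px2 = image.pixel_size_um**2

    nuc_of_cell = np.where(np.isin(nuclei.labels, ids), nuclei.labels, 0)
    cyto = np.where(nuc_of_cell == 0, labels, 0)

    cell_counts = np.bincount(labels.ravel(), minlength=n + 1)
    nuc_counts = np.bincount(nuc_of_cell.ravel(), minlength=n + 1)
    cyto_counts = np.bincount(cyto.ravel(), minlength=n + 1)

    data = {
        "cell_id": ids,
        "stratum": cells.table["stratum"].to_numpy(),
        "row": cells.table["row"].to_numpy(),
        "col": cells.table["col"].to_numpy(),
        "nucleus_area_um2": nuc_counts[ids] * px2,
        "cell_area_um2": cell_counts[ids] * px2,
    }
    for role, plane in image.planes.items():
        plane = plane.astype(float)
        key = role.replace("other:", "")
        data[f"{key}_nuc_mean"] = _label_means(nuc_of_cell, plane, n)[ids]
        data[f"{key}_cyto_mean"] = _label_means(cyto, plane, n)[ids]
        data[f"{key}_cell_mean"] = _label_means(labels, plane, n)[ids]

    table = pd.DataFrame(data)
    table["cyto_missing"] = cyto_counts[ids] == 0

    if "brightfield" in image:
        bf = image.channel("brightfield").astype(float)
        i_max = background_level(bf, bf_area)
        od = _label_means(cyto, i_max - bf, n)[ids]
        table["activity_od"] = np.clip(od, 0, None)
        table.attrs["od_anchor"] = i_max
    logger.info("measure_cells: %d cells measured", len(table))
    return table


def _empty_table(image: MultiChannelImage) -> pd.DataFrame:
    cols = ["cell_id", "stratum", "row", "col", "nucleus_area_um2",
            "cell_area_um2"]
    for role in image.planes:
        key = role.replace("other:", "")
        cols += [f"{key}_nuc_mean", f"{key}_cyto_mean", f"{key}_cell_mean"]
    cols += ["cyto_missing"]
    if "brightfield" in image:
        cols += ["activity_od"]
    return pd.DataFrame({c: [] for c in cols})


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def gate_cells(
    table: pd.DataFrame,
    channel: str,
    rule="otsu",
    compartment: str = "cyto",
    k: float = 3.0,
    control: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Flag cells positive for a channel; records the threshold used.

    ``rule`` is a number (absolute threshold), ``"otsu"`` (Otsu's method
    on the measured distribution), or ``"bg+k*sd"`` (mean + ``k``
    standard deviations of the ``control`` subset, which must then be
    supplied as a boolean mask over the table).
    """
    col = f"{channel}_{compartment}_mean"
    if col not in table.columns:
        raise KeyError(f"channel column {col!r} not measured")
    values = table[col].to_numpy(dtype=float)
    if isinstance(rule, (int, float)):
        thr = float(rule)
        rule_name = "absolute"
    elif rule == "otsu":
        finite = values[np.isfinite(values)]
        thr = float(filters.threshold_otsu(finite))
        rule_name = "otsu"
    elif rule == "bg+k*sd":
        if control is None:
            raise ValueError("bg+k*sd gating requires a control group mask")
        ctrl = values[np.asarray(control, dtype=bool)]
        thr = float(np.nanmean(ctrl) + k * np.nanstd(ctrl))
        rule_name = f"bg+{k}*sd"
    else:
        raise ValueError(f"unsupported gate rule {rule!r}")
    out = table.copy()
    out.attrs = dict(table.attrs)
    out[f"{channel}_pos"] = values > thr
    gates = dict(out.attrs.get("gates", {}))
    gates[channel] = {"rule": rule_name, "threshold": thr, "compartment": compartment}
    out.attrs["gates"] = gates
    logger.info("gate_cells: %s %s threshold %.4g", channel, rule_name, thr)
    return out


def stratum_distribution(
    table: pd.DataFrame,
    subset: Optional[np.ndarray] = None,
) -> pd.Series:
    """Fraction of (a subset of) cells per stratum; sums to 1 if non-empty.

    An empty subset returns all zeros with ``attrs['empty']=True``.
    """
    sel = table if subset is None else table[np.asarray(subset, dtype=bool)]
    cats = [s for s in STRATA_ORDER
            if s in set(table["stratum"]) or s in ("basal", "low_suprabasal",
                                                   "high_suprabasal")]
    counts = sel["stratum"].value_counts()
    out = pd.Series({c: float(counts.get(c, 0)) for c in cats})
    total = out.sum()
    if total == 0:
        out.attrs["empty"] = True
        return out
    out = out / total
    out.attrs["empty"] = False
    return out


@dataclass
class ScatterSummary:
    """2-D histogram of one stratum plus its 95 % density region."""

    hist: np.ndarray
    xedges: np.ndarray
    yedges: np.ndarray
    contour: Optional[np.ndarray]   # boolean bin mask, None if n too small
    n: int
    coverage: float                 # fraction of points inside the contour


def scatter_summary(
    table: pd.DataFrame,
    channel_x: str,
    channel_y: str,
    by_stratum: bool = True,
    bins: int = 50,
    level: float = 0.95,
    min_cells: int = 10,
) -> Dict[str, ScatterSummary]:
    """Binned density per stratum plus the smallest bin set holding
    ``level`` of that stratum's cells.

    All groups share one set of bin edges so contours are comparable.
    Groups with fewer than ``min_cells`` cells keep the histogram but
    omit the contour.
    """
    x = table[channel_x].to_numpy(dtype=float)
    y = table[channel_y].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    xedges = np.histogram_bin_edges(x[ok], bins=bins)
    yedges = np.histogram_bin_edges(y[ok], bins=bins)
    groups = table["stratum"].unique() if by_stratum else ["all"]
    out = {}
    for g in groups:
        sel = ok & ((table["stratum"] == g).to_numpy() if by_stratum else True)
        hist, _, _ = np.histogram2d(x[sel], y[sel], bins=(xedges, yedges))
        n = int(sel.sum())
        contour, cov = (None, 0.0)
        if n >= min_cells:
            contour, cov = _density_region(hist, level)
        out[str(g)] = ScatterSummary(hist, xedges, yedges, contour, n, cov)
    return out


def _density_region(hist: np.ndarray, level: float) -> Tuple[np.ndarray, float]:
    """Smallest set of highest-count bins holding >= level of the mass."""
    total = hist.sum()
    flat = np.sort(hist.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, level * total) + 1)
    thr = flat[k - 1]
    region = hist >= thr
    # ties at the threshold count may overshoot; trim surplus tie bins
    inside = hist[region].sum()
    if thr > 0:
        surplus = int((inside - cum[k - 1]) / thr) if inside > cum[k - 1] else 0
        if surplus:
            ties = np.argwhere(region & (hist == thr))
            for idx in ties[:surplus]:
                if inside - thr >= level * total:
                    region[tuple(idx)] = False
                    inside -= thr
    return region, float(inside / total) if total else 0.0
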