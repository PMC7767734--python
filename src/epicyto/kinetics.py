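"""Enzymatic-assay time courses: linear-range fits and inhibitor baselines.

A :class:`KineticSeries` holds per-timepoint stratum-level mean optical
densities; :func:`fit_timecourse` fits an ordinary least-squares line
and reports whether the accumulation is linear over the largest prefix
window (the assay's useful range), and
:func:`subtract_inhibited_baseline` removes the inhibitor (DHEA)
negative-control signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .histocytometry import background_level
from .io import MultiChannelImage


@dataclass
class KineticSeries:
    """One activity time course (minutes vs mean OD)."""

    timepoints: np.ndarray
    values: np.ndarray
    label: str = ""
    n_floored: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.ndim != 1 or self.values.shape != self.timepoints.shape:
            raise ValueError("timepoints and values must be 1-D and matched")
        if self.timepoints.size and np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class KineticFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float
    verdict: str                 # "linear", "nonlinear" or "flat"
    window: int                  # number of leading points in the fit


def fit_timecourse(series: KineticSeries, r2_threshold: float = 0.95) -> KineticFit:
    """OLS line through the largest linear prefix of the series.

    The linear range is the largest prefix window of at least three
    points whose fit reaches ``r2_threshold``; the verdict is
    ``"linear"`` if the full series qualifies, ``"nonlinear"`` if only a
    prefix (or none) does, and ``"flat"`` for a constant series (where
    R-squared is undefined).
    """
    t, y = series.timepoints, series.values
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.allclose(y, y[0]):
        return KineticFit(slope=0.0, intercept=float(y[0]), r_squared=float("nan"),
                          stderr=0.0, verdict="flat", window=t.size)
    best = None
    for k in range(t.size, 2, -1):
        res = sps.linregress(t[:k], y[:k])
        r2 = res.rvalue**2
        if r2 >= r2_threshold:
            best = (k, res)
            break
        if best is None:
            best = (k, res)  # keep the full-series fit as fallback
    k, res = best
    verdict = "linear" if (k == t.size and res.rvalue**2 >= r2_threshold) else "nonlinear"
    return KineticFit(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=float(res.rvalue**2), stderr=float(res.stderr),
                      verdict=verdict, window=k)


def subtract_inhibited_baseline(
    series: KineticSeries, inhibited: KineticSeries
) -> KineticSeries:
    """Subtract the DHEA negative-control series, flooring at zero.

    The number of floored points is reported on the result rather than
    silently clipped away, since negative corrected OD indicates
    mis-registration or an implausible baseline.
    """
    if not np.array_equal(series.timepoints, inhibited.timepoints):
        raise ValueError("series and inhibited baseline have different timepoints")
    corrected = series.values - inhibited.values
    floored = int(np.sum(corrected < 0))
    corrected = np.clip(corrected, 0, None)
    return replace(series, values=corrected, n_floored=floored,
                   label=(series.label + "-corrected").strip("-"))


# ---------------------------------------------------------------------------
# building series from images
# ---------------------------------------------------------------------------

def stratum_od_series(
    images: Sequence[MultiChannelImage],
    timepoints: Sequence[float],
    strata: "StrataMasks | dict",
    bf_area: Optional[np.ndarray] = None,
    strata_names: Sequence[str] = ("basal", "low_suprabasal", "high_suprabasal"),
) -> Dict[str, KineticSeries]:
    """Mean inverted-brightfield OD over fixed stratum masks per timepoint.

    ``strata`` is a :class:`~epicyto.strata.StrataMasks` or any mapping
    from stratum name to a boolean mask.

    The stratum-mask mean is the default per-timepoint quantity; a
    cell-level alternative can be built by running the full pipeline per
    timepoint and averaging ``activity_od`` instead.
    """
    if len(images) != len(list(timepoints)):
        raise ValueError("one image per timepoint required")
    out = {}
    for name in strata_names:
        mask = strata[name] if isinstance(strata, dict) else getattr(strata, name)
        vals = []
        for img in images:
            bf = img.channel("brightfield").astype(float)
            i_max = background_level(bf, bf_area)
            vals.append(float((i_max - bf)[mask].mean()) if mask.any() else 0.0)
        out[name] = KineticSeries(np.asarray(list(timepoints), dtype=float),
                                  np.asarray(vals), label=name)
    return out
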