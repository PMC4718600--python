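"""Algorithmic (model-free) extraction of tuning-curve shape features.

Features are scalar descriptors computed by fixed rules from a *sampled*
curve -- either the 12 measured trial-mean rates themselves (the "direct
method") or a parametric fit sampled on a fine uniform grid.  Because the
rules only ever see discrete samples, the same code serves both routes.

Conventions (all curves are assumed aligned so the uni-condition maximum /
the right peak sits at 240 degrees):

* the left peak is searched in [0, 180), the right peak in [180, 360);
* argmax/argmin ties resolve to the smallest angle, and peak ties to the
  sample closest to 120 (left) / 240 (right);
* InnerMinimum is the minimum strictly between the two peak angles,
  OuterMinimumAngle the minimum on the wrapped outer arc;
* bandwidths walk outward from a peak, without interpolation, while the
  GlobalMinimum-subtracted rate stays at or above X% of that peak's
  PeakToPeak;
* peak skewness is the weighted third standardized moment of angle over the
  peak's support arc, with GlobalMinimum-subtracted rates as weights (a
  documented reconstruction; see docs/methods.md);
* GlobalMinimumAngle is reported in (-120, 240] degrees;
* "normalized" variants divide rate-unit features by the cell's maximum
  uni-condition firing rate.

Features that do not apply to a modality (e.g. CircularVariance for bimodal
curves, left-peak features for unimodal ones) are returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .fitting import FitResult

__all__ = [
    "RATE_FEATURES",
    "ANGLE_FEATURES",
    "SampledCurve",
    "sample_fit",
    "extract",
    "zscore_agreement",
    "feature_names",
]

#: features in s^-1 that get a "normalized" counterpart
RATE_FEATURES = (
    "GlobalMinimum",
    "GlobalMaximum",
    "Maximum_left",
    "Maximum_right",
    "PeakToPeak_left",
    "PeakToPeak_right",
    "InnerMinimum",
)

ANGLE_FEATURES = (
    "GlobalMinimumAngle",
    "GlobalMaximumAngle",
    "MaximumAngle_left",
    "MaximumAngle_right",
    "InnerMinimumAngle",
    "OuterMinimumAngle",
    "InnerWidth_left",
    "InnerWidth_right",
    "DeltaInnerWidth",
    "OuterWidth_left",
    "OuterWidth_right",
    "DeltaOuterWidth",
    "Bandwidth25_left",
    "Bandwidth25_right",
    "Bandwidth50_left",
    "Bandwidth50_right",
    "Bandwidth75_left",
    "Bandwidth75_right",
)

OTHER_FEATURES = (
    "Skewness_right",
    "minusSkewness_left",
    "DeltaSkewness",
    "CircularVariance",
    "DeltaPeakToPeak",
)


def feature_names(include_normalized: bool = True) -> list[str]:
    names = list(RATE_FEATURES) + list(ANGLE_FEATURES) + list(OTHER_FEATURES)
    if include_normalized:
        names += ["normalized" + f for f in RATE_FEATURES]
    return names


@dataclass
class SampledCurve:
    """A tuning profile as discrete (angle, rate) samples on a uniform grid."""

    thetas: np.ndarray
    values: np.ndarray
    source: str = "direct"  # "direct" | "fitted"

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.thetas.shape != self.values.shape:
            raise ValueError("thetas and values must have the same length")
        if np.any(np.diff(self.thetas) <= 0):
            raise ValueError("thetas must be strictly increasing")

    @property
    def resolution(self) -> float:
        return 360.0 / len(self.thetas)


def sample_fit(fit: FitResult, resolution: float = 1.0) -> SampledCurve:
    """Evaluate a fitted model on a uniform grid 0, r, 2r, ... < 360."""
    if not fit.converged:
        raise ValueError("cannot sample a non-converged fit")
    if resolution <= 0 or abs(360.0 / resolution - round(360.0 / resolution)) > 1e-9:
        raise ValueError(f"resolution {resolution} does not divide 360")
    thetas = np.arange(0.0, 360.0, resolution)
    values = models.tuning_value(fit.family, fit.modality, fit.params, thetas)
    return SampledCurve(thetas=thetas, values=np.asarray(values), source="fitted")


# ---------------------------------------------------------------------------
# extraction primitives
# ---------------------------------------------------------------------------

def _peak_index(thetas, values, mask, target):
    """Index of the maximum within ``mask``; ties toward ``target`` angle."""
    idxs = np.flatnonzero(mask)
    vmax = values[idxs].max()
    cand = idxs[values[idxs] == vmax]
    dist = np.minimum(np.abs(thetas[cand] - target), 360.0 - np.abs(thetas[cand] - target))
    order = np.lexsort((thetas[cand], dist))
    return int(cand[order[0]])


def _bandwidth(values, peak_idx, gmin, ptp, frac, resolution):
    """Sample-resolution outward walk; width between outermost survivors."""
    n = len(values)
    thr = frac * ptp
    steps_r = 0
    while steps_r < n - 1 and values[(peak_idx + steps_r + 1) % n] - gmin >= thr:
        steps_r += 1
    steps_l = 0
    while steps_l < n - 1 and values[(peak_idx - steps_l - 1) % n] - gmin >= thr:
        steps_l += 1
    return min(steps_l + steps_r, n - 1) * resolution


def _weighted_skew(angles, weights):
    sw = weights.sum()
    if sw <= 0:
        return np.nan
    mu = np.sum(weights * angles) / sw
    m2 = np.sum(weights * (angles - mu) ** 2) / sw
    if m2 <= 0:
        return np.nan
    m3 = np.sum(weights * (angles - mu) ** 3) / sw
    return float(m3 / m2 ** 1.5)


def _arc_indices(start_idx, end_idx, n):
    """Circular index walk start..end inclusive, in increasing direction."""
    steps = (end_idx - start_idx) % n
    return (start_idx + np.arange(steps + 1)) % n


def _report_min_angle(angle: float) -> float:
    """Map an angle to the reporting range (-120, 240]."""
    return angle - 360.0 if angle > 240.0 else angle


# ---------------------------------------------------------------------------
# main extraction
# ---------------------------------------------------------------------------

def extract(curve: SampledCurve, modality: str, uni_max: float | None = None) -> dict:
    """Extract all applicable shape features from a sampled curve.

    ``uni_max`` is the cell's maximum uni-condition firing rate, used for
    the normalized feature variants (NaN when absent).
    """
    thetas, values = curve.thetas, curve.values
    n = len(values)
    res = curve.resolution
    out = {name: np.nan for name in feature_names()}

    gmin_idx = int(np.argmin(values))
    gmax_idx = int(np.argmax(values))
    gmin = float(values[gmin_idx])
    gmax = float(values[gmax_idx])
    out["GlobalMinimum"] = gmin
    out["GlobalMaximum"] = gmax
    out["GlobalMinimumAngle"] = _report_min_angle(float(thetas[gmin_idx]))
    out["GlobalMaximumAngle"] = float(thetas[gmax_idx])

    if modality == "unimodal":
        out["Maximum_right"] = gmax
        out["MaximumAngle_right"] = float(thetas[gmax_idx])
        ptp = gmax - gmin
        out["PeakToPeak_right"] = ptp
        for x in (25, 50, 75):
            out[f"Bandwidth{x}_right"] = _bandwidth(values, gmax_idx, gmin, ptp, x / 100.0, res)
        sw = values.sum()
        if sw > 0:
            resultant = np.abs(np.sum(values * np.exp(1j * models.OMEGA * thetas)))
            out["CircularVariance"] = float(1.0 - resultant / sw)
    elif modality == "bimodal":
        left_mask = thetas < 180.0
        right_mask = ~left_mask
        li = _peak_index(thetas, values, left_mask, 120.0)
        ri = _peak_index(thetas, values, right_mask, 240.0)
        ma_l, ma_r = float(thetas[li]), float(thetas[ri])
        out["Maximum_left"] = float(values[li])
        out["Maximum_right"] = float(values[ri])
        out["MaximumAngle_left"] = ma_l
        out["MaximumAngle_right"] = ma_r
        out["PeakToPeak_left"] = float(values[li]) - gmin
        out["PeakToPeak_right"] = float(values[ri]) - gmin
        out["DeltaPeakToPeak"] = out["PeakToPeak_right"] - out["PeakToPeak_left"]

        inner = np.flatnonzero((thetas > ma_l) & (thetas < ma_r))
        if inner.size:
            ii = int(inner[np.argmin(values[inner])])
        else:  # adjacent peaks: fall back to the smaller peak sample
            ii = li if values[li] <= values[ri] else ri
        out["InnerMinimum"] = float(values[ii])
        out["InnerMinimumAngle"] = float(thetas[ii])

        outer = np.flatnonzero((thetas > ma_r) | (thetas < ma_l))
        if outer.size:
            oi = int(outer[np.argmin(values[outer])])
        else:
            oi = li if values[li] <= values[ri] else ri
        oma = float(thetas[oi])
        out["OuterMinimumAngle"] = oma

        out["InnerWidth_left"] = float(thetas[ii]) - ma_l
        out["InnerWidth_right"] = ma_r - float(thetas[ii])
        out["DeltaInnerWidth"] = out["InnerWidth_right"] - out["InnerWidth_left"]
        out["OuterWidth_left"] = (ma_l - oma) % 360.0
        out["OuterWidth_right"] = (oma - ma_r) % 360.0
        out["DeltaOuterWidth"] = out["OuterWidth_right"] - out["OuterWidth_left"]

        for x in (25, 50, 75):
            out[f"Bandwidth{x}_left"] = _bandwidth(
                values, li, gmin, out["PeakToPeak_left"], x / 100.0, res)
            out[f"Bandwidth{x}_right"] = _bandwidth(
                values, ri, gmin, out["PeakToPeak_right"], x / 100.0, res)

        # peak skewness over support arcs (inner->outer through each peak)
        right_arc = _arc_indices(ii, oi, n)
        ang_r = float(thetas[ii]) + np.arange(right_arc.size) * res
        out["Skewness_right"] = _weighted_skew(ang_r, values[right_arc] - gmin)
        left_arc = _arc_indices(oi, ii, n)
        ang_l = oma + np.arange(left_arc.size) * res
        sk_l = _weighted_skew(ang_l, values[left_arc] - gmin)
        out["minusSkewness_left"] = -sk_l if np.isfinite(sk_l) else np.nan
        if np.isfinite(out["Skewness_right"]) and np.isfinite(out["minusSkewness_left"]):
            out["DeltaSkewness"] = out["Skewness_right"] - out["minusSkewness_left"]
    else:
        raise ValueError(f"unknown modality: {modality!r}")

    if uni_max is not None and uni_max > 0:
        for name in RATE_FEATURES:
            out["normalized" + name] = out[name] / uni_max
    return out


def zscore_agreement(model_values: dict[str, np.ndarray],
                     direct_values: dict[str, np.ndarray]) -> dict[str, float]:
    """Population z-score of a model's feature means against the direct method.

    z(F) = (mean(F)_model - mean(F)_direct) / std(F)_direct, computed per
    feature across cells (NaN-aware).  Features whose direct-method spread is
    zero (or with < 2 finite values) come back as NaN.
    """
    out: dict[str, float] = {}
    for feat, direct in direct_values.items():
        if feat not in model_values:
            continue
        d = np.asarray(direct, dtype=float)
        m = np.asarray(model_values[feat], dtype=float)
        d_ok = d[np.isfinite(d)]
        m_ok = m[np.isfinite(m)]
        if d_ok.size < 2 or m_ok.size < 1:
            out[feat] = np.nan
            continue
        sd = np.std(d_ok, ddof=1)
        out[feat] = np.nan if sd == 0 else float((m_ok.mean() - d_ok.mean()) / sd)
    return out
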