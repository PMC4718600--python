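"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops,
enumeration, closed forms) so it stays independent of the library code it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

OMEGA = 2.0 * math.pi / 360.0


# ---------------------------------------------------------------------------
# wrapped-model summation
# ---------------------------------------------------------------------------

def principal_angle(delta):
    """Wrap an angle difference into [-180, 180)."""
    return (delta + 180.0) % 360.0 - 180.0


def wrapped_gaussian_sum(theta, a, b, c, d, n_wrap=4):
    delta = principal_angle(theta - c)
    total = 0.0
    for i in range(-n_wrap, n_wrap + 1):
        total += math.exp(-0.5 * ((delta + 360.0 * i) / b) ** 2)
    return a * total + d


def wrapped_bell_sum(theta, a, b, c, d, s, n_wrap=4):
    def term(x):
        return 1.0 / (1.0 + abs(x / b) ** (2 * s))

    delta = principal_angle(theta - c)
    alpha = sum(term(360.0 * i) for i in range(-n_wrap, n_wrap + 1))
    beta = sum(term(180.0 + 360.0 * i) for i in range(-n_wrap, n_wrap + 1))
    tot = sum(term(delta + 360.0 * i) for i in range(-n_wrap, n_wrap + 1))
    return a * (tot - beta) / (alpha - beta) + d


# ---------------------------------------------------------------------------
# weighted linear least squares via the normal equations
# ---------------------------------------------------------------------------

def fourier_normal_equations(thetas, y, sigma, order):
    """Solve (A^T A) p = A^T b directly; independent of the SVD route."""
    rows = []
    for t in thetas:
        row = [1.0]
        for h in range(1, order + 1):
            row += [math.cos(h * OMEGA * t), math.sin(h * OMEGA * t)]
        rows.append(row)
    X = np.array(rows)
    A = X / np.asarray(sigma)[:, None]
    b = np.asarray(y) / np.asarray(sigma)
    return np.linalg.solve(A.T @ A, A.T @ b)


# ---------------------------------------------------------------------------
# exact rank / distribution tests by enumeration
# ---------------------------------------------------------------------------

def _rankdata(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_h(values, group_a_idx):
    """Two-group Kruskal-Wallis H with tie correction, written from scratch."""
    n = len(values)
    ranks = _rankdata(values)
    in_a = set(group_a_idx)
    ra = sum(r for i, r in enumerate(ranks) if i in in_a)
    rb = sum(r for i, r in enumerate(ranks) if i not in in_a)
    na = len(in_a)
    nb = n - na
    h = 12.0 / (n * (n + 1)) * (ra * ra / na + rb * rb / nb) - 3.0 * (n + 1)
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    tie = 1.0 - sum(c ** 3 - c for c in counts.values()) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def exact_kw_p(a, b):
    """Permutation p-value of the two-group KW statistic by full enumeration."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    h_obs = kw_h(pooled, range(na))
    count = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if kw_h(pooled, idx) >= h_obs - 1e-12:
            count += 1
    return count / total


def ks_d(a, b):
    """Two-sample KS statistic by scanning the pooled support."""
    support = sorted(set(a) | set(b))
    d = 0.0
    for x in support:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def exact_ks_p(a, b):
    """Permutation p-value of the two-sample KS D by full enumeration."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    d_obs = ks_d(a, b)
    count = total = 0
    for idx in combinations(range(n), na):
        total += 1
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in set(idx)]
        if ks_d(ga, gb) >= d_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# regularized upper incomplete gamma by quadrature
# ---------------------------------------------------------------------------

def gamma_tail_quadrature(shape, x):
    from scipy.integrate import quad

    val, _ = quad(lambda t: t ** (shape - 1.0) * math.exp(-t), x, math.inf)
    return val / math.gamma(shape)


# ---------------------------------------------------------------------------
# exhaustive feature-extraction scan
# ---------------------------------------------------------------------------

def feature_scan(thetas, values, modality, uni_max=None):
    """Plain-loop reference implementation of the feature extraction rules."""
    thetas = [float(t) for t in thetas]
    values = [float(v) for v in values]
    n = len(values)
    res = 360.0 / n
    out = {}

    gmin = min(values)
    gmax = max(values)
    gmin_angle = min(t for t, v in zip(thetas, values) if v == gmin)
    gmax_angle = min(t for t, v in zip(thetas, values) if v == gmax)
    out["GlobalMinimum"] = gmin
    out["GlobalMaximum"] = gmax
    out["GlobalMinimumAngle"] = gmin_angle - 360.0 if gmin_angle > 240.0 else gmin_angle
    out["GlobalMaximumAngle"] = gmax_angle

    def bandwidth(peak_i, ptp, frac):
        thr = frac * ptp
        right = 0
        while right < n - 1 and values[(peak_i + right + 1) % n] - gmin >= thr:
            right += 1
        left = 0
        while left < n - 1 and values[(peak_i - left - 1) % n] - gmin >= thr:
            left += 1
        return min(left + right, n - 1) * res

    if modality == "unimodal":
        peak_i = thetas.index(gmax_angle)
        out["Maximum_right"] = gmax
        out["MaximumAngle_right"] = gmax_angle
        out["PeakToPeak_right"] = gmax - gmin
        for x in (25, 50, 75):
            out[f"Bandwidth{x}_right"] = bandwidth(peak_i, gmax - gmin, x / 100.0)
        total = sum(values)
        if total > 0:
            re = sum(v * math.cos(OMEGA * t) for t, v in zip(thetas, values))
            im = sum(v * math.sin(OMEGA * t) for t, v in zip(thetas, values))
            out["CircularVariance"] = 1.0 - math.hypot(re, im) / total
        return out

    def peak(side_lo, side_hi, target):
        cand = [i for i in range(n) if side_lo <= thetas[i] < side_hi]
        vmax = max(values[i] for i in cand)
        best = None
        for i in cand:
            if values[i] != vmax:
                continue
            dist = abs(thetas[i] - target)
            dist = min(dist, 360.0 - dist)
            key = (dist, thetas[i])
            if best is None or key < best[0]:
                best = (key, i)
        return best[1]

    li = peak(0.0, 180.0, 120.0)
    ri = peak(180.0, 360.0, 240.0)
    ma_l, ma_r = thetas[li], thetas[ri]
    out["Maximum_left"] = values[li]
    out["Maximum_right"] = values[ri]
    out["MaximumAngle_left"] = ma_l
    out["MaximumAngle_right"] = ma_r
    out["PeakToPeak_left"] = values[li] - gmin
    out["PeakToPeak_right"] = values[ri] - gmin
    out["DeltaPeakToPeak"] = out["PeakToPeak_right"] - out["PeakToPeak_left"]

    inner = [i for i in range(n) if ma_l < thetas[i] < ma_r]
    if inner:
        vmin = min(values[i] for i in inner)
        ii = min((i for i in inner if values[i] == vmin), key=lambda i: thetas[i])
    else:
        ii = li if values[li] <= values[ri] else ri
    out["InnerMinimum"] = values[ii]
    out["InnerMinimumAngle"] = thetas[ii]

    outer = [i for i in range(n) if thetas[i] > ma_r or thetas[i] < ma_l]
    if outer:
        vmin = min(values[i] for i in outer)
        oi = min((i for i in outer if values[i] == vmin), key=lambda i: thetas[i])
    else:
        oi = li if values[li] <= values[ri] else ri
    oma = thetas[oi]
    out["OuterMinimumAngle"] = oma

    out["InnerWidth_left"] = thetas[ii] - ma_l
    out["InnerWidth_right"] = ma_r - thetas[ii]
    out["DeltaInnerWidth"] = out["InnerWidth_right"] - out["InnerWidth_left"]
    out["OuterWidth_left"] = (ma_l - oma) % 360.0
    out["OuterWidth_right"] = (oma - ma_r) % 360.0
    out["DeltaOuterWidth"] = out["OuterWidth_right"] - out["OuterWidth_left"]

    for x in (25, 50, 75):
        out[f"Bandwidth{x}_left"] = bandwidth(li, out["PeakToPeak_left"], x / 100.0)
        out[f"Bandwidth{x}_right"] = bandwidth(ri, out["PeakToPeak_right"], x / 100.0)

    def arc_skew(start_i, end_i):
        steps = (end_i - start_i) % n
        angles, weights = [], []
        for j in range(steps + 1):
            angles.append(thetas[start_i] + j * res)
            weights.append(values[(start_i + j) % n] - gmin)
        sw = sum(weights)
        if sw <= 0:
            return float("nan")
        mu = sum(w * t for w, t in zip(weights, angles)) / sw
        m2 = sum(w * (t - mu) ** 2 for w, t in zip(weights, angles)) / sw
        if m2 <= 0:
            return float("nan")
        m3 = sum(w * (t - mu) ** 3 for w, t in zip(weights, angles)) / sw
        return m3 / m2 ** 1.5

    out["Skewness_right"] = arc_skew(ii, oi)
    sk_l = arc_skew(oi, ii)
    out["minusSkewness_left"] = -sk_l if not math.isnan(sk_l) else float("nan")
    if not math.isnan(out["Skewness_right"]) and not math.isnan(out["minusSkewness_left"]):
        out["DeltaSkewness"] = out["Skewness_right"] - out["minusSkewness_left"]

    if uni_max:
        for name in ("GlobalMinimum", "GlobalMaximum", "Maximum_left", "Maximum_right",
                     "PeakToPeak_left", "PeakToPeak_right", "InnerMinimum"):
            if name in out:
                out["normalized" + name] = out[name] / uni_max
    return out
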