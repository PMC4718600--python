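"""Nonparametric comparison machinery.

Two tests are used throughout:

* **feature-pair comparisons** across conditions/paradigms pool one feature
  value per cell into two groups and apply a two-sample Kruskal-Wallis rank
  test (with tie correction; exact permutation p-value for small samples,
  chi^2 approximation otherwise).  A comparison is "significant" when
  p < 0.05; the direction of change comes from the group medians, falling
  back to means on an exact median tie.

* **specific effects**: per cell and per stimulus direction, the trial
  ensembles of two conditions are compared with a two-sample
  Kolmogorov-Smirnov test (exact small-sample p-values).  Significant
  stimulus- and cell-resolved differences are the "specific effects";
  enhancement/suppression again follows the medians (means on ties).

No multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ALPHA",
    "PairResult",
    "kruskal_two_sample",
    "compare_feature_pair",
    "model_agreement_histogram",
    "specific_effects",
    "population_specific_summary",
    "benjamini_hochberg",
]

ALPHA = 0.05

#: largest number of group assignments enumerated for the exact KW p-value
EXACT_KW_LIMIT = 20000

#: largest combined sample size for which the KS test uses the exact method
EXACT_KS_LIMIT = 25


@dataclass
class PairResult:
    statistic: float
    p: float
    significant: bool
    direction: int  # +1: group b larger, -1: group a larger, 0: indistinguishable
    n_a: int
    n_b: int


def _kw_statistic(ranks: np.ndarray, n_a: int, tie_term: float) -> float:
    """Tie-corrected two-group Kruskal-Wallis H from pooled ranks."""
    n = len(ranks)
    ra = ranks[:n_a].sum()
    rb = ranks[n_a:].sum()
    n_b = n - n_a
    h = 12.0 / (n * (n + 1)) * (ra ** 2 / n_a + rb ** 2 / n_b) - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _tie_correction(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)


def kruskal_two_sample(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-group Kruskal-Wallis statistic and p-value.

    ``method`` is one of ``auto`` (exact when the number of assignments is
    enumerable, asymptotic otherwise), ``exact`` (full permutation
    enumeration of group memberships) or ``asymptotic`` (chi^2 tail with one
    degree of freedom, as in :func:`scipy.stats.kruskal`).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    n, n_a = len(pooled), len(a)
    if method == "auto":
        method = "exact" if comb(n, n_a) <= EXACT_KW_LIMIT else "asymptotic"
    if method == "asymptotic":
        h, p = stats.kruskal(a, b)
        return float(h), float(p)
    if method != "exact":
        raise ValueError(f"unknown method: {method!r}")
    ranks = stats.rankdata(pooled)
    tie = _tie_correction(pooled)
    h_obs = _kw_statistic(ranks, n_a, tie)
    count = 0
    total = 0
    idx = np.arange(n)
    for group_a in combinations(idx, n_a):
        sel = np.array(group_a)
        rest = np.setdiff1d(idx, sel, assume_unique=True)
        h = _kw_statistic(np.concatenate([ranks[sel], ranks[rest]]), n_a, tie)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return float(h_obs), count / total


def _direction(a: np.ndarray, b: np.ndarray) -> int:
    """+1 when group b sits higher (median; means on an exact median tie)."""
    med_a, med_b = np.median(a), np.median(b)
    if med_b > med_a:
        return 1
    if med_b < med_a:
        return -1
    mean_a, mean_b = a.mean(), b.mean()
    if mean_b > mean_a:
        return 1
    if mean_b < mean_a:
        return -1
    return 0


def compare_feature_pair(values_a, values_b, alpha: float = ALPHA,
                         method: str = "auto") -> PairResult:
    """Compare one feature between two groups of cells (NaN values dropped)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 non-NA values per group")
    # exact enumeration is infeasible for population-sized groups
    if method == "auto" and comb(len(a) + len(b), len(a)) > EXACT_KW_LIMIT:
        method = "asymptotic"
    h, p = kruskal_two_sample(a, b, method=method)
    return PairResult(
        statistic=h, p=p, significant=p < alpha,
        direction=_direction(a, b), n_a=len(a), n_b=len(b),
    )


def model_agreement_histogram(pair_results_by_method: dict[str, dict[str, bool]],
                              direct_verdicts: dict[str, bool] | None = None):
    """Count, per feature pair, how many methods find a significant effect.

    ``pair_results_by_method`` maps method name -> {pair id -> significant}.
    Returns ``(counts, histogram)`` where ``counts`` maps pair id -> count
    and ``histogram`` is a length ``n_methods + 1`` array.  When
    ``direct_verdicts`` is given, two additional histograms stratify pairs
    by the direct method's verdict.
    """
    methods = list(pair_results_by_method)
    if not methods:
        raise ValueError("no methods given")
    common = set.intersection(*(set(v) for v in pair_results_by_method.values()))
    skipped = set.union(*(set(v) for v in pair_results_by_method.values())) - common
    for pair in skipped:
        log.warning("pair %s missing for some method; excluded", pair)
    counts = {
        pair: sum(bool(pair_results_by_method[m][pair]) for m in methods)
        for pair in sorted(common)
    }
    hist = np.bincount(list(counts.values()), minlength=len(methods) + 1)
    if direct_verdicts is None:
        return counts, hist
    sig = [c for p, c in counts.items() if direct_verdicts.get(p)]
    nonsig = [c for p, c in counts.items() if p in direct_verdicts and not direct_verdicts[p]]
    hist_sig = np.bincount(sig, minlength=len(methods) + 1)
    hist_nonsig = np.bincount(nonsig, minlength=len(methods) + 1)
    return counts, hist, hist_sig, hist_nonsig


def specific_effects(trials_a: dict[float, np.ndarray],
                     trials_b: dict[float, np.ndarray],
                     alpha: float = ALPHA) -> dict[float, dict]:
    """Per-stimulus two-sample KS comparison of trial ensembles.

    ``trials_a``/``trials_b`` map direction -> per-trial firing rates of the
    two conditions.  Returns per direction a dict with ``statistic``, ``p``,
    ``significant`` and ``direction`` (+1 enhancement in b, -1 suppression);
    directions with fewer than two trials on either side are marked
    ``testable=False``.
    """
    out: dict[float, dict] = {}
    for direction in sorted(set(trials_a) | set(trials_b)):
        a = np.asarray(trials_a.get(direction, ()), dtype=float)
        b = np.asarray(trials_b.get(direction, ()), dtype=float)
        if len(a) < 2 or len(b) < 2:
            out[direction] = {"testable": False, "statistic": np.nan, "p": np.nan,
                              "significant": False, "direction": 0}
            continue
        method = "exact" if len(a) + len(b) <= EXACT_KS_LIMIT else "asymp"
        res = stats.ks_2samp(a, b, method=method)
        out[direction] = {
            "testable": True,
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "significant": res.pvalue < alpha,
            "direction": _direction(a, b),
        }
    return out


def population_specific_summary(maps: list[dict[float, dict]]):
    """Population summary of specific-effect maps.

    Returns ``(per_cell_counts, histogram, per_stimulus_fractions)``:
    the number of significant stimuli for each cell, its histogram over
    0..12, and per stimulus direction the fractions of cells with no
    significant modulation / enhancement / suppression (summing to 1).
    """
    if not maps:
        return [], np.zeros(13, dtype=int), {}
    per_cell = [sum(1 for v in m.values() if v["significant"]) for m in maps]
    hist = np.bincount(per_cell, minlength=13)
    directions = sorted({d for m in maps for d in m})
    fractions: dict[float, dict[str, float]] = {}
    for d in directions:
        entries = [m[d] for m in maps if d in m]
        n = len(entries)
        enh = sum(1 for e in entries if e["significant"] and e["direction"] > 0)
        sup = sum(1 for e in entries if e["significant"] and e["direction"] < 0)
        fractions[d] = {
            "none": (n - enh - sup) / n,
            "enhanced": enh / n,
            "suppressed": sup / n,
        }
    return per_cell, hist, fractions


def benjamini_hochberg(p_values, alpha: float = ALPHA) -> np.ndarray:
    """BH step-up significance flags at FDR level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        flags[order[: k + 1]] = True
    return flags
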