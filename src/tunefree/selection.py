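"""Information-criterion model comparison and per-cell best-model choice.

AIC = K * ln(SSE / K) + 2 M, computed from the *unweighted* sum of squared
errors at the K = 12 grid points; AICc adds the small-sample correction
2 M (M + 1) / (K - M - 1).  Per cell, DeltaAIC(m) = AIC(m) - min_m AIC; the
model with DeltaAIC = 0 is the "best model" (bM) and models with
DeltaAIC <= 1 are "equally good contenders".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .fitting import FitResult

log = logging.getLogger(__name__)

__all__ = [
    "AIC_SENTINEL",
    "FAMILY_TIE_ORDER",
    "SelectionResult",
    "aic",
    "aicc",
    "select",
    "population_fractions",
]

#: large negative sentinel returned when SSE = 0 (perfect interpolation)
AIC_SENTINEL = -1e12

#: deterministic tie-break order (parsimony first is applied before this)
FAMILY_TIE_ORDER = ("F2", "F3", "F4", "sbeta", "vM", "wC", "wG", "wB")


def aic(fit: FitResult) -> float:
    """Akaike information criterion from the unweighted SSE."""
    if fit.K <= 0:
        raise ValueError("K must be positive")
    if fit.sse <= 0.0:
        log.warning("SSE = 0 for %s; returning AIC sentinel", fit.family)
        return AIC_SENTINEL
    return fit.K * math.log(fit.sse / fit.K) + 2 * fit.M


def aicc(fit: FitResult) -> float:
    """Corrected AIC; undefined (error) when K - M - 1 <= 0."""
    if fit.K - fit.M - 1 <= 0:
        raise ValueError(f"AICc undefined for K={fit.K}, M={fit.M}")
    return aic(fit) + 2.0 * fit.M * (fit.M + 1) / (fit.K - fit.M - 1)


@dataclass
class SelectionResult:
    """Per-(cell, condition) model ranking under one criterion."""

    criterion: str
    scores: dict[str, float]
    delta: dict[str, float]
    best_family: str
    contenders: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.best_family in self.contenders


def _tie_key(family: str, fits: dict[str, FitResult]):
    return (fits[family].M, FAMILY_TIE_ORDER.index(family))


def select(fits: dict[str, FitResult], criterion: str = "AIC",
           contender_threshold: float = 1.0) -> SelectionResult:
    """Rank fitted families by AIC or AICc.

    Non-converged fits are excluded with a logged warning.  Ties at the
    minimum are broken by fewest parameters, then by the fixed family order.
    """
    if criterion not in ("AIC", "AICc"):
        raise ValueError(f"criterion must be 'AIC' or 'AICc', got {criterion!r}")
    usable = {f: r for f, r in fits.items() if r.converged}
    excluded = [f for f in fits if f not in usable]
    for f in excluded:
        log.warning("excluding non-converged fit: %s", f)
    if not usable:
        raise ValueError("no converged fits to select among")
    score_fn = aic if criterion == "AIC" else aicc
    scores = {f: score_fn(r) for f, r in usable.items()}
    lo = min(scores.values())
    delta = {f: s - lo for f, s in scores.items()}
    tied = [f for f, d in delta.items() if d == 0.0]
    best = min(tied, key=lambda f: _tie_key(f, usable))
    contenders = sorted(
        (f for f, d in delta.items() if d <= contender_threshold),
        key=lambda f: _tie_key(f, usable),
    )
    return SelectionResult(
        criterion=criterion, scores=scores, delta=delta,
        best_family=best, contenders=contenders, excluded=excluded,
    )


def population_fractions(selections: list[SelectionResult]) -> dict[str, tuple[float, float]]:
    """Per family, the fraction of cells where it is best / a contender."""
    if not selections:
        raise ValueError("no selections given")
    n = len(selections)
    out: dict[str, tuple[float, float]] = {}
    families = sorted({f for s in selections for f in s.scores},
                      key=FAMILY_TIE_ORDER.index)
    for fam in families:
        best = sum(1 for s in selections if s.delta.get(fam) == 0.0)
        cont = sum(1 for s in selections if fam in s.contenders)
        out[fam] = (best / n, cont / n)
    return out
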