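"""Weighted least-squares fitting of tuning-curve models.

The objective is the chi^2 statistic sum_i ((y_i - f(theta_i)) / sigma_i)^2
with per-direction trial standard deviations as weights.  Non-linear families
are minimized by sequential quadratic programming (SLSQP) from a small
multistart grid over plausible widths, followed by a bounded trust-region
least-squares polish.  Fourier series admit an exact solution through the
singular value decomposition of the whitened design matrix.

Goodness of fit is the null probability Q of a sum of squared errors at
least as large as observed: for the (linear) Fourier families Q is the
regularized upper incomplete gamma function at shape (K - M)/2 and argument
chi^2/2; for non-linear families Q is estimated by Monte-Carlo resampling
(synthetic curves = fitted values + Gaussian noise with the observed
sigma_i, refitted with the same family).  Fits with Q <= 0.1 are termed
"bad".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from . import models
from .dataset import TuningCurve

log = logging.getLogger(__name__)

__all__ = [
    "SIGMA_FLOOR",
    "Q_BAD_THRESHOLD",
    "FitConfig",
    "FitResult",
    "chi_squared",
    "fit",
    "fit_fourier_analytic",
    "fit_all_families",
    "goodness_of_fit",
]

SIGMA_FLOOR = 1e-6
Q_BAD_THRESHOLD = 0.1

# width multistarts, reconstructed from the published initial-condition table:
# half-widths at half-maximum of 15, 45 and 90 degrees expressed in each
# family's own width parameter.
_HWHM = np.array([15.0, 45.0, 90.0])
_WIDTH_STARTS = {
    "wG": list(_HWHM / np.sqrt(2.0 * np.log(2.0))),   # b: HWHM = b*sqrt(2 ln 2)
    "wC": [0.2618, 0.7530, 1.3170],                    # cosh(b) = 2 - cos(Omega*HWHM)
    "vM": [20.34, 2.3, 0.001],                         # concentration k (0 -> 0.001)
    "sbeta": [100.0, 10.74, 2.41],                     # exponent b
    "wB": list(_HWHM),                                 # b is the HWHM directly
}
_WIDTH_BOUNDS = {
    "wG": (1.0, 180.0),
    "wC": (0.01, 10.0),
    "vM": (0.001, 500.0),
    "sbeta": (0.01, 1000.0),
    "wB": (1.0, 180.0),
}
_WB_S_START = 1.0
_WB_S_BOUNDS = (0.1, 10.0)


@dataclass
class FitConfig:
    """Configuration of a single-family fit."""

    family: str
    modality: str = "unimodal"
    mc_replicas: int = 10000
    seed: int | None = None
    max_iterations: int = 200
    q_threshold: float = Q_BAD_THRESHOLD

    def __post_init__(self) -> None:
        if self.family not in models.FAMILY_NAMES:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.mc_replicas < 100:
            raise ValueError("mc_replicas must be >= 100")


@dataclass
class FitResult:
    """Outcome of fitting one family to one tuning curve."""

    family: str
    modality: str
    params: np.ndarray
    chi2: float
    sse: float
    K: int
    M: int
    converged: bool
    Q: float | None = None
    fitted: np.ndarray = field(default=None, repr=False)

    @property
    def is_bad(self) -> bool | None:
        return None if self.Q is None else self.Q <= Q_BAD_THRESHOLD


def _floored_sigma(sigma: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(sigma, dtype=float), SIGMA_FLOOR)


def chi_squared(curve: TuningCurve, model_values) -> float:
    """Weighted sum of squared residuals sum ((y - f)/sigma)^2."""
    f = np.asarray(model_values, dtype=float)
    if f.shape != curve.y.shape:
        raise ValueError("model values and curve have different lengths")
    sig = _floored_sigma(curve.sigma)
    return float(np.sum(((curve.y - f) / sig) ** 2))


# ---------------------------------------------------------------------------
# initial conditions and bounds
# ---------------------------------------------------------------------------

def _starts_and_bounds(family: str, modality: str, curve: TuningCurve):
    """Multistart initial vectors and per-parameter bounds.

    Amplitudes and baseline are bounded in [0, u] with
    u = min(y) + 1.2 * (max(y) - min(y)); widths are multistarted over
    three half-widths at half-maximum (15, 45, 90 degrees); peak positions
    start at the grid argmax (unimodal) or at 120/240 degrees (bimodal).
    """
    y = curve.y
    u = float(np.min(y) + 1.2 * np.ptp(y))
    u = max(u, 1.0)
    a0 = max(float(np.ptp(y)), 1e-3)
    d0 = float(np.min(y))
    wlo, whi = _WIDTH_BOUNDS[family]
    starts, bounds = [], None
    if modality == "unimodal":
        c0 = float(curve.grid[int(np.argmax(y))])
        bounds = [(0.0, u), (wlo, whi), (c0 - 180.0, c0 + 180.0), (0.0, u)]
        if family == "wB":
            bounds.append(_WB_S_BOUNDS)
        for w0 in _WIDTH_STARTS[family]:
            x0 = [a0, w0, c0, d0]
            if family == "wB":
                x0.append(_WB_S_START)
            starts.append(np.array(x0))
    else:
        c1, c2 = 120.0, 240.0
        bounds = [
            (0.0, u), (wlo, whi), (c1 - 90.0, c1 + 90.0),
            (0.0, u), (wlo, whi), (c2 - 90.0, c2 + 90.0),
            (0.0, u),
        ]
        if family == "wB":
            bounds += [_WB_S_BOUNDS, _WB_S_BOUNDS]
        for w0 in _WIDTH_STARTS[family]:
            x0 = [a0, w0, c1, a0, w0, c2, d0]
            if family == "wB":
                x0 += [_WB_S_START, _WB_S_START]
            starts.append(np.array(x0))
    return starts, bounds


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def _minimize_family(family, modality, curve, starts, bounds, max_iterations, polish=True):
    thetas = curve.grid
    y = curve.y
    sig = _floored_sigma(curve.sigma)

    def objective(p):
        f = models.tuning_value(family, modality, p, thetas)
        return float(np.sum(((y - f) / sig) ** 2))

    best_x, best_val, any_ok = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            _clip_to_bounds(x0, bounds),
            method="SLSQP",
            bounds=bounds,
            options={"maxiter": max_iterations, "ftol": 1e-10},
        )
        any_ok = any_ok or res.success
        val = objective(res.x)
        if val < best_val:
            best_val, best_x = val, res.x
    if polish and best_x is not None:
        def residuals(p):
            return (y - models.tuning_value(family, modality, p, thetas)) / sig

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        try:
            ls = optimize.least_squares(
                residuals, _clip_to_bounds(best_x, bounds), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            val = objective(ls.x)
            if val <= best_val:
                best_val, best_x = val, ls.x
                any_ok = any_ok or ls.success
        except Exception:  # pragma: no cover - optimizer edge cases
            log.warning("least-squares polish failed for %s/%s", family, modality)
    return best_x, best_val, any_ok


def fit(curve: TuningCurve, config: FitConfig) -> FitResult:
    """Fit one family to one tuning curve by bounded chi^2 minimization.

    Fourier families are delegated to the exact analytic solver.  Optimizer
    failure is reported through ``converged=False``; the cell is never
    silently dropped.
    """
    family, modality = config.family, config.modality
    if family in models.FOURIER_FAMILIES:
        return fit_fourier_analytic(curve, int(family[1]))
    starts, bounds = _starts_and_bounds(family, modality, curve)
    best_x, best_val, converged = _minimize_family(
        family, modality, curve, starts, bounds, config.max_iterations
    )
    fitted = models.tuning_value(family, modality, best_x, curve.grid)
    sse = float(np.sum((curve.y - fitted) ** 2))
    return FitResult(
        family=family,
        modality=modality,
        params=np.asarray(best_x, dtype=float),
        chi2=best_val,
        sse=sse,
        K=len(curve.y),
        M=models.n_params(family, modality),
        converged=bool(converged),
        fitted=fitted,
    )


def fit_fourier_analytic(curve: TuningCurve, order: int) -> FitResult:
    """Exact weighted least-squares Fourier fit via the SVD.

    With b_i = y_i/sigma_i and A_im = X_m(theta_i)/sigma_i, the coefficient
    vector is p = sum_m (U(m).b / w_m) V(m) over the singular triplets of A.
    Singular values below machine-precision relative threshold are dropped
    (standard SVD regularization) and the fit flagged non-converged.
    """
    if order not in (2, 3, 4):
        raise ValueError(f"Fourier order must be 2, 3 or 4, got {order}")
    sig = _floored_sigma(curve.sigma)
    X = models.fourier_design_matrix(curve.grid, order)
    A = X / sig[:, None]
    b = curve.y / sig
    U, w, Vt = np.linalg.svd(A, full_matrices=False)
    keep = w > max(A.shape) * np.finfo(float).eps * w[0]
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d singular mode(s) in F%d fit of cell %s",
                    dropped, order, curve.cell_id)
    p = Vt[keep].T @ ((U[:, keep].T @ b) / w[keep])
    fitted = X @ p
    chi2 = float(np.sum(((curve.y - fitted) / sig) ** 2))
    sse = float(np.sum((curve.y - fitted) ** 2))
    return FitResult(
        family=f"F{order}",
        modality="unimodal",
        params=p,
        chi2=chi2,
        sse=sse,
        K=len(curve.y),
        M=2 * order + 1,
        converged=dropped == 0,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def _analytic_q(K: int, M: int, chi2: float) -> float:
    if K <= M:
        raise ValueError(f"Q undefined for K={K} <= M={M}")
    return float(special.gammaincc((K - M) / 2.0, chi2 / 2.0))


def _mc_q_linear(fit_result: FitResult, curve: TuningCurve, config: FitConfig,
                 rng: np.random.Generator) -> float:
    """Vectorized Monte-Carlo Q for the linear (Fourier) families.

    The whitened refit is an orthogonal projection, so replica chi^2 values
    are residual norms of noise + fitted under (I - A A^+).
    """
    sig = _floored_sigma(curve.sigma)
    order = int(fit_result.family[1])
    X = models.fourier_design_matrix(curve.grid, order)
    A = X / sig[:, None]
    P = A @ np.linalg.pinv(A)
    resid_op = np.eye(len(curve.y)) - P
    noise = rng.normal(0.0, 1.0, size=(config.mc_replicas, len(curve.y)))
    b_sim = (fit_result.fitted / sig)[None, :] + noise  # sigma_i/sigma_i = 1
    chi2_sim = np.sum((b_sim @ resid_op.T) ** 2, axis=1)
    return float(np.mean(chi2_sim >= fit_result.chi2))


def _refit_from(fit_result: FitResult, curve: TuningCurve, y_sim: np.ndarray) -> float:
    """Single-start bounded refit of a replica, returning its chi^2."""
    family, modality = fit_result.family, fit_result.modality
    sim_curve = TuningCurve(
        cell_id=curve.cell_id, paradigm=curve.paradigm, condition=curve.condition,
        grid=curve.grid, y=y_sim, sigma=curve.sigma, n_trials=curve.n_trials,
    )
    _, bounds = _starts_and_bounds(family, modality, sim_curve)
    sig = _floored_sigma(curve.sigma)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def residuals(p):
        return (y_sim - models.tuning_value(family, modality, p, curve.grid)) / sig

    x0 = np.clip(fit_result.params, lo, hi)
    ls = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
    return float(np.sum(residuals(ls.x) ** 2))


def goodness_of_fit(fit_result: FitResult, curve: TuningCurve, config: FitConfig,
                    rng: np.random.Generator | None = None) -> float:
    """Goodness-of-fit probability Q in [0, 1] (also stored on the result).

    Fourier families use the incomplete-gamma tail; non-linear families use
    Monte-Carlo resampling with ``config.mc_replicas`` replicas (replica
    refits start from the observed fit).
    """
    if fit_result.K <= fit_result.M:
        raise ValueError(f"Q undefined for K={fit_result.K} <= M={fit_result.M}")
    if fit_result.family in models.FOURIER_FAMILIES:
        q = _analytic_q(fit_result.K, fit_result.M, fit_result.chi2)
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        sig = _floored_sigma(curve.sigma)
        n_at_least = 0
        for _ in range(config.mc_replicas):
            y_sim = fit_result.fitted + rng.normal(0.0, sig)
            chi2_sim = _refit_from(fit_result, curve, y_sim)
            if chi2_sim >= fit_result.chi2:
                n_at_least += 1
        q = n_at_least / config.mc_replicas
    fit_result.Q = q
    return q


def mc_q_linear(fit_result: FitResult, curve: TuningCurve, config: FitConfig,
                rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo Q for a Fourier fit (cross-check of the analytic tail)."""
    if fit_result.family not in models.FOURIER_FAMILIES:
        raise ValueError("mc_q_linear applies to Fourier fits only")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _mc_q_linear(fit_result, curve, config, rng)


def fit_all_families(curve: TuningCurve, mc_replicas: int = 10000,
                     seed: int | None = None, compute_q: bool = False,
                     families=models.FAMILY_NAMES) -> dict[str, FitResult]:
    """Fit every family to one curve (modality from its condition)."""
    out: dict[str, FitResult] = {}
    rng = np.random.default_rng(seed)
    for family in families:
        modality = curve.modality if family in models.NONLINEAR_FAMILIES else "unimodal"
        cfg = FitConfig(family=family, modality=modality, mc_replicas=mc_replicas)
        res = fit(curve, cfg)
        if compute_q:
            goodness_of_fit(res, curve, cfg, rng=rng)
        out[family] = res
    return out
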