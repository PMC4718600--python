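"""Parametric tuning-curve model families.

Eight families are supported: five bell-shaped circular profiles -- wrapped
Gaussian (``wG``), wrapped Cauchy (``wC``), modified von Mises (``vM``),
symmetric Beta (``sbeta``), wrapped generalized bell-shaped membership
function (``wB``) -- and truncated Fourier series of order 2, 3 and 4
(``F2``, ``F3``, ``F4``).

All angles are in degrees; every model is 360-degree periodic.  The circular
frequency ``OMEGA = 2*pi/360`` converts degrees to radians internally.
Wrapped families sum image terms over ``i = -N..N`` with ``N = 4``.

Bimodal response profiles (two stimulus components 120 degrees apart) are
modelled as the sum of two copies of the same unimodal shape with a shared
baseline split equally between the components.  Fourier series have a single
functional form for both modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OMEGA",
    "WRAP_N",
    "FAMILY_NAMES",
    "FOURIER_FAMILIES",
    "NONLINEAR_FAMILIES",
    "ModelFamily",
    "get_family",
    "n_params",
    "evaluate",
    "evaluate_bimodal",
    "tuning_value",
    "fourier_design_row",
    "fourier_design_matrix",
]

OMEGA = 2.0 * np.pi / 360.0
WRAP_N = 4

#: floor for the von Mises concentration (k = 0 makes the normalizer vanish)
VM_K_FLOOR = 1e-3

FOURIER_FAMILIES = ("F2", "F3", "F4")
NONLINEAR_FAMILIES = ("wG", "wC", "vM", "sbeta", "wB")
FAMILY_NAMES = FOURIER_FAMILIES + NONLINEAR_FAMILIES


@dataclass(frozen=True)
class ModelFamily:
    """Descriptor of one model family at one modality."""

    name: str
    modality: str  # "unimodal" | "bimodal"
    n_params: int

    @property
    def is_fourier(self) -> bool:
        return self.name in FOURIER_FAMILIES


def n_params(name: str, modality: str = "unimodal") -> int:
    """Number of free parameters of a family at the given modality.

    Unimodal: wG/wC/vM/sbeta have 4 (amplitude, width, position, baseline),
    wB 5 (extra shape exponent), Fn 2n+1.  Bimodal non-Fourier doubles the
    per-peak parameters while sharing the baseline: 7 (or 9 for wB).
    """
    if name in FOURIER_FAMILIES:
        order = int(name[1])
        return 2 * order + 1
    if name not in NONLINEAR_FAMILIES:
        raise ValueError(f"unknown model family: {name!r}")
    if modality == "unimodal":
        return 5 if name == "wB" else 4
    if modality == "bimodal":
        return 9 if name == "wB" else 7
    raise ValueError(f"unknown modality: {modality!r}")


def get_family(name: str, modality: str = "unimodal") -> ModelFamily:
    return ModelFamily(name=name, modality=modality, n_params=n_params(name, modality))


# ---------------------------------------------------------------------------
# unimodal shapes
# ---------------------------------------------------------------------------

def _wrap_offsets() -> np.ndarray:
    return 360.0 * np.arange(-WRAP_N, WRAP_N + 1, dtype=float)


def _principal(delta: np.ndarray) -> np.ndarray:
    """Wrap an angle difference into [-180, 180).

    Recentering the truncated image sum on the principal difference keeps
    the wrapped families exactly 360-degree periodic (the truncation window
    is always symmetric about the nearest image of the peak).
    """
    return (delta + 180.0) % 360.0 - 180.0


def _wg(theta: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    dev = (_principal(theta - c)[..., None] + _wrap_offsets()) / b
    return a * np.exp(-0.5 * dev ** 2).sum(axis=-1) + d


def _wc(theta: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a * np.sinh(b) / (np.cosh(b) - np.cos(OMEGA * (theta - c))) + d


def _vm(theta: np.ndarray, a: float, k: float, c: float, d: float) -> np.ndarray:
    k = max(float(k), VM_K_FLOOR)
    cosd = np.cos(OMEGA * (theta - c))
    # (e^{k cos} - e^{-k}) / (e^k - e^{-k}), written to stay finite for large k
    return a * (np.exp(k * (cosd - 1.0)) - np.exp(-2.0 * k)) / (1.0 - np.exp(-2.0 * k)) + d


def _sbeta(theta: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    x = np.mod((OMEGA * (theta - c) + np.pi) / (2.0 * np.pi), 1.0)
    return a * (4.0 * x * (1.0 - x)) ** b + d


def _wb(theta: np.ndarray, a: float, b: float, c: float, d: float, s: float) -> np.ndarray:
    offs = _wrap_offsets()
    terms = 1.0 / (1.0 + np.abs((_principal(theta - c)[..., None] + offs) / b) ** (2.0 * s))
    alpha = (1.0 / (1.0 + np.abs(offs / b) ** (2.0 * s))).sum()
    beta = (1.0 / (1.0 + np.abs((180.0 + offs) / b) ** (2.0 * s))).sum()
    return a * (terms.sum(axis=-1) - beta) / (alpha - beta) + d


_UNIMODAL = {"wG": _wg, "wC": _wc, "vM": _vm, "sbeta": _sbeta, "wB": _wb}


# ---------------------------------------------------------------------------
# evaluation API
# ---------------------------------------------------------------------------

def _check_arity(name: str, modality: str, params) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    expected = n_params(name, modality)
    if params.shape != (expected,):
        raise ValueError(
            f"{name} ({modality}) expects {expected} parameters, got {params.shape}"
        )
    return params


def fourier_design_row(order: int, theta: float) -> np.ndarray:
    """Basis values (1, cos(Omega t), sin(Omega t), ..., cos(n Omega t), sin(n Omega t))."""
    if order not in (2, 3, 4):
        raise ValueError(f"Fourier order must be 2, 3 or 4, got {order}")
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    harmonics = np.arange(1, order + 1)
    ang = OMEGA * th[:, None] * harmonics
    row = np.concatenate(
        [np.ones((th.size, 1)), np.stack([np.cos(ang), np.sin(ang)], axis=-1).reshape(th.size, -1)],
        axis=1,
    )
    return row[0] if np.isscalar(theta) or np.ndim(theta) == 0 else row


def fourier_design_matrix(thetas, order: int) -> np.ndarray:
    thetas = np.asarray(thetas, dtype=float)
    return fourier_design_row(order, thetas.reshape(-1))


def evaluate(name: str, params, thetas) -> np.ndarray:
    """Evaluate a unimodal model (or a Fourier series) at ``thetas`` (degrees)."""
    thetas = np.asarray(thetas, dtype=float)
    if name in FOURIER_FAMILIES:
        p = _check_arity(name, "unimodal", params)
        return fourier_design_matrix(thetas, int(name[1])) @ p
    p = _check_arity(name, "unimodal", params)
    return _UNIMODAL[name](thetas, *p)


def evaluate_bimodal(name: str, params, thetas) -> np.ndarray:
    """Evaluate a bimodal (sum-of-two) model at ``thetas`` (degrees).

    Parameter layout: ``(a1, b1, c1, a2, b2, c2, d)`` with the shared baseline
    ``d`` split as ``d/2`` per component; ``wB`` appends ``(s1, s2)``.
    """
    if name in FOURIER_FAMILIES:
        raise ValueError(
            "Fourier series share one functional form across modalities; use evaluate()"
        )
    p = _check_arity(name, "bimodal", params)
    thetas = np.asarray(thetas, dtype=float)
    a1, b1, c1, a2, b2, c2, d = p[:7]
    fn = _UNIMODAL[name]
    if name == "wB":
        s1, s2 = p[7], p[8]
        return fn(thetas, a1, b1, c1, d / 2.0, s1) + fn(thetas, a2, b2, c2, d / 2.0, s2)
    return fn(thetas, a1, b1, c1, d / 2.0) + fn(thetas, a2, b2, c2, d / 2.0)


def tuning_value(name: str, modality: str, params, thetas) -> np.ndarray:
    """Dispatch to :func:`evaluate` or :func:`evaluate_bimodal` as appropriate."""
    if name in FOURIER_FAMILIES or modality == "unimodal":
        return evaluate(name, params, thetas)
    return evaluate_bimodal(name, params, thetas)
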