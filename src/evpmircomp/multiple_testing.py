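"""Bonferroni, Benjamini-Hochberg, and Storey q-value procedures.

The q-value construction estimates the null proportion pi0 from the
p-value histogram: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a
lambda grid, smoothed with a cubic fit and evaluated at the largest
lambda, clamped to (0, 1].  Sorted q-values are the step-up quantities
q_(i) = min_{j>=i} pi0 * m * p_(j) / j, which reduce exactly to
Benjamini-Hochberg when pi0 = 1.  For small scans (m < 100, the regime of
this pipeline's 55-77-test post hoc scans) the histogram estimate of pi0
is unstable, so pi0 is conservatively fixed at 1 and q equals BH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


from .errors import ConfigurationError

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ConfigurationError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return p


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p*m); m defaults to len(p)."""
    p = _check_p(p)
    if m is None:
        m = p.size
    if m < p.size:
        raise ConfigurationError(f"m={m} smaller than the {p.size} tests supplied")
    return np.minimum(1.0, p * m)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order).

    Computed with the same step-up arithmetic as the q-value routine so
    that q with pi0 = 1 reduces to BH bit-for-bit.
    """
    p = _check_p(p)
    return _step_up(p, pi0=1.0)


def _step_up(p: np.ndarray, pi0: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = pi0 * m * ranked / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class QValueResult:
    p: np.ndarray
    q: np.ndarray
    pi0_hat: float
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    pi0_smoothed: bool = False


def estimate_pi0(
    p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> tuple[float, bool]:
    """Smoothed histogram estimate of the null proportion pi0.

    Returns ``(pi0_hat, smoothed)``; ``smoothed`` is False when the
    estimate degenerated and the conservative pi0 = 1 was used.
    """
    p = _check_p(p)
    m = p.size
    grid = np.asarray(lambda_grid, dtype=float)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if np.allclose(pi0_lambda, pi0_lambda[0]):
        pi0 = float(pi0_lambda[0])
        return (min(max(pi0, 1e-8), 1.0), True) if pi0 > 0 else (1.0, False)
    try:
        coeffs = np.polyfit(grid, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, grid.max()))
    except np.linalg.LinAlgError:
        return 1.0, False
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0, False
    return min(pi0, 1.0), True


def storey_qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pi0: float | None = None,
    small_m_cutoff: int = 100,
) -> QValueResult:
    """Storey q-values with smoothed pi0 (BH fallback for small scans).

    ``pi0`` may be forced (e.g. ``pi0=1`` gives BH exactly); otherwise it
    is estimated when m >= ``small_m_cutoff`` and fixed at 1 below it.
    """
    p = _check_p(p)
    m = p.size
    smoothed = False
    if pi0 is None:
        if m < small_m_cutoff:
            pi0 = 1.0
        else:
            pi0, smoothed = estimate_pi0(p, lambda_grid)
    if not 0.0 < pi0 <= 1.0:
        raise ConfigurationError("pi0 must lie in (0, 1]")
    q = _step_up(p, pi0)
    return QValueResult(
        p=p,
        q=q,
        pi0_hat=float(pi0),
        lambda_grid=np.asarray(lambda_grid, dtype=float),
        pi0_smoothed=smoothed,
    )
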