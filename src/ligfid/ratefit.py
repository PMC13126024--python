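"""Initial velocities from fraction-product time courses, and active-site titration.

Initial rates are ordinary least-squares lines through the early, linear part
of the F_p(t) progress curve — points with F_p below a product-fraction
threshold (default 0.20).  The fraction slope (s⁻¹) is converted to a
per-enzyme turnover by

    v_init / [E] = slope × [DNA]_total / [E]    (s⁻¹)

because F_p is a fraction of total DNA.  The intercept is left free: quench
dead-time and background produce small offsets.

Active enzyme concentration is estimated from a single-turnover titration
(product vs nominal enzyme, no ATP) with a continuous two-segment
piecewise-linear model: a rising line that breaks to a flat plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class InsufficientDataError(ValueError):
    """Too few in-window points to fit an initial rate."""


class NoBreakpointError(RuntimeError):
    """Titration data show no detectable plateau; widen the titration range."""


@dataclass(frozen=True)
class RateEstimate:
    """Initial velocity per enzyme with regression diagnostics."""

    v_init_per_E: float  # s⁻¹
    v_se: float
    slope: float  # fraction s⁻¹
    slope_se: float
    intercept: float
    n_points: int
    r_squared: float
    f_abort_linear_phase: float | None = None
    warnings: tuple[str, ...] = ()


def initial_rate(
    time_s,
    f_p,
    dna_nM: float,
    enzyme_nM: float,
    threshold: float = 0.20,
    f_abort: float | None = None,
) -> RateEstimate:
    """Fit the linear phase of F_p(t) and convert the slope to turnover s⁻¹.

    Only points with ``F_p < threshold`` enter the fit; at least three are
    required.  A fitted slope more than 2 SE below zero is flagged rather
    than raised, as is a DNA:enzyme ratio below 5 (fewer than ~5 turnovers,
    outside the multiple-turnover regime).
    """
    if enzyme_nM <= 0 or dna_nM <= 0:
        raise ValueError("enzyme_nM and dna_nM must be positive")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    t = np.asarray(time_s, dtype=float)
    fp = np.asarray(f_p, dtype=float)
    if t.shape != fp.shape or t.ndim != 1:
        raise ValueError("time_s and f_p must be 1-D arrays of equal length")
    mask = fp < threshold
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points with F_p < {threshold}; need >= 3"
        )
    res = stats.linregress(t[mask], fp[mask])
    warnings = []
    if res.slope < -2 * res.stderr:
        warnings.append("negative_slope")
    if dna_nM / enzyme_nM < 5:
        warnings.append("few_turnovers")
    scale = dna_nM / enzyme_nM
    return RateEstimate(
        v_init_per_E=res.slope * scale,
        v_se=res.stderr * scale,
        slope=res.slope,
        slope_se=res.stderr,
        intercept=res.intercept,
        n_points=int(mask.sum()),
        r_squared=res.rvalue**2,
        f_abort_linear_phase=f_abort,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class TitrationFit:
    """Two-segment fit of a single-turnover active-site titration."""

    breakpoint_nM: float
    rising_slope: float  # product nM per nM nominal enzyme
    plateau_level: float  # product nM
    active_fraction: float
    sse: float
    n_points: int


def _piecewise_sse(x, y, x0):
    """Least-squares fit of y = a + b·min(x, x0); returns (sse, a, b)."""
    z = np.minimum(x, x0)
    A = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def active_site_titration(enzyme_nM, product_nM) -> TitrationFit:
    """Fit product vs nominal enzyme with a rising segment and a plateau.

    The breakpoint is profiled over the interior data x-values, then refined
    by bounded scalar minimization between the neighbours of the best grid
    point; ties go to the smaller breakpoint.  ``active_fraction`` is the
    plateau product divided by the nominal enzyme at the breakpoint.
    """
    x = np.asarray(enzyme_nM, dtype=float)
    y = np.asarray(product_nM, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("enzyme_nM and product_nM must be 1-D and equal length")
    if len(x) < 5:
        raise ValueError("need >= 5 titration points spanning rise and plateau")
    order = np.argsort(x)
    x, y = x[order], y[order]

    # single-line reference fit
    A1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    sse_line = float(np.sum((y - A1 @ coef1) ** 2))

    interior = x[1:-1]
    grid = [(x0, *_piecewise_sse(x, y, x0)) for x0 in np.unique(interior)]
    grid.sort(key=lambda r: (r[1], r[0]))  # best SSE, ties to smaller x0
    best_x0, best_sse, _, _ = grid[0]

    lo = x[max(0, np.searchsorted(x, best_x0) - 1)]
    hi = x[min(len(x) - 1, np.searchsorted(x, best_x0) + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x0: _piecewise_sse(x, y, x0)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10 * max(hi, 1.0)},
        )
        if res.fun < best_sse - 1e-12 * (1 + best_sse):
            best_x0, best_sse = float(res.x), float(res.fun)
    sse, a, b = _piecewise_sse(x, y, best_x0)

    # a breakpoint at/after the last point, or no improvement over one line,
    # means the plateau was never reached
    improvement = sse_line - sse
    if best_x0 >= x[-1] * (1 - 1e-9) or (
        sse_line > 0 and improvement < 0.01 * sse_line
    ):
        raise NoBreakpointError(
            "no detectable plateau; widen the titration above the breakpoint"
        )
    plateau = a + b * best_x0
    if best_x0 <= 0:
        raise NoBreakpointError("degenerate breakpoint at or below zero enzyme")
    return TitrationFit(
        breakpoint_nM=best_x0,
        rising_slope=b,
        plateau_level=plateau,
        active_fraction=plateau / best_x0,
        sse=sse,
        n_points=len(x),
    )
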