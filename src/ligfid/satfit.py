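"""Hyperbolic saturation fits: Michaelis–Menten over DNA, Mg²⁺ activation.

Both dependences are single-site rectangular hyperbolas of per-enzyme
velocity on the varied concentration x (DNA in nM, or free Mg²⁺ in mM):

    v_init/[E] = k_cat · x / (K_half + x)

fit by weighted nonlinear least squares (weights 1/SE² when rate standard
errors are supplied, else unweighted).  Parameter standard errors come from
the covariance of the fit; the catalytic efficiency k_cat/K_half carries a
quadrature-propagated SE.  A single-site hyperbola is used even though the
ligase binds multiple Mg²⁺ ions, because the activation data behave as a
single essential cofactor site; an optional Hill exponent is available for
exploration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit

from .fidelity import propagate_quadrature
from .util import round_sig

MODEL_KINDS = ("dna", "mg")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


def hyperbola(x, k_cat, k_half):
    return k_cat * x / (k_half + x)


def _hill(x, k_cat, k_half, n):
    return k_cat * x**n / (k_half**n + x**n)


@dataclass(frozen=True)
class SaturationFit:
    """Hyperbolic saturation fit result.

    Units follow ``model_kind``: K_half is nM for the DNA dependence, mM for
    Mg²⁺ activation; k_cat is s⁻¹ in both.
    """

    model_kind: str
    k_cat: float
    k_half: float
    k_cat_se: float
    k_half_se: float
    efficiency: float
    efficiency_se: float
    n_points: int
    r_squared: float
    hill_n: float | None = None
    warnings: tuple[str, ...] = ()

    def predict(self, x):
        if self.hill_n is None:
            return hyperbola(np.asarray(x, dtype=float), self.k_cat, self.k_half)
        return _hill(np.asarray(x, dtype=float), self.k_cat, self.k_half, self.hill_n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        return d


def fit_michaelis_menten(
    conc,
    v,
    se=None,
    model_kind: str = "dna",
    hill: bool = False,
) -> SaturationFit:
    """Fit v = k_cat·x/(K_half + x) to per-enzyme velocities.

    Initial guesses are data-driven (k_cat₀ = max v; K₀ = x at half-max by
    interpolation).  Requires >= 4 distinct concentrations.  Degenerate
    designs are flagged on the returned fit rather than raised:
    ``saturated_design`` when the velocities barely vary (K_half not
    identifiable) and ``extrapolated_K_half`` when the K estimate lies beyond
    10× the largest tested concentration.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    x = np.asarray(conc, dtype=float)
    y = np.asarray(v, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("conc and v must be 1-D arrays of equal length")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if np.max(y) <= 0:
        raise ValueError("all velocities <= 0; nothing to fit")
    warnings = []
    if np.any(y < 0):
        warnings.append("negative_velocities_present")

    k_cat0 = float(np.max(y))
    half = k_cat0 / 2
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    above = np.nonzero(ys >= half)[0]
    k0 = float(xs[above[0]]) if len(above) else float(np.median(xs))
    k0 = max(k0, np.min(xs[xs > 0], initial=1.0) * 1e-3)

    sigma = None
    if se is not None:
        sigma = np.asarray(se, dtype=float)
        if np.any(sigma <= 0):
            sigma = None  # fall back to unweighted rather than divide by zero
            warnings.append("nonpositive_se_ignored")

    spread = (np.max(y) - np.min(y)) / np.max(np.abs(y))
    try:
        popt, pcov = curve_fit(
            _hill if hill else hyperbola,
            x,
            y,
            p0=[k_cat0, k0] + ([1.0] if hill else []),
            sigma=sigma,
            bounds=(0, np.inf),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(
            f"hyperbola fit did not converge (p0 k_cat={k_cat0:.3g}, K={k0:.3g}): {exc}"
        ) from exc
    perr = np.sqrt(np.diag(pcov))
    k_cat, k_half = float(popt[0]), float(popt[1])
    k_cat_se, k_half_se = float(perr[0]), float(perr[1])
    if spread < 0.05 or (np.isfinite(k_half_se) and k_half > 0 and k_half_se / k_half > 1):
        warnings.append("saturated_design")
    if k_half > 10 * np.max(x):
        warnings.append("extrapolated_K_half")
    eff, eff_se = propagate_quadrature(
        [(k_cat, k_cat_se), (k_half, k_half_se)], operation="ratio"
    )
    yhat = (hyperbola if not hill else _hill)(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return SaturationFit(
        model_kind=model_kind,
        k_cat=k_cat,
        k_half=k_half,
        k_cat_se=k_cat_se,
        k_half_se=k_half_se,
        efficiency=eff,
        efficiency_se=eff_se,
        n_points=len(x),
        r_squared=r2,
        hill_n=float(popt[2]) if hill else None,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class FoldChangeReport:
    """Ratios of kinetic parameters between two fits, with quadrature SEs."""

    ratio_k_cat: float
    ratio_k_cat_se: float
    ratio_k_half: float
    ratio_k_half_se: float
    ratio_efficiency: float
    ratio_efficiency_se: float

    def summary(self, sig: int = 2) -> dict[str, str]:
        """Ratios rounded to ``sig`` significant figures (reporting convention)."""
        return {
            "k_cat": f"{round_sig(self.ratio_k_cat, sig)} ± {round_sig(self.ratio_k_cat_se, sig)}",
            "K_half": f"{round_sig(self.ratio_k_half, sig)} ± {round_sig(self.ratio_k_half_se, sig)}",
            "efficiency": f"{round_sig(self.ratio_efficiency, sig)} ± {round_sig(self.ratio_efficiency_se, sig)}",
        }


def compare_fits(fit_a: SaturationFit, fit_b: SaturationFit) -> FoldChangeReport:
    """Fold changes a/b of k_cat, K_half and efficiency with propagated SEs."""
    if fit_a.model_kind != fit_b.model_kind:
        raise ValueError(
            f"cannot compare fits of different kinds/units: "
            f"{fit_a.model_kind} vs {fit_b.model_kind}"
        )
    rk, rk_se = propagate_quadrature(
        [(fit_a.k_cat, fit_a.k_cat_se), (fit_b.k_cat, fit_b.k_cat_se)], "ratio"
    )
    rK, rK_se = propagate_quadrature(
        [(fit_a.k_half, fit_a.k_half_se), (fit_b.k_half, fit_b.k_half_se)], "ratio"
    )
    re_, re_se = propagate_quadrature(
        [(fit_a.efficiency, fit_a.efficiency_se), (fit_b.efficiency, fit_b.efficiency_se)],
        "ratio",
    )
    return FoldChangeReport(rk, rk_se, rK, rK_se, re_, re_se)


def plot_fit(fit: SaturationFit, conc, v, se=None, path=None):
    """Diagnostic plot of data and fitted hyperbola (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(conc, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(x, v, yerr=se, fmt="o", ms=4, capsize=2)
    xx = np.linspace(0, x.max() * 1.05, 200)
    ax.plot(xx, fit.predict(xx), "-")
    unit = "nM DNA" if fit.model_kind == "dna" else "mM free Mg$^{2+}$"
    ax.set_xlabel(unit)
    ax.set_ylabel(r"$v_{init}/[E]$ (s$^{-1}$)")
    ax.set_title(
        f"k_cat={fit.k_cat:.3g}±{fit.k_cat_se:.2g}, K={fit.k_half:.3g}±{fit.k_half_se:.2g}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
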