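"""Discrimination (fidelity) decomposition with quadrature error propagation.

Overall fidelity is the ratio of catalytic efficiencies for the canonical
(C•G) and damaged (8oxoG•A) nicked substrates:

    D_overall = (k_cat/K_M)_C•G / (k_cat/K_M)_8oxoG•A

It factors into the AMP-transfer and nick-sealing steps,

    D_overall = D_step2 · D_step3,     D_step3 = F_sealed,C•G / F_sealed,8oxoG•A

so D_step2 follows as D_overall / D_step3.  Standard errors of independent
ratio/product chains combine in quadrature on the relative scale (the
sum-of-squares rule): SE_rel = sqrt(Σ SE_rel,k²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .util import round_sig


class FidelityInputError(ValueError):
    """Non-positive value where a positive ratio/product term is required."""


def propagate_quadrature(
    values: Sequence[tuple[float, float]],
    operation: str = "product",
) -> tuple[float, float]:
    """Combine (value, SE) terms of a product or ratio chain.

    ``operation='product'`` multiplies all terms; ``'ratio'`` divides the
    first by the product of the rest.  Relative SEs combine as the square
    root of the sum of squares, exact for independent errors in the
    log-normal approximation.  A single term passes through unchanged.
    """
    if operation not in ("product", "ratio"):
        raise ValueError("operation must be 'product' or 'ratio'")
    if len(values) == 0:
        raise ValueError("empty chain")
    rel_sq = 0.0
    result = None
    for k, (val, se) in enumerate(values):
        if val <= 0:
            raise FidelityInputError(
                f"term {k} has non-positive value {val}; ratio/product chains "
                "require positive values"
            )
        if se < 0:
            raise ValueError("standard errors must be >= 0")
        rel_sq += (se / val) ** 2
        if result is None:
            result = val
        elif operation == "product":
            result *= val
        else:
            result /= val
    return result, abs(result) * math.sqrt(rel_sq)


@dataclass(frozen=True)
class Ratio:
    """A fold-factor with its propagated SE; possibly a censored lower bound.

    When the denominator is exactly zero (e.g. no detectable sealing of the
    damaged substrate) the discrimination is unbounded: ``censored`` is set
    and ``lower_bound`` holds the value implied by the denominator's SE
    (infinite if that too is zero); ``value`` is NaN.
    """

    value: float
    se: float
    censored: bool = False
    lower_bound: float | None = None

    def rounded(self, sig: int = 2) -> float:
        return round_sig(self.value, sig)


def discrimination_overall(
    eff_canonical: tuple[float, float], eff_damaged: tuple[float, float]
) -> Ratio:
    """Overall discrimination: ratio of catalytic efficiencies (canonical/damaged)."""
    val, se = propagate_quadrature([eff_canonical, eff_damaged], "ratio")
    return Ratio(val, se)


def discrimination_step3(
    f_sealed_canonical: tuple[float, float], f_sealed_damaged: tuple[float, float]
) -> Ratio:
    """Nick-sealing discrimination: ratio of sealed fractions (canonical/damaged).

    Sealed fractions must lie in (0, 1]; a damaged sealed fraction of exactly
    zero yields a censored lower bound instead of a number.
    """
    fc, fc_se = f_sealed_canonical
    fd, fd_se = f_sealed_damaged
    for name, v in (("canonical", fc), ("damaged", fd)):
        if not 0 <= v <= 1:
            raise FidelityInputError(f"{name} sealed fraction {v} outside [0, 1]")
    if fc == 0:
        raise FidelityInputError("canonical sealed fraction is zero")
    if fd == 0:
        bound = fc / fd_se if fd_se > 0 else math.inf
        return Ratio(math.nan, math.nan, censored=True, lower_bound=bound)
    val, se = propagate_quadrature([(fc, fc_se), (fd, fd_se)], "ratio")
    return Ratio(val, se)


def discrimination_step2(overall: tuple[float, float] | Ratio, step3: tuple[float, float] | Ratio) -> Ratio:
    """AMP-transfer discrimination from the identity D_step2 = D_overall / D_step3."""
    o = (overall.value, overall.se) if isinstance(overall, Ratio) else overall
    s3 = (step3.value, step3.se) if isinstance(step3, Ratio) else step3
    val, se = propagate_quadrature([o, s3], "ratio")
    return Ratio(val, se)


def step2_from_inclusive_efficiencies(
    eff_incl_canonical: tuple[float, float], eff_incl_damaged: tuple[float, float]
) -> Ratio:
    """Direct step-2 discrimination from abortive-inclusive efficiencies.

    Catalytic efficiency measured on total adenylylated DNA (sealed product
    plus released intermediate) reflects AMP transfer only; its canonical /
    damaged ratio is the step-2 discrimination, and must agree with the
    identity route ``D_overall / D_step3`` — a useful internal consistency
    check.
    """
    val, se = propagate_quadrature([eff_incl_canonical, eff_incl_damaged], "ratio")
    return Ratio(val, se)


@dataclass(frozen=True)
class FidelityReport:
    """Overall, step-2 and step-3 discrimination with the inputs that made them."""

    overall: Ratio
    step2: Ratio
    step3: Ratio
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.step2.censored or self.step3.censored or self.overall.censored):
            prod = self.step2.value * self.step3.value
            if abs(prod - self.overall.value) > 1e-9 * abs(self.overall.value):
                raise ValueError(
                    "report violates the identity overall = step2 × step3"
                )

    def to_dict(self) -> dict:
        def r(x: Ratio) -> dict:
            return {
                "value": x.value,
                "se": x.se,
                "censored": x.censored,
                "lower_bound": x.lower_bound,
                "rounded_2sf": None if x.censored else x.rounded(2),
            }

        return {
            "overall": r(self.overall),
            "step2": r(self.step2),
            "step3": r(self.step3),
            "inputs": self.inputs,
        }


def build_report(
    eff_canonical: tuple[float, float],
    eff_damaged: tuple[float, float],
    f_sealed_canonical: tuple[float, float],
    f_sealed_damaged: tuple[float, float],
    inputs: dict | None = None,
) -> FidelityReport:
    """Full decomposition from efficiencies and sealed fractions.

    The overall factor comes from the efficiency ratio, step 3 from the
    sealed-fraction ratio, and step 2 from the identity overall / step3, so
    overall = step2 × step3 holds by construction.
    """
    overall = discrimination_overall(eff_canonical, eff_damaged)
    step3 = discrimination_step3(f_sealed_canonical, f_sealed_damaged)
    if step3.censored:
        step2 = Ratio(math.nan, math.nan, censored=True, lower_bound=None)
    else:
        step2 = discrimination_step2(overall, step3)
    record = dict(inputs or {})
    record.update(
        eff_canonical=eff_canonical,
        eff_damaged=eff_damaged,
        f_sealed_canonical=f_sealed_canonical,
        f_sealed_damaged=f_sealed_damaged,
    )
    return FidelityReport(overall=overall, step2=step2, step3=step3, inputs=record)
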