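"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the code paths they check: branching fractions
come from absorbing-state linear algebra on the CTMC generator, saturation
parameters from a brute-force grid search, propagated errors from Monte
Carlo, and the titration breakpoint from an exhaustive fine grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from ligfid.simulate import MechanismParams


# ---------------------------------------------------------------------------
# absorbing-state branching oracle

def branching_abort_probability(params: MechanismParams) -> float:
    """P(a DNA molecule ends as released AMP-DNA) by linear algebra.

    Single-molecule CTMC over transient states {S, ES_open, ES_closed,
    EI_closed, EI_open} with absorbers {I (abortive), P (sealed)}.  The
    binding rate constant cancels from the branching (unproductive
    dissociation returns to S), so any positive pseudo-first-order rate works.
    """
    kb = 1.0  # arbitrary positive binding rate; cancels in the branching
    ko, kc, kd = params.k_open, params.k_close, params.k_diss
    kt, ks = params.k_transfer, params.k_seal
    # transient: 0=S, 1=ESo, 2=ESc, 3=EIc, 4=EIo ; absorbing: 0=I, 1=P
    Q_tt = np.array(
        [
            [-kb, kb, 0, 0, 0],
            [kd, -(kd + kc), kc, 0, 0],
            [0, ko, -(ko + kt), kt, 0],
            [0, 0, 0, -(ko + ks), ko],
            [0, 0, 0, kc, -(kc + kd)],
        ]
    )
    Q_ta = np.array(
        [
            [0, 0],
            [0, 0],
            [0, 0],
            [0, ks],
            [kd, 0],
        ]
    )
    B = np.linalg.solve(-Q_tt, Q_ta)
    return float(B[0, 0])


def steady_state_turnover(params: MechanismParams, dna_free_nM: float) -> float:
    """Per-enzyme product flux (s⁻¹) at fixed free DNA, by stationary analysis.

    Solves πQ = 0 for the single-enzyme cycle {E, ESo, ESc, EIc, EIo} with
    pseudo-first-order binding at ``dna_free_nM``; the sealing flux is
    k_seal · π(EI_closed).
    """
    kb = params.k_bind * dna_free_nM
    ko, kc, kd = params.k_open, params.k_close, params.k_diss
    kt, ks = params.k_transfer, params.k_seal
    # states: 0=E, 1=ESo, 2=ESc, 3=EIc, 4=EIo
    Q = np.array(
        [
            [-kb, kb, 0, 0, 0],
            [kd, -(kd + kc), kc, 0, 0],
            [0, ko, -(ko + kt), kt, 0],
            [ks, 0, 0, -(ko + ks), ko],
            [kd, 0, 0, kc, -(kc + kd)],
        ]
    )
    A = np.vstack([Q.T, np.ones(5)])
    b = np.zeros(6)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return ks * float(pi[3])


# ---------------------------------------------------------------------------
# brute-force hyperbola minimizer

def grid_search_hyperbola(x, y, n_grid: int = 2001, n_refine: int = 6):
    """Brute-force minimizer of SSE for k_cat·x/(K+x).

    For fixed K the model is linear in k_cat, so the conditional optimum is
    the closed-form projection k_cat(K) = Σu·y / Σu² with u = x/(K+x); K is
    scanned exhaustively on a refining log grid.  Independent of the
    Levenberg–Marquardt path used by the fitting code.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    K_lo, K_hi = x[x > 0].min() / 30.0, x.max() * 30.0
    for _ in range(n_refine):
        Ks = np.geomspace(K_lo, K_hi, n_grid)
        u = x[None, :] / (Ks[:, None] + x[None, :])
        kc = (u @ y) / np.einsum("ij,ij->i", u, u)
        sse = ((kc[:, None] * u - y[None, :]) ** 2).sum(axis=1)
        j = int(np.argmin(sse))
        span = (K_hi / K_lo) ** (1.0 / (n_grid - 1))
        K_lo, K_hi = Ks[j] / span**2, Ks[j] * span**2
    return float(kc[j]), float(Ks[j])


# ---------------------------------------------------------------------------
# Monte-Carlo error propagation oracle

def mc_chain_relative_sd(values, operation: str, n: int = 100_000, seed: int = 0) -> float:
    """Empirical relative SD of a product/ratio chain under independent errors.

    Terms are sampled log-normal with matching mean and SD — the error model
    under which relative-error propagation of products/ratios is meaningful,
    and the only standard one for which a ratio has finite variance at
    moderate CV.  Returned on the relative scale (SD / mean of the chain
    samples) for comparison with a relative-quadrature SE.
    """
    rng = np.random.default_rng(seed)
    samples = None
    for k, (val, se) in enumerate(values):
        cv = se / val
        s2 = np.log1p(cv**2)
        draw = val * np.exp(rng.normal(-s2 / 2, np.sqrt(s2), size=n))
        if samples is None:
            samples = draw.astype(float)
        elif operation == "product":
            samples = samples * draw
        else:
            samples = samples / draw
    return float(np.std(samples) / np.mean(samples))


# ---------------------------------------------------------------------------
# exhaustive titration breakpoint oracle

def exhaustive_breakpoint(x, y, n: int = 20001) -> float:
    """Breakpoint minimizing piecewise SSE over a dense grid (independent path)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = (np.inf, np.nan)
    for x0 in np.linspace(x.min(), x.max(), n):
        z = np.minimum(x, x0)
        A = np.column_stack([np.ones_like(z), z])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ coef) ** 2))
        if sse < best[0] - 1e-15:
            best = (sse, x0)
    return best[1]


# ---------------------------------------------------------------------------
# long-horizon simulation helper

def longtime_abort_fraction(params: MechanismParams, tol: float = 1e-10) -> float:
    """Simulate until essentially all DNA is absorbed; return F_i/(F_i+F_p)."""
    from ligfid.simulate import simulate_mechanism

    rates = [
        params.k_bind * params.enzyme_total,
        params.k_open,
        params.k_close,
        params.k_diss,
        params.k_transfer,
        params.k_seal,
    ]
    horizon = 50.0 / min(r for r in rates if r > 0)
    for _ in range(24):
        tc = simulate_mechanism(params, np.array([horizon]))
        fi, fp = tc.f_i[-1], tc.f_p[-1]
        if fi + fp > 1.0 - tol:
            return fi / (fi + fp)
        horizon *= 2.0
    raise AssertionError(f"system did not absorb within horizon {horizon}")


# ---------------------------------------------------------------------------
# fixtures

def random_mechanism(rng: np.random.Generator, enzyme_excess: bool = True) -> MechanismParams:
    """A random small parameter set with rates in a well-conditioned range."""
    return MechanismParams(
        k_bind=rng.uniform(0.01, 0.5),
        k_open=rng.uniform(0.2, 5.0),
        k_close=rng.uniform(0.2, 10.0),
        k_diss=rng.uniform(0.1, 5.0),
        k_transfer_max=rng.uniform(1.0, 20.0),
        k_seal_max=rng.uniform(0.2, 10.0),
        K_mg_step2=rng.uniform(0.05, 1.0),
        K_mg_step3=rng.uniform(0.3, 3.0),
        enzyme_total=rng.uniform(50.0, 200.0) if enzyme_excess else 1.0,
        dna_total=50.0 if enzyme_excess else 1000.0,
        mg_free=rng.uniform(0.2, 5.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def wt_canonical():
    from ligfid.simulate import CANONICAL, Condition, params_for

    return params_for(Condition("WT", CANONICAL, 1.0, 1000.0, 0.2, 1.0))
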