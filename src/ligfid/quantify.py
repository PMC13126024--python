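"""Band intensities → fraction observables.

Three bands are quantified per gel lane: unreacted nicked substrate ``s``,
AMP-DNA intermediate ``i`` and sealed product ``p``.  The observables are

    F_p      = p / (p + s + i)     fraction of total DNA sealed
    F_abort  = i / (p + i)         fraction of adenylylated DNA released unsealed
    F_sealed = 1 − F_abort         fraction of adenylylated DNA sealed

All are invariant to rescaling the lane, so background-corrected intensities
in arbitrary units are sufficient input.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .simulate import BAND_COLUMNS

#: columns identifying a reaction condition (replicate handled separately)
CONDITION_KEYS = ["variant", "substrate", "enzyme_nM", "dna_nM", "atp_mM", "mg_free_mM"]


class UndefinedFractionError(ValueError):
    """A fraction's denominator is zero (no signal, or no AMP transfer yet)."""


def _check_nonneg(**bands: float) -> None:
    for name, v in bands.items():
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0):
            raise ValueError(f"band intensity {name} must be non-negative")


def fraction_product(s, i, p):
    """Fraction of total DNA converted to sealed product, p/(p+s+i)."""
    _check_nonneg(s=s, i=i, p=p)
    total = np.asarray(s, dtype=float) + i + p
    if np.any(total <= 0):
        raise UndefinedFractionError("all band intensities are zero")
    out = np.asarray(p, dtype=float) / total
    return float(out) if isinstance(s, numbers.Number) else out


def fraction_abortive(i, p):
    """Fraction of AMP-DNA intermediate released unsealed, i/(p+i)."""
    _check_nonneg(i=i, p=p)
    denom = np.asarray(i, dtype=float) + p
    if np.any(denom <= 0):
        raise UndefinedFractionError(
            "p + i = 0: no AMP transfer has occurred, abortive fraction undefined"
        )
    out = np.asarray(i, dtype=float) / denom
    return float(out) if isinstance(i, numbers.Number) else out


def fraction_sealed(f_abort):
    """Complement of the abortive fraction, 1 − F_abort = p/(p+i)."""
    arr = np.asarray(f_abort, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("F_abort must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if isinstance(f_abort, numbers.Number) else out


def band_table_to_fractions(bands: pd.DataFrame) -> pd.DataFrame:
    """Per-lane fraction observables from a band-record table.

    Adds ``F_p`` for every lane and per-lane ``F_abort``/``F_sealed`` where
    defined (NaN before any AMP transfer).  Condition-level abortive fractions
    pooled over the linear phase come from :func:`abortive_fractions`.
    """
    missing = [c for c in BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise ValueError(f"band table missing column(s): {missing}")
    s = bands["intensity_s"].to_numpy(float)
    i = bands["intensity_i"].to_numpy(float)
    p = bands["intensity_p"].to_numpy(float)
    out = bands.copy()
    out["F_p"] = fraction_product(s, i, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        fab = np.where(i + p > 0, i / np.where(i + p > 0, i + p, 1.0), np.nan)
    out["F_abort"] = fab
    out["F_sealed"] = 1.0 - fab
    return out


def abortive_fractions(
    fractions: pd.DataFrame,
    threshold: float = 0.20,
    mode: str = "linear_phase",
) -> pd.DataFrame:
    """Abortive fraction per condition and replicate.

    In ``linear_phase`` mode (default) intensities are pooled over lanes with
    ``F_p`` below ``threshold`` — the steady-state partitioning is constant in
    the linear phase, so pooling reduces noise.  ``per_timepoint`` averages
    the per-lane ratios instead.
    """
    if mode not in ("linear_phase", "per_timepoint"):
        raise ValueError("mode must be 'linear_phase' or 'per_timepoint'")
    keys = CONDITION_KEYS + ["replicate"]
    rows = []
    for key, grp in fractions.groupby(keys, sort=False):
        if mode == "linear_phase":
            sel = grp[grp["F_p"] < threshold]
            isum = sel["intensity_i"].sum()
            psum = sel["intensity_p"].sum()
            fab = isum / (isum + psum) if (isum + psum) > 0 else np.nan
        else:
            fab = grp["F_abort"].mean()
        rows.append((*key, fab, np.nan if np.isnan(fab) else 1.0 - fab))
    return pd.DataFrame(rows, columns=keys + ["F_abort", "F_sealed"])


def summarize_replicates(
    records: pd.DataFrame,
    value_cols: list[str] | str,
    group_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean, sample SD (n−1 denominator) and n.

    Groups with a single record report the value with SD = NaN (flagged by
    ``n = 1``); empty input raises.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    if group_keys is None:
        group_keys = CONDITION_KEYS
    if len(records) == 0:
        raise ValueError("no records to summarize")
    agg = {c: ["mean", "std", "count"] for c in value_cols}
    out = records.groupby(group_keys, sort=False).agg(agg)
    out.columns = [f"{c}_{stat}" if stat != "count" else "n" for c, stat in out.columns]
    # 'n' appears once per value col; keep the first
    n_cols = [c for c in out.columns if c == "n"]
    if len(n_cols) > 1:
        out = out.loc[:, ~out.columns.duplicated()]
    return out.reset_index()
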