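"""Per-gene normalization statistics: NT fold change, deltaT, robust Z.

Every screen parameter is expressed as fold change (FC) relative to the mean
of the non-targeting (siOTP-NT) control wells on the same plate, so plate-
scale effects cancel by construction. Cell viability is the change in cell
number over the 48 h treatment window, deltaT = T48 - T0 (negative values
indicate net cell death), normalized to the NT deltaT on the plate. Robust
Z-scores standardize a gene's replicate-averaged value against the median
and median absolute deviation of the whole library-gene population for that
parameter and arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Normal-consistency scaling for the MAD (1/Phi^-1(0.75)). The published
#: thresholds may assume either this or raw MAD; configurable at call sites.
MAD_CONSTANT = 1.4826


class DegeneratePopulationError(ValueError):
    pass


@dataclass(frozen=True)
class RobustZInfo:
    median: float
    mad: float
    scale: float
    n: int
    degenerate: bool


def normalize_to_nt(values, nt_values):
    """Fold change of each value relative to the mean of NT wells.

    Returns an array of FCs. A non-positive or undefined NT mean makes the
    plate unusable for this parameter: all FCs come back NaN and the caller
    should flag the plate.
    """
    vals = np.asarray(values, dtype=float)
    nt = np.asarray(nt_values, dtype=float)
    nt = nt[np.isfinite(nt)]
    if nt.size == 0:
        raise ValueError("no NT well with a defined value on this plate")
    nt_mean = nt.mean()
    if nt_mean <= 0:
        return np.full(vals.shape, np.nan)
    return vals / nt_mean


def delta_t(t48_count, t0_count):
    """Change in cell number over the treatment window (T48 - T0)."""
    return np.asarray(t48_count, dtype=float) - np.asarray(t0_count, dtype=float)


def average_replicates(*replicate_values) -> tuple[float, int]:
    """Arithmetic mean of the defined replicate values.

    Returns ``(mean, n_contributing)``; ``(nan, 0)`` when every replicate is
    missing.
    """
    vals = np.asarray(replicate_values, dtype=float)
    mask = np.isfinite(vals)
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return float(vals[mask].mean()), n


def robust_z(values, population=None, mad_constant: float = MAD_CONSTANT
             ) -> tuple[np.ndarray, RobustZInfo]:
    """Robust Z-scores: ``(x - median(pop)) / (mad_constant * MAD(pop))``.

    ``population`` defaults to ``values`` itself (screen-wide scoping is the
    default; callers wanting per-plate scoping pass the plate's population).
    Missing values propagate as NaN. A zero MAD makes every score undefined
    (NaN) and is flagged as degenerate rather than raising, so an all-equal
    zero-noise screen still flows through the pipeline.
    """
    x = np.asarray(values, dtype=float)
    pop = x if population is None else np.asarray(population, dtype=float)
    pop = pop[np.isfinite(pop)]
    if pop.size < 3:
        raise DegeneratePopulationError(
            f"robust Z needs >= 3 defined population values, got {pop.size}")
    med = float(np.median(pop))
    mad = float(np.median(np.abs(pop - med)))
    scale = mad_constant * mad
    if scale == 0:
        z = np.full(x.shape, np.nan)
        return z, RobustZInfo(med, mad, scale, pop.size, degenerate=True)
    return (x - med) / scale, RobustZInfo(med, mad, scale, pop.size, degenerate=False)


def add_plate_fc(df: pd.DataFrame, value_col: str, fc_col: str,
                 plate_keys=("library_plate", "arm", "replicate"),
                 role_col: str = "role", nt_role: str = "control_NT") -> pd.DataFrame:
    """Vectorized per-plate NT normalization for a long-format well table.

    Adds ``fc_col`` = value / mean(NT values on the same plate instance).
    Plates whose NT mean is non-positive or undefined yield NaN.
    """
    def _nt_mean(group: pd.DataFrame) -> float:
        nt = group.loc[group[role_col] == nt_role, value_col].to_numpy(dtype=float)
        nt = nt[np.isfinite(nt)]
        if nt.size == 0 or nt.mean() <= 0:
            return np.nan
        return nt.mean()

    keys = list(plate_keys)
    nt_means = df.groupby(keys, sort=False).apply(_nt_mean, include_groups=False)
    nt_means.name = "_nt_mean"
    out = df.merge(nt_means.reset_index(), on=keys, how="left")
    out[fc_col] = out[value_col] / out["_nt_mean"]
    return out.drop(columns="_nt_mean")
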