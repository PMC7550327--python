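"""Lactate quantitation: standard curves, background subtraction, per-cell values.

The LDH endpoint assay reports absorbance at 490 nm. A linear standard curve
``A = intercept + slope * C`` is fitted per assay batch over a 0-3.2 mM
lactate ladder (quadruplicate wells averaged per level). Media-only wells in
column 24 of each plate define the plate background — media lactate plus the
assay's intrinsic color — so assay-well concentrations are recovered from the
net absorbance alone:

    concentration = dilution_factor * (A - plate_background) / slope

(the curve intercept is already contained in the plate background, see
``lactate_per_cell``). Media were diluted 1:3 before the assay, hence the
default ``dilution_factor = 3``. The lactate-per-cell value divides the
background-subtracted concentration by the same well's T48 cell count; wells
in the low-cell-density regime (T48 fold change below 0.2) are excluded
because the quantitation is unreliable there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LADDER_TOP_MM = 3.2
DEFAULT_DILUTION = 3.0
DEFAULT_LOW_CELL_FC = 0.2


class AssayError(ValueError):
    """Raised when the standard-curve fit indicates assay failure."""


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear lactate standard curve (absorbance units vs mM)."""

    slope: float
    intercept: float
    residual_sd: float = 0.0
    r_squared: float = 1.0
    ladder_range: tuple[float, float] = (0.0, LADDER_TOP_MM)

    def absorbance(self, concentration_mm):
        return self.intercept + self.slope * np.asarray(concentration_mm, dtype=float)

    def concentration(self, absorbance):
        """Invert the fitted line: ``C = (A - intercept) / slope``."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class LactateResult:
    """Background-subtracted lactate for one well."""

    concentration_mm: float
    lactate_per_cell: float
    excluded: bool = False
    reason: str = ""
    clamped: bool = False


def fit_standard_curve(concentration_mm, absorbance) -> StandardCurve:
    """Least-squares line through the (averaged) standard ladder.

    Replicate wells at the same concentration are averaged before fitting,
    matching how quadruplicate standards are handled. Requires at least two
    distinct concentrations; a non-positive slope is an assay failure.
    """
    conc = np.asarray(concentration_mm, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if conc.shape != ab.shape:
        raise ValueError("concentration and absorbance must have equal length")
    level = pd.DataFrame({"c": conc, "a": ab}).groupby("c")["a"].mean()
    if len(level) < 2:
        raise ValueError("standard curve needs >= 2 distinct concentrations")
    fit = stats.linregress(level.index.to_numpy(), level.to_numpy())
    if fit.slope <= 0:
        raise AssayError(f"non-positive standard-curve slope ({fit.slope:.4g})")
    resid = level.to_numpy() - (fit.intercept + fit.slope * level.index.to_numpy())
    rsd = float(np.sqrt(np.mean(resid ** 2)))
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         residual_sd=rsd, r_squared=float(fit.rvalue ** 2),
                         ladder_range=(float(level.index.min()), float(level.index.max())))


def plate_background(media_absorbances) -> float:
    """Mean absorbance of a plate's media-only (column 24) wells."""
    vals = np.asarray(media_absorbances, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("plate has no media-only wells with absorbance")
    return float(vals.mean())


def lactate_concentration(absorbance, background: float, curve: StandardCurve,
                          dilution_factor: float = DEFAULT_DILUTION):
    """Net lactate concentration (mM, undiluted media scale) for assay wells.

    Negative net absorbances are clamped to zero concentration; callers can
    detect clamping by comparing against the unclamped value.
    """
    net = np.asarray(absorbance, dtype=float) - background
    return dilution_factor * np.clip(net, 0.0, None) / curve.slope


def lactate_per_cell(absorbance: float, curve: StandardCurve, background: float,
                     t48_count: float, t48_fc: float | None = None,
                     dilution_factor: float = DEFAULT_DILUTION,
                     low_cell_fc: float = DEFAULT_LOW_CELL_FC) -> LactateResult:
    """Lactate production per cell for a single well.

    Exclusion is decided on the well's T48 fold change (if supplied), never
    on the raw count alone; a zero count excludes the well rather than
    raising a division error.
    """
    if absorbance is None or not np.isfinite(absorbance):
        return LactateResult(np.nan, np.nan, excluded=True, reason="missing")
    net = absorbance - background
    clamped = net < 0
    conc = float(dilution_factor * max(net, 0.0) / curve.slope)
    if t48_fc is not None and np.isfinite(t48_fc) and t48_fc < low_cell_fc:
        return LactateResult(conc, np.nan, excluded=True,
                             reason="low_cell_density", clamped=clamped)
    if t48_count is None or not np.isfinite(t48_count) or t48_count <= 0:
        return LactateResult(conc, np.nan, excluded=True,
                             reason="low_cell_density", clamped=clamped)
    return LactateResult(conc, conc / t48_count, clamped=clamped)
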