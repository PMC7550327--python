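"""Screen quality-control statistics and plate gating.

Four complementary measures of assay quality are used:

* replicate Pearson correlation on raw (unnormalized) library-well values;
* per-plate coefficient of variation (CV) of each control type, with a
  plate failing when any control CV exceeds 30%;
* the Z' factor, ``1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|``, a
  dynamic-range statistic suited to strong positive controls such as the
  PLK1 kill control;
* the strictly standardized mean difference (SSMD) on log2 fold-change
  data, better behaved for moderate controls such as PDK1 in the lactate
  assay. Wells with non-positive fold change cannot be log-transformed and
  are excluded with a count; an all-negative positive-control population
  (PLK1 deltaT) leaves the SSMD undefined with a recorded reason.

Z' and SSMD are computed per plate and averaged across the screen. Sample
(n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CVGateResult:
    passed: bool
    cvs: dict
    threshold: float
    reasons: tuple = ()


@dataclass(frozen=True)
class SSMDResult:
    value: float
    n_pos: int
    n_neg: int
    n_pos_excluded: int = 0
    n_neg_excluded: int = 0
    reason: str = ""

    def __float__(self) -> float:
        return self.value


def replicate_correlation(rep1, rep2) -> float:
    """Pearson r between paired raw replicate values.

    NaN pairs are dropped; needs >= 3 pairs and non-zero variance in both
    replicates (otherwise NaN).
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def control_cv(values) -> float:
    """Coefficient of variation in percent (sample sd / mean * 100)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return float("nan")
    mean = vals.mean()
    if mean <= 0:
        return float("inf")
    return float(100.0 * vals.std(ddof=1) / mean)


def control_cv_gate(control_values: dict, threshold: float = 30.0) -> CVGateResult:
    """Per-plate control gate: fail if any control type's CV exceeds the threshold.

    ``control_values`` maps a label (e.g. ``"control_NT/cell_count"``) to the
    wells' raw values. A non-positive mean is a failure with its own reason.
    """
    cvs, reasons = {}, []
    for label, values in control_values.items():
        cv = control_cv(values)
        cvs[label] = cv
        if not np.isfinite(cv):
            reasons.append(f"{label}: non-positive or undefined control mean")
        elif cv > threshold:
            reasons.append(f"{label}: CV {cv:.1f}% > {threshold:.0f}%")
    return CVGateResult(passed=not reasons, cvs=cvs, threshold=threshold,
                        reasons=tuple(reasons))


def z_prime(positive, negative) -> float:
    """Z' factor between positive and negative control populations.

    Returns ``-inf`` when the control means coincide (zero dynamic range);
    symmetric in its arguments.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if pos.size < 2 or neg.size < 2:
        return float("nan")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return float("-inf")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


def ssmd(positive_fc, negative_fc, log2_input: bool = False) -> SSMDResult:
    """SSMD between control populations, computed on log2 fold-change data.

    ``positive_fc``/``negative_fc`` are fold changes (log2-transformed here
    unless ``log2_input``). The sign is oriented so a depleting positive
    control yields a positive SSMD: ``(mean_neg - mean_pos) /
    sqrt(var_pos + var_neg)`` — paired differences are unavailable, so the
    denominator assumes independent control populations.
    """
    pos = np.asarray(positive_fc, dtype=float)
    neg = np.asarray(negative_fc, dtype=float)
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if log2_input:
        lpos, lneg = pos, neg
        n_pos_ex = n_neg_ex = 0
    else:
        pos_ok, neg_ok = pos > 0, neg > 0
        n_pos_ex = int((~pos_ok).sum())
        n_neg_ex = int((~neg_ok).sum())
        lpos, lneg = np.log2(pos[pos_ok]), np.log2(neg[neg_ok])
    if lpos.size < 2:
        return SSMDResult(float("nan"), lpos.size, lneg.size, n_pos_ex, n_neg_ex,
                          reason="all positive-control fold changes non-positive"
                          if n_pos_ex else "too few positive-control wells")
    if lneg.size < 2:
        return SSMDResult(float("nan"), lpos.size, lneg.size, n_pos_ex, n_neg_ex,
                          reason="too few negative-control wells")
    denom = np.sqrt(lpos.var(ddof=1) + lneg.var(ddof=1))
    if denom == 0:
        return SSMDResult(float("inf") if lneg.mean() != lpos.mean() else 0.0,
                          lpos.size, lneg.size, n_pos_ex, n_neg_ex,
                          reason="zero variance in both controls")
    return SSMDResult(float((lneg.mean() - lpos.mean()) / denom),
                      lpos.size, lneg.size, n_pos_ex, n_neg_ex)
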