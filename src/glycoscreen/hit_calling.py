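"""Bin classification, hit thresholds, drug-enhancer logic, expression triage.

Genes are classified per parameter and arm into ordered severity bins on the
fold-change scale:

* viability (deltaT FC): ``Hi`` (high count), ``CV1``-``CV3`` (graded
  viability loss) and ``LC`` (low count / net cell death);
* lactate per cell (FC): ``LAC1`` (unchanged or up) through ``LAC5``
  (strong suppression).

Only three edges are pinned by the screen's published thresholds — the
viability hit correspondence FC < 0.08, the glycolysis hit region FC < 0.5
(= LAC4 ∪ LAC5) and the low-cell-count exclusion at T48 FC < 0.2 — the
remaining default edges are this package's own convention and are fully
configurable. A fold change exactly on an edge falls on the lower-severity
side.

Hits are genes whose control-arm robust Z falls strictly below the
parameter's threshold (-1.5 viability, -1.66 glycolysis); lactate hits are
first filtered on the T48 count to drop the unreliable low-cell regime.
Drug enhancers are genes whose drug-arm bin is at least two severity levels
beyond their control-arm bin; the enumerated control/drug bin pairs and the
severity-difference rule are both implemented and agree by construction.
Finally, hit lists are triaged against the cell line's expression profile:
genes below the (default 12th) percentile are recorded as not expressed and
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .plate_model import ExpressionProfile

VIABILITY_BINS = ("Hi", "CV1", "CV2", "CV3", "LC")
LACTATE_BINS = ("LAC1", "LAC2", "LAC3", "LAC4", "LAC5")
#: T48 cell-count bins; LC is the low-cell exclusion regime (FC < 0.2).
COUNT_BINS = ("Hi", "CV1", "CV2", "LC")

#: Enumerated drug-enhancer (control bin, drug bin) pairs.
ENHANCER_PAIRS_VIABILITY = frozenset({
    ("Hi", "CV2"), ("Hi", "CV3"), ("Hi", "LC"),
    ("CV1", "CV3"), ("CV1", "LC"),
    ("CV2", "LC"),
})
ENHANCER_PAIRS_LACTATE = frozenset({
    ("LAC1", "LAC3"), ("LAC1", "LAC4"), ("LAC1", "LAC5"),
    ("LAC2", "LAC4"), ("LAC2", "LAC5"),
    ("LAC3", "LAC5"),
})


@dataclass(frozen=True)
class BinScheme:
    """Configurable bin edges and hit thresholds.

    Edges are the lower bounds of successive lower-severity bins, strictly
    decreasing; values below the last edge land in the most severe bin.
    ``viability_lc_on`` selects whether the viability ``LC`` bin is defined
    by the deltaT sign (default: deltaT FC < 0, i.e. net cell death) or by
    the T48 count fold change.
    """

    viability_edges: tuple[float, ...] = (0.8, 0.4, 0.08, 0.0)
    lactate_edges: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    count_edges: tuple[float, ...] = (0.8, 0.4, 0.2)
    low_cell_fc: float = 0.2          # T48 FC below which lactate is unreliable
    z_viability: float = -1.5
    z_glycolysis: float = -1.66
    expression_percentile: float = 12.0
    viability_lc_on: str = "deltat_sign"   # or "t48_fc"

    def __post_init__(self):
        for edges, labels in ((self.viability_edges, VIABILITY_BINS),
                              (self.lactate_edges, LACTATE_BINS),
                              (self.count_edges, COUNT_BINS)):
            if len(edges) != len(labels) - 1:
                raise ValueError("need one edge fewer than bin labels")
            if any(a <= b for a, b in zip(edges, edges[1:])):
                raise ValueError("bin edges must be strictly decreasing")

    def edges(self, parameter: str) -> tuple[float, ...]:
        return {"viability": self.viability_edges,
                "lactate": self.lactate_edges,
                "t48_count": self.count_edges}[parameter]

    def labels(self, parameter: str) -> tuple[str, ...]:
        return {"viability": VIABILITY_BINS,
                "lactate": LACTATE_BINS,
                "t48_count": COUNT_BINS}[parameter]


DEFAULT_SCHEME = BinScheme()


def severity_index(label: str, parameter: str) -> int:
    """Position of a bin on the ordered severity scale (0 = least severe)."""
    return {"viability": VIABILITY_BINS, "lactate": LACTATE_BINS,
            "t48_count": COUNT_BINS}[parameter].index(label)


def assign_bin(fc, scheme: BinScheme = DEFAULT_SCHEME, parameter: str = "viability"):
    """Map fold changes to bin labels (vectorized; NaN propagates as None).

    The partition is half-open ``[edge_i, edge_{i-1})`` with the boundary
    assigned to the lower-severity side: a value exactly equal to an edge
    takes the bin above that edge.
    """
    fc_arr = np.asarray(fc, dtype=float)
    scalar = fc_arr.ndim == 0
    fc_arr = np.atleast_1d(fc_arr)
    edges = np.asarray(scheme.edges(parameter))
    labels = np.asarray(scheme.labels(parameter), dtype=object)
    # descending edges: count how many edges are strictly above the value
    idx = (fc_arr[:, None] < edges[None, :]).sum(axis=1)
    out = labels[idx]
    out = np.where(np.isfinite(fc_arr), out, None)
    return out[0] if scalar else out


def call_viability_hits(z_deltat_control) -> np.ndarray:
    """Hit iff control-arm deltaT robust Z < -1.5 (strict)."""
    z = np.asarray(z_deltat_control, dtype=float)
    return np.isfinite(z) & (z < DEFAULT_SCHEME.z_viability)


def call_viability_hits_with(z_deltat_control, scheme: BinScheme) -> np.ndarray:
    z = np.asarray(z_deltat_control, dtype=float)
    return np.isfinite(z) & (z < scheme.z_viability)


def call_glycolysis_hits(z_lactate_control, t48_fc_control,
                         scheme: BinScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Hit iff control-arm lactate robust Z < -1.66, after low-cell filtering.

    Genes in the control low-count bin (T48 FC < ``scheme.low_cell_fc``) are
    removed first — lactate quantitation is unreliable at low cell number —
    and can never be glycolysis hits.
    """
    z = np.asarray(z_lactate_control, dtype=float)
    t48 = np.asarray(t48_fc_control, dtype=float)
    not_lc = np.isfinite(t48) & (t48 >= scheme.low_cell_fc)
    return not_lc & np.isfinite(z) & (z < scheme.z_glycolysis)


def is_enhancer_pair(control_bin: str, drug_bin: str, parameter: str) -> bool:
    """Enumerated pair-table form of the drug-enhancer rule."""
    pairs = (ENHANCER_PAIRS_VIABILITY if parameter == "viability"
             else ENHANCER_PAIRS_LACTATE)
    return (control_bin, drug_bin) in pairs


def is_enhancer_by_index(control_bin: str, drug_bin: str, parameter: str) -> bool:
    """Severity-difference form: drug bin >= 2 levels more severe than control."""
    return (severity_index(drug_bin, parameter)
            - severity_index(control_bin, parameter)) >= 2


def call_drug_enhancers(control_bins, drug_bins, parameter: str,
                        rule: str = "pairs") -> np.ndarray:
    """Drug-enhancer flags from per-gene control/drug bins.

    ``rule`` selects the enumerated pair table (default) or the equivalent
    severity-index rule; genes with an undefined bin in either arm are never
    enhancers. Lactate enhancer candidates must already be filtered for the
    low-cell count bin in both arms by the caller.
    """
    fn = is_enhancer_pair if rule == "pairs" else is_enhancer_by_index
    out = np.zeros(len(control_bins), dtype=bool)
    for i, (cb, db) in enumerate(zip(control_bins, drug_bins)):
        if cb is None or db is None or (isinstance(cb, float) and np.isnan(cb)) \
                or (isinstance(db, float) and np.isnan(db)):
            continue
        out[i] = fn(cb, db, parameter)
    return out


@dataclass(frozen=True)
class TriageResult:
    """Outcome of expression triage for one hit list."""

    retained: tuple[int, ...]
    removed: tuple[int, ...]
    missing: tuple[int, ...]      # hits without an expression value (kept, flagged)
    threshold: float
    percentile: float

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def expression_triage(hit_genes, profile: ExpressionProfile,
                      percentile: float = 12.0,
                      missing_policy: str = "keep") -> TriageResult:
    """Remove hit genes not expressed in the screened cell line.

    The threshold is the empirical ``percentile`` of the whole expression
    profile; hits with an expression value strictly below it are recorded as
    ``removed_not_expressed``. Hits absent from the profile follow
    ``missing_policy`` (``"keep"``, the default, keeps them flagged;
    ``"remove"`` drops them).
    """
    if missing_policy not in ("keep", "remove"):
        raise ValueError("missing_policy must be 'keep' or 'remove'")
    threshold = profile.percentile(percentile)
    retained, removed, missing = [], [], []
    for gene in hit_genes:
        value = profile.value(int(gene))
        if np.isnan(value):
            missing.append(int(gene))
            (retained if missing_policy == "keep" else removed).append(int(gene))
        elif value < threshold:
            removed.append(int(gene))
        else:
            retained.append(int(gene))
    return TriageResult(tuple(retained), tuple(removed), tuple(missing),
                        float(threshold), float(percentile))
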