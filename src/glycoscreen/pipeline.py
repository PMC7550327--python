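"""End-to-end screen analysis: quantitation -> normalization -> QC -> hit calling.

``analyze_primary`` executes the full primary-screen analysis on long-format
measurement tables; ``analyze_deconvolution`` runs the duplex-level
validation against a primary screen's bins. Both are pure functions of their
input tables; the ``run_*`` wrappers add file I/O, configuration and
provenance for the command-line interface.

A note on calibration scopes in the deconvolution analysis: bin thresholds
are primary-screen constructs, so the binned *lactate* criterion converts
duplex absorbances with the primary screen's standard curve and normalizes
to the primary screen's NT lactate-per-cell reference. If the assay gain
drifted between batches this analysis is biased — which is exactly what
``dynamic_range_check`` detects, and why the drug/control ratio criterion
(gain cancels within each gene) is advised for attenuated batches. Count
and deltaT criteria involve no calibration step and use within-screen fold
changes throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .plate_model import (Arm, WellRole, ExpressionProfile,
                          read_screen_table, write_screen_table,
                          write_results_table)
from .quantitation import StandardCurve, fit_standard_curve
from .screen_stats import MAD_CONSTANT, add_plate_fc, robust_z
from .qc_metrics import (control_cv, control_cv_gate, replicate_correlation,
                         ssmd, z_prime)
from .hit_calling import (BinScheme, DEFAULT_SCHEME, assign_bin,
                          call_drug_enhancers, call_glycolysis_hits,
                          call_viability_hits_with, expression_triage,
                          TriageResult)
from .deconvolution import (duplex_pass_binned,
                            duplex_pass_threshold, dynamic_range_check,
                            nt_ratio_threshold, validate_genes)

log = logging.getLogger("glycoscreen")

INSTANCE_KEYS = ["library_plate", "arm", "replicate"]


@dataclass
class HitList:
    name: str
    pre_triage: tuple
    post_triage: tuple
    triage: TriageResult | None = None


@dataclass
class PrimaryResult:
    """Outputs of the primary-screen analysis."""

    metrics: pd.DataFrame
    well_table: pd.DataFrame
    plate_qc: pd.DataFrame
    screen_qc: dict
    curve: StandardCurve
    scheme: BinScheme
    failed_plates: list
    hits: dict
    nt_reference: dict


@dataclass
class DeconvResult:
    """Outputs of the deconvolution validation analysis."""

    duplex_metrics: pd.DataFrame
    summaries: dict
    confirmed: pd.DataFrame
    nt_ratio_threshold: float
    threshold_degenerate: bool
    attenuation_report: object
    curve: StandardCurve
    incomplete_genes: tuple = ()

    def summary_table(self) -> pd.DataFrame:
        """Validation layout: criterion x (0/4..4/4, confirmed, %)."""
        rows = []
        for name, s in self.summaries.items():
            row = {"criterion": name}
            row.update({f"{k}/4": v for k, v in s.histogram.items()})
            row["confirmed"] = s.confirmed
            row["confirmed_pct"] = s.confirmed_percent
            rows.append(row)
        return pd.DataFrame(rows)


def _well_metrics(measurements: pd.DataFrame, curve: StandardCurve,
                  scheme: BinScheme, dilution_factor: float = 3.0) -> pd.DataFrame:
    """Per-well derived values for the T48 arms.

    Adds plate background, net lactate concentration, T48 fold change,
    lactate per cell (low-cell wells excluded), per-plate NT fold changes
    and the per-replicate deltaT fold change.
    """
    t48 = measurements[measurements["arm"] != Arm.T0.value].copy()
    if t48.empty:
        raise ValueError("no post-treatment (control/drug) measurements")

    media = t48[t48["role"] == WellRole.MEDIA.value]
    bg = (media.groupby(INSTANCE_KEYS)["absorbance"].mean()
          .rename("plate_background").reset_index())
    t48 = t48.merge(bg, on=INSTANCE_KEYS, how="left")
    net = t48["absorbance"] - t48["plate_background"]
    t48["concentration_mm"] = dilution_factor * net.clip(lower=0) / curve.slope
    t48["concentration_clamped"] = net < 0

    t48 = add_plate_fc(t48, "cell_count", "t48_fc")
    counts = t48["cell_count"].where(t48["cell_count"] > 0)
    per_cell = t48["concentration_mm"] / counts
    low_cell = t48["t48_fc"] < scheme.low_cell_fc
    t48["low_cell_well"] = low_cell.fillna(False)
    t48["lactate_per_cell"] = per_cell.where(~t48["low_cell_well"])
    t48 = add_plate_fc(t48, "lactate_per_cell", "lactate_fc")

    t0 = measurements[measurements["arm"] == Arm.T0.value]
    t0 = (t0[["library_plate", "replicate", "well", "cell_count"]]
          .rename(columns={"cell_count": "t0_count"}))
    t48 = t48.merge(t0, on=["library_plate", "replicate", "well"], how="left")
    t48["deltat"] = t48["cell_count"] - t48["t0_count"]
    t48 = add_plate_fc(t48, "deltat", "deltat_fc")
    return t48


def _plate_qc(t48: pd.DataFrame, measurements: pd.DataFrame,
              cv_threshold: float) -> tuple[pd.DataFrame, list]:
    """Per-plate-instance control statistics and the CV gate."""
    rows, failed = [], []
    for keys, grp in t48.groupby(INSTANCE_KEYS):
        nt = grp[grp["role"] == WellRole.NT.value]
        plk1 = grp[grp["role"] == WellRole.PLK1.value]
        pdk1 = grp[grp["role"] == WellRole.PDK1.value]
        gate = control_cv_gate({
            "NT/cell_count": nt["cell_count"],
            "NT/deltat": nt["deltat"],
            "NT/lactate_per_cell": nt["lactate_per_cell"],
        }, threshold=cv_threshold)
        ssmd_count = ssmd(plk1["t48_fc"], nt["t48_fc"])
        ssmd_deltat = ssmd(plk1["deltat_fc"], nt["deltat_fc"])
        ssmd_lac = ssmd(pdk1["lactate_fc"], nt["lactate_fc"])
        row = dict(zip(INSTANCE_KEYS, keys))
        row.update({
            "cv_nt_count": control_cv(nt["cell_count"]),
            "cv_nt_deltat": control_cv(nt["deltat"]),
            "cv_nt_lactate": control_cv(nt["lactate_per_cell"]),
            "cv_plk1_count": control_cv(plk1["cell_count"]),
            "cv_pdk1_lactate": control_cv(pdk1["lactate_per_cell"]),
            "zprime_count": z_prime(plk1["cell_count"], nt["cell_count"]),
            "zprime_deltat": z_prime(plk1["deltat"], nt["deltat"]),
            "zprime_lactate": z_prime(pdk1["lactate_per_cell"],
                                      nt["lactate_per_cell"]),
            "ssmd_count": ssmd_count.value,
            "ssmd_deltat": ssmd_deltat.value,
            "ssmd_deltat_reason": ssmd_deltat.reason,
            "ssmd_lactate": ssmd_lac.value,
            "passed": gate.passed,
            "fail_reasons": "; ".join(gate.reasons),
        })
        rows.append(row)
        if not gate.passed:
            failed.append(keys)
    return pd.DataFrame(rows), failed


def _replicate_qc(t48: pd.DataFrame) -> dict:
    """Pooled raw replicate correlations over library wells, per arm."""
    lib = t48[t48["role"] == WellRole.LIBRARY.value]
    out = {}
    for arm, grp in lib.groupby("arm"):
        wide_c = grp.pivot_table(index=["library_plate", "well"],
                                 columns="replicate", values="cell_count")
        wide_a = grp.pivot_table(index=["library_plate", "well"],
                                 columns="replicate", values="absorbance")
        if {1, 2} <= set(wide_c.columns):
            out[f"pearson_count_{arm}"] = replicate_correlation(
                wide_c[1], wide_c[2])
        if {1, 2} <= set(wide_a.columns):
            out[f"pearson_lactate_{arm}"] = replicate_correlation(
                wide_a[1], wide_a[2])
    return out


def _viability_bins(deltat_fc, t48_fc, scheme: BinScheme):
    if scheme.viability_lc_on == "t48_fc":
        bins = assign_bin(deltat_fc, scheme, "viability")
        t48 = np.asarray(t48_fc, dtype=float)
        lc = np.isfinite(t48) & (t48 < scheme.low_cell_fc)
        bins = np.where(lc & pd.notna(bins), "LC", bins)
        return bins
    return assign_bin(deltat_fc, scheme, "viability")


def analyze_primary(measurements: pd.DataFrame, standards: pd.DataFrame,
                    scheme: BinScheme = DEFAULT_SCHEME,
                    expression: ExpressionProfile | None = None,
                    qc_gate: bool = True, cv_threshold: float = 30.0,
                    mad_constant: float = MAD_CONSTANT,
                    dilution_factor: float = 3.0,
                    enhancer_rule: str = "pairs") -> PrimaryResult:
    """Full primary-screen analysis.

    Stages: standard-curve fit, background subtraction and lactate
    quantitation, per-plate NT normalization (T48 counts, deltaT, lactate
    per cell), plate QC with the 30% control-CV gate (failed plate
    instances are excluded from hit calling but stay in the QC report),
    replicate averaging, screen-wide robust Z-scores, bin assignment, hit
    and drug-enhancer calling, and optional expression triage.
    """
    curve = fit_standard_curve(standards["concentration_mm"],
                               standards["absorbance"])
    t48 = _well_metrics(measurements, curve, scheme, dilution_factor)
    plate_qc, failed = _plate_qc(t48, measurements, cv_threshold)
    screen_qc = _replicate_qc(t48)

    usable = t48
    if qc_gate and failed:
        bad = pd.MultiIndex.from_tuples(failed, names=INSTANCE_KEYS)
        idx = pd.MultiIndex.from_frame(t48[INSTANCE_KEYS])
        usable = t48[~idx.isin(bad)]
        for keys in failed:
            log.info("plate instance %s failed the control CV gate; "
                     "excluded from hit calling", keys)

    lib = usable[(usable["role"] == WellRole.LIBRARY.value)
                 & (usable["catalog_id"] != "")]
    agg = (lib.groupby(["catalog_id", "entrez_id", "duplex", "arm"])
           .agg(t48_fc=("t48_fc", "mean"), deltat_fc=("deltat_fc", "mean"),
                lactate_fc=("lactate_fc", "mean"),
                lactate_per_cell=("lactate_per_cell", "mean"),
                t48_raw=("cell_count", "mean"), t0_raw=("t0_count", "mean"),
                n_rep=("t48_fc", "count"))
           .reset_index())
    wide = agg.pivot(index=["catalog_id", "entrez_id", "duplex"],
                     columns="arm")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    wide = wide.rename(columns={"t0_raw_control": "t0_raw"})

    for arm in ("control", "drug"):
        for param, col in (("t48", f"t48_fc_{arm}"),
                           ("deltat", f"deltat_fc_{arm}"),
                           ("lactate", f"lactate_fc_{arm}")):
            if col not in wide.columns:
                wide[col] = np.nan
            z, _info = robust_z(wide[col].to_numpy(),
                                mad_constant=mad_constant)
            wide[f"z_{param}_{arm}"] = z
        wide[f"bin_t48_{arm}"] = assign_bin(
            wide[f"t48_fc_{arm}"].to_numpy(), scheme, "t48_count")
        wide[f"bin_deltat_{arm}"] = _viability_bins(
            wide[f"deltat_fc_{arm}"].to_numpy(),
            wide[f"t48_fc_{arm}"].to_numpy(), scheme)
        wide[f"bin_lactate_{arm}"] = assign_bin(
            wide[f"lactate_fc_{arm}"].to_numpy(), scheme, "lactate")
        t48_arm = wide[f"t48_fc_{arm}"].to_numpy(dtype=float)
        wide[f"low_cell_{arm}"] = np.isfinite(t48_arm) & (t48_arm < scheme.low_cell_fc)

    wide["viability_hit"] = call_viability_hits_with(
        wide["z_deltat_control"].to_numpy(), scheme)
    wide["glycolysis_hit"] = call_glycolysis_hits(
        wide["z_lactate_control"].to_numpy(),
        wide["t48_fc_control"].to_numpy(), scheme)
    wide["viability_enhancer"] = call_drug_enhancers(
        wide["bin_deltat_control"], wide["bin_deltat_drug"],
        "viability", rule=enhancer_rule)
    wide["glycolysis_enhancer"] = (
        call_drug_enhancers(wide["bin_lactate_control"],
                            wide["bin_lactate_drug"], "lactate",
                            rule=enhancer_rule)
        & ~wide["low_cell_control"] & ~wide["low_cell_drug"])
    wide["exclusion_reason"] = np.where(wide["low_cell_control"],
                                        "low_cell_density", "")

    hits = {}
    status = pd.Series("", index=wide.index, dtype=object)
    for name in ("viability_hit", "glycolysis_hit",
                 "viability_enhancer", "glycolysis_enhancer"):
        genes = tuple(int(g) for g in wide.loc[wide[name], "entrez_id"])
        if expression is not None:
            tri = expression_triage(genes, expression,
                                    percentile=scheme.expression_percentile)
            hits[name] = HitList(name, genes, tri.retained, tri)
            removed = set(tri.removed)
            mask = wide[name] & wide["entrez_id"].astype(int).isin(removed)
            status[mask] = "removed_not_expressed"
            status[wide[name] & ~mask & (status == "")] = "expressed"
            wide[name] = wide[name] & ~wide["entrez_id"].astype(int).isin(removed)
            wide[f"{name}_pre_triage"] = [int(g) in set(genes)
                                          for g in wide["entrez_id"].astype(int)]
        else:
            hits[name] = HitList(name, genes, genes, None)
    wide["triage_status"] = status

    nt_wells = t48[t48["role"] == WellRole.NT.value]
    nt_reference = {
        "lactate_per_cell_control": float(
            nt_wells.loc[nt_wells["arm"] == "control", "lactate_per_cell"].mean()),
        "lactate_per_cell_drug": float(
            nt_wells.loc[nt_wells["arm"] == "drug", "lactate_per_cell"].mean()),
    }

    screen_qc.update(_screen_summary(plate_qc))
    log.info("primary analysis: %d genes, %d plate instances (%d failed gate)",
             len(wide), len(plate_qc), len(failed))
    return PrimaryResult(metrics=wide, well_table=t48, plate_qc=plate_qc,
                         screen_qc=screen_qc, curve=curve, scheme=scheme,
                         failed_plates=failed, hits=hits,
                         nt_reference=nt_reference)


def _screen_summary(plate_qc: pd.DataFrame) -> dict:
    out = {}
    for col in ("zprime_count", "zprime_deltat", "zprime_lactate",
                "ssmd_count", "ssmd_lactate"):
        for arm in ("control", "drug"):
            vals = plate_qc.loc[plate_qc["arm"] == arm, col]
            vals = vals[np.isfinite(vals)]
            out[f"{col}_{arm}"] = float(vals.mean()) if len(vals) else float("nan")
    out["n_failed_plates"] = int((~plate_qc["passed"]).sum())
    return out


# ---------------------------------------------------------------------------
# Deconvolution

DECONV_CRITERIA = (
    ("control_t48_bin", "t48_fc_control", "bin_t48_control", "t48_count"),
    ("drug_t48_bin", "t48_fc_drug", "bin_t48_drug", "t48_count"),
    ("control_deltat_bin", "deltat_fc_control", "bin_deltat_control", "viability"),
    ("drug_deltat_bin", "deltat_fc_drug", "bin_deltat_drug", "viability"),
    ("control_lactate_bin", "lactate_fc_control", "bin_lactate_control", "lactate"),
)


def analyze_deconvolution(measurements: pd.DataFrame, standards: pd.DataFrame,
                          primary_bins: pd.DataFrame,
                          scheme: BinScheme = DEFAULT_SCHEME,
                          min_duplexes: int = 2,
                          primary_curve: StandardCurve | None = None,
                          primary_nt_lactate_per_cell: float | None = None,
                          ratio_threshold_override: float | None = None,
                          dilution_factor: float = 3.0,
                          dynamic_range_trigger: float = 0.2) -> DeconvResult:
    """Duplex-level validation against the primary screen's bins.

    ``primary_bins`` is indexed by ``entrez_id`` and carries the gene's
    primary-screen bins (``bin_t48_control`` ... ``bin_lactate_control``).
    When the primary standard curve and NT lactate reference are supplied,
    the binned lactate criterion uses that (primary) calibration; otherwise
    it falls back to within-screen normalization. The drug/control
    lactate-per-cell ratio criterion thresholds at 2 SD below the NT
    control ratios (recomputed here unless overridden).
    """
    deconv_curve = fit_standard_curve(standards["concentration_mm"],
                                      standards["absorbance"])
    report = None
    if primary_curve is not None:
        report = dynamic_range_check(primary_curve, deconv_curve,
                                     trigger=dynamic_range_trigger)
    lactate_curve = primary_curve if primary_curve is not None else deconv_curve
    t48 = _well_metrics(measurements, lactate_curve, scheme, dilution_factor)

    if primary_nt_lactate_per_cell is not None:
        t48["lactate_fc"] = t48["lactate_per_cell"] / primary_nt_lactate_per_cell

    lib = t48[(t48["role"] == WellRole.LIBRARY.value) & (t48["catalog_id"] != "")]
    agg = (lib.groupby(["catalog_id", "entrez_id", "duplex", "arm"])
           .agg(t48_fc=("t48_fc", "mean"), deltat_fc=("deltat_fc", "mean"),
                lactate_fc=("lactate_fc", "mean"),
                lactate_per_cell=("lactate_per_cell", "mean"))
           .reset_index())
    wide = agg.pivot(index=["catalog_id", "entrez_id", "duplex"], columns="arm")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    wide["lactate_ratio"] = (wide["lactate_per_cell_drug"]
                             / wide["lactate_per_cell_control"])

    nt = t48[t48["role"] == WellRole.NT.value]
    nt_pc = nt.pivot_table(index=["library_plate", "well"], columns="arm",
                           values="lactate_per_cell")
    nt_ratios = (nt_pc["drug"] / nt_pc["control"]).dropna()
    if ratio_threshold_override is not None:
        threshold, degenerate = float(ratio_threshold_override), False
    else:
        threshold, degenerate = nt_ratio_threshold(nt_ratios)

    bins = primary_bins.copy()
    if "entrez_id" in bins.columns:
        bins = bins.set_index("entrez_id")
    wide = wide.merge(bins, left_on="entrez_id", right_index=True,
                      how="left", suffixes=("", "_primary"))

    summaries, confirmed_cols = {}, {}
    for name, fc_col, bin_col, param in DECONV_CRITERIA:
        passes = []
        for fc, pbin in zip(wide[fc_col], wide[bin_col]):
            if pbin is None or (isinstance(pbin, float) and np.isnan(pbin)):
                passes.append(None)
            else:
                passes.append(duplex_pass_binned(fc, pbin, scheme, param))
        wide[f"pass_{name}"] = passes
        conf, summ = validate_genes(
            pd.DataFrame({"gene": wide["entrez_id"], "passed": passes}),
            min_duplexes=min_duplexes, criterion=name)
        summaries[name] = summ
        confirmed_cols[name] = conf

    ratio_passes = [duplex_pass_threshold(r, threshold)
                    for r in wide["lactate_ratio"]]
    wide["pass_drug_control_lactate_ratio"] = ratio_passes
    conf, summ = validate_genes(
        pd.DataFrame({"gene": wide["entrez_id"], "passed": ratio_passes}),
        min_duplexes=min_duplexes, criterion="drug_control_lactate_ratio")
    summaries["drug_control_lactate_ratio"] = summ
    confirmed_cols["drug_control_lactate_ratio"] = conf
    incomplete = conf.attrs.get("incomplete_genes", ())

    confirmed = pd.DataFrame(confirmed_cols)
    confirmed.index.name = "entrez_id"
    return DeconvResult(duplex_metrics=wide, summaries=summaries,
                        confirmed=confirmed, nt_ratio_threshold=threshold,
                        threshold_degenerate=degenerate,
                        attenuation_report=report, curve=deconv_curve,
                        incomplete_genes=incomplete)


# ---------------------------------------------------------------------------
# File-level orchestration (CLI backend)

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance(cfg: dict, seed: int | None) -> str:
    return (f"glycoscreen {_version} config_hash={config_hash(cfg)} "
            f"seed={seed}")


def scheme_from_config(cfg: dict) -> BinScheme:
    block = cfg.get("scheme", {})
    kwargs = {}
    for key in ("viability_edges", "lactate_edges", "count_edges"):
        if key in block:
            kwargs[key] = tuple(block[key])
    for key in ("low_cell_fc", "z_viability", "z_glycolysis",
                "expression_percentile", "viability_lc_on"):
        if key in block:
            kwargs[key] = block[key]
    return BinScheme(**kwargs)


def run_simulate(cfg: dict, out_dir: str | Path, seed: int) -> dict:
    """Generate a synthetic screen bundle and write its tables."""
    from .synthetic_screen import SimulationConfig, simulate_screen
    sim_cfg = SimulationConfig(**cfg.get("simulation", {}))
    sim = simulate_screen(sim_cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg, seed)
    write_screen_table(sim.measurements, out / "screen_table.csv", prov)
    sim.standards.to_csv(out / "standards.csv", index=False)
    sim.truth.effects.to_csv(out / "truth_effects.csv", index=False)
    if sim.truth.labels is not None:
        sim.truth.labels.to_csv(out / "truth_labels.csv", index=False)
    manifest = {"seed": seed, "config_hash": config_hash(cfg),
                "n_genes": sim_cfg.n_genes, "version": _version,
                "files": ["screen_table.csv", "standards.csv",
                          "truth_effects.csv", "truth_labels.csv"]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_primary(cfg: dict, out_dir: str | Path, seed: int | None = None) -> PrimaryResult:
    """Read input tables per the config, run the primary analysis, write outputs."""
    paths = cfg.get("paths", {})
    measurements = read_screen_table(paths["screen_table"])
    standards = pd.read_csv(paths["standards"], comment="#")
    expression = (ExpressionProfile.read(paths["expression"])
                  if paths.get("expression") else None)
    scheme = scheme_from_config(cfg)
    qc_cfg = cfg.get("qc", {})
    res = analyze_primary(measurements, standards, scheme=scheme,
                          expression=expression,
                          qc_gate=qc_cfg.get("gate", True),
                          cv_threshold=qc_cfg.get("cv_threshold", 30.0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg, seed)
    write_results_table(res.metrics, out / "gene_results.csv", prov)
    res.plate_qc.to_csv(out / "plate_qc.csv", index=False)
    payload = {
        "screen_qc": {k: _jsonable(v) for k, v in res.screen_qc.items()},
        "failed_plates": [list(map(_jsonable, f)) for f in res.failed_plates],
        "hits": {name: {"pre_triage": len(h.pre_triage),
                        "post_triage": len(h.post_triage)}
                 for name, h in res.hits.items()},
        "standard_curve": {"slope": res.curve.slope,
                           "intercept": res.curve.intercept,
                           "r_squared": res.curve.r_squared},
        "provenance": prov,
    }
    with open(out / "screen_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return res


def run_deconvolution(cfg: dict, out_dir: str | Path,
                      seed: int | None = None) -> DeconvResult:
    """Run the duplex-validation analysis from config-specified tables."""
    paths = cfg.get("paths", {})
    measurements = read_screen_table(paths["deconv_table"])
    standards = pd.read_csv(paths["deconv_standards"], comment="#")
    primary_bins = pd.read_csv(paths["primary_bins"], comment="#")
    scheme = scheme_from_config(cfg)
    deconv_cfg = cfg.get("deconvolution", {})
    primary_curve = None
    if paths.get("primary_standards"):
        pstd = pd.read_csv(paths["primary_standards"], comment="#")
        primary_curve = fit_standard_curve(pstd["concentration_mm"],
                                           pstd["absorbance"])
    res = analyze_deconvolution(
        measurements, standards, primary_bins, scheme=scheme,
        min_duplexes=deconv_cfg.get("min_duplexes", 2),
        primary_curve=primary_curve,
        primary_nt_lactate_per_cell=deconv_cfg.get("primary_nt_lactate_per_cell"),
        ratio_threshold_override=deconv_cfg.get("ratio_threshold"))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.duplex_metrics.to_csv(out / "duplex_metrics.csv", index=False)
    res.summary_table().to_csv(out / "validation_summary.csv", index=False)
    payload = {
        "nt_ratio_threshold": res.nt_ratio_threshold,
        "threshold_degenerate": res.threshold_degenerate,
        "confirmed": {k: int(v.sum()) for k, v in res.confirmed.items()},
        "provenance": _provenance(cfg, seed),
    }
    if res.attenuation_report is not None:
        payload["attenuation"] = res.attenuation_report.attenuation
        payload["advise_ratio_criterion"] = bool(
            res.attenuation_report.advise_ratio_criterion)
    with open(out / "deconv_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return res


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
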