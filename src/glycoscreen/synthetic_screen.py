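"""Forward simulator for multiparameter siRNA screens.

Generates per-well measurement tables with the statistical structure the
analysis assumes — plate layouts with controls, three treatment arms
(pre-treatment T0, DMSO control, drug at IC25), duplicate plates, a
lactate assay read through a standard curve — plus planted gene effects so
every downstream stage can be tested against known truth.

Forward model (per well):

* ``T0 = seeded_cells * pre_growth`` (the 72 h from seeding through
  transfection to the pre-treatment fix);
* ``T48 = T0 * arm_growth * viability_multiplier * plate_effect``, with the
  drug arm's net growth scaled to 75% of control (IC25 semantics);
* media lactate = ``yield_per_cell * lactate_multiplier * T48`` (exposure
  proportional to the final cell number, matching the analysis's
  normalization to the T48 count), plus the media's own background lactate;
* absorbance = ``intercept + slope * gain * diluted concentration`` with
  additive Gaussian read noise. ``gain`` is 1 at full assay strength; an
  attenuated enzyme batch (as seen in deconvolution screens) scales the net
  signal so the top 3.2 mM standard loses exactly the configured fraction
  while the 0 mM background is unchanged.

Count noise and plate effects are multiplicative log-normal (keeps
positivity); counts are rounded to whole nuclei. PLK1 control wells get a
strong kill, PDK1 wells a ~0.6 lactate multiplier, NT wells are neutral.
Library genes draw continuous log-normal effect multipliers (the
between-gene dispersion that real screens show, and the reason replicate
plates correlate strongly on raw counts) on top of which hit classes are
planted: strong-kill viability hits, lactate-suppressing glycolysis hits,
and drug enhancers whose effect is conditional on the drug arm. Wells that
die release cellular contents, which the optional death-artifact term
converts into spuriously high lactate.

Truth labels are defined as the analysis outcome on the zero-noise forward
realization (measurement-limit labels): with noise disabled the pipeline
reproduces them exactly, and under noise the sensitivity/FDR of the caller
measures noise robustness alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import plate_model
from .plate_model import (Arm, WellRole, SCREEN_COLUMNS, LIBRARY_WELLS_PER_PLATE,
                          MEDIA_COLUMN, build_layout)


DEFAULT_LADDER = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults encode the screen design: 450 cells seeded per well, duplicate
    plates per arm, drug at IC25 (net growth 75% of control), 1:3 media
    dilution, a 0-3.2 mM standard ladder in quadruplicate, and a 36%
    dynamic-range attenuation for deconvolution batches. Noise levels are a
    calibration chosen to reproduce the replicate-plate correlations real
    screens of this design report (~0.93 on raw counts).
    """

    n_genes: int = 2000
    seed_cells: int = 450
    pre_growth: float = 2.0          # seeding -> T0 growth factor
    growth_control: float = 2.0      # T0 -> T48 in the DMSO arm
    drug_viability_factor: float = 0.75   # IC25: drug-arm net growth vs control
    drug_lactate_factor: float = 0.75     # BRAFi suppression of per-cell lactate
    lactate_yield_per_cell: float = 0.0025   # mM media lactate per cell
    media_background_mm: float = 0.45
    curve_slope: float = 0.25        # AU per mM
    curve_intercept: float = 0.10    # AU
    dilution_factor: float = 3.0
    standard_ladder: tuple = DEFAULT_LADDER
    n_standard_replicates: int = 4
    # noise calibration
    count_cv: float = 0.04
    absorbance_sd: float = 0.008
    plate_effect_sd: float = 0.05    # multiplicative, log scale
    # library effect structure
    effect_sd_viability: float = 0.25    # log-sd of the background viability continuum
    effect_sd_lactate: float = 0.25
    #: mild gene-by-drug interaction spread applied to every gene's drug-arm
    #: multipliers (no gene responds to the drug exactly like the NT average)
    drug_interaction_sd_viability: float = 0.05
    drug_interaction_sd_lactate: float = 0.08
    frac_viability_hit: float = 0.05
    frac_glycolysis_hit: float = 0.05
    frac_viability_enhancer: float = 0.025
    frac_glycolysis_enhancer: float = 0.05
    kill_multiplier_range: tuple = (0.02, 0.3)
    glycolysis_multiplier_range: tuple = (0.15, 0.45)
    viability_enhancer_factor_range: tuple = (0.1, 0.5)
    glycolysis_enhancer_factor_range: tuple = (0.25, 0.5)
    # controls
    plk1_multiplier: float = 0.02
    pdk1_lactate_multiplier: float = 0.6
    # death artifact
    death_artifact: bool = True
    artifact_threshold: float = 0.2      # true T48 FC below which contents release
    artifact_mm_per_cell: float = 0.0008  # media lactate bonus per lost cell
    # deconvolution
    deconv_attenuation: float = 0.64     # net-signal fraction retained at 3.2 mM
    duplex_effective_prob: float = 0.55
    duplex_effective_range: tuple = (0.75, 1.0)
    duplex_inert_range: tuple = (0.0, 0.35)

    def __post_init__(self):
        for name in ("seed_cells", "pre_growth", "growth_control",
                     "drug_viability_factor", "drug_lactate_factor",
                     "lactate_yield_per_cell", "curve_slope", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("count_cv",):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be a CV in [0, 1)")
        if not 0 < self.deconv_attenuation <= 1:
            raise ValueError("deconv_attenuation must be in (0, 1]")

    def zero_noise(self) -> "SimulationConfig":
        return replace(self, count_cv=0.0, absorbance_sd=0.0, plate_effect_sd=0.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated screen."""

    seed: int
    config: SimulationConfig
    effects: pd.DataFrame            # per-reagent multipliers and planted class
    labels: pd.DataFrame | None      # per-gene truth flags (zero-noise analysis)
    noiseless_measurements: pd.DataFrame
    noiseless_standards: pd.DataFrame


@dataclass
class SimulatedScreen:
    measurements: pd.DataFrame
    standards: pd.DataFrame
    layout: pd.DataFrame
    truth: SyntheticTruth


def make_gene_table(n_genes: int, prefix: str = "M") -> pd.DataFrame:
    """Synthetic library annotation: one SMARTpool entry per gene."""
    idx = np.arange(1, n_genes + 1)
    return pd.DataFrame({
        "catalog_id": [f"{prefix}-{i:06d}-00" for i in idx],
        "entrez_id": 100000 + idx,
        "gene_symbol": [f"GENE{i}" for i in idx],
        "duplex": 0,
    })


def assay_response(concentration_mm, attenuation: float = 1.0) -> np.ndarray:
    """Effective concentration seen by the colorimetric readout.

    An attenuated enzyme batch converts a constant fraction of the lactate,
    scaling the net signal: the 3.2 mM standard of a 0.64-attenuated batch
    reads 36% lower above background than at full strength, while the 0 mM
    background is unchanged.
    """
    c = np.asarray(concentration_mm, dtype=float)
    return attenuation * c


def draw_gene_effects(genes: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene effect multipliers and planted class labels.

    Every gene draws background log-normal multipliers; planted classes
    override one parameter with a strong, well-separated effect. Class
    labels record the *planting*, not the truth call — truth flags come from
    the zero-noise analysis (``SyntheticTruth.labels``).
    """
    n = len(genes)
    sv, sl = config.effect_sd_viability, config.effect_sd_lactate
    m_v = rng.lognormal(mean=0.0, sigma=sv, size=n) if sv > 0 else np.ones(n)
    m_l = rng.lognormal(mean=0.0, sigma=sl, size=n) if sl > 0 else np.ones(n)

    probs = np.array([config.frac_viability_hit, config.frac_glycolysis_hit,
                      config.frac_viability_enhancer,
                      config.frac_glycolysis_enhancer])
    if probs.sum() > 1:
        raise ValueError("planted class fractions sum to more than 1")
    classes = rng.choice(
        ["viability_hit", "glycolysis_hit", "viability_enhancer",
         "glycolysis_enhancer", "background"],
        size=n, p=np.append(probs, 1.0 - probs.sum()))

    div = config.drug_interaction_sd_viability
    dil = config.drug_interaction_sd_lactate
    w_v = rng.lognormal(0.0, div, size=n) if div > 0 else np.ones(n)
    w_l = rng.lognormal(0.0, dil, size=n) if dil > 0 else np.ones(n)
    eff = pd.DataFrame({
        "catalog_id": genes["catalog_id"].to_numpy(),
        "entrez_id": genes["entrez_id"].to_numpy(),
        "planted_class": classes,
        "m_v_control": m_v, "m_v_drug": m_v * w_v,
        "m_l_control": m_l, "m_l_drug": m_l * w_l,
    })

    def _u(lo_hi, size):
        return rng.uniform(lo_hi[0], lo_hi[1], size=size)

    mask = classes == "viability_hit"
    kill = _u(config.kill_multiplier_range, mask.sum())
    eff.loc[mask, "m_v_control"] = kill
    eff.loc[mask, "m_v_drug"] = kill * w_v[mask]
    mask = classes == "glycolysis_hit"
    glyc = _u(config.glycolysis_multiplier_range, mask.sum())
    eff.loc[mask, "m_l_control"] = glyc
    eff.loc[mask, "m_l_drug"] = glyc * w_l[mask]
    mask = classes == "viability_enhancer"
    eff.loc[mask, "m_v_drug"] = (eff.loc[mask, "m_v_control"]
                                 * _u(config.viability_enhancer_factor_range, mask.sum()))
    mask = classes == "glycolysis_enhancer"
    eff.loc[mask, "m_l_drug"] = (eff.loc[mask, "m_l_control"]
                                 * _u(config.glycolysis_enhancer_factor_range, mask.sum()))
    return eff


def apply_death_artifact(concentration_mm, true_t48_fc, cells_lost,
                         threshold: float = 0.2,
                         mm_per_cell: float = 0.0008,
                         enabled: bool = True) -> np.ndarray:
    """Add the death-release lactate bonus to dying wells.

    Wells whose true T48 fold change falls below ``threshold`` receive an
    additive media-lactate bonus proportional to the cells lost (release of
    cellular contents upon death). With the switch off, concentrations are
    returned unchanged.
    """
    conc = np.asarray(concentration_mm, dtype=float).copy()
    if not enabled:
        return conc
    fc = np.asarray(true_t48_fc, dtype=float)
    lost = np.clip(np.asarray(cells_lost, dtype=float), 0.0, None)
    dying = np.isfinite(fc) & (fc < threshold)
    conc[dying] += mm_per_cell * lost[dying]
    return conc


def _merge_effects(layout: pd.DataFrame, effects: pd.DataFrame,
                   config: SimulationConfig) -> pd.DataFrame:
    lay = layout.merge(
        effects[["catalog_id", "m_v_control", "m_v_drug", "m_l_control", "m_l_drug"]],
        on="catalog_id", how="left")
    for col in ("m_v_control", "m_v_drug", "m_l_control", "m_l_drug"):
        lay[col] = lay[col].fillna(1.0)
    plk1 = lay["role"] == WellRole.PLK1.value
    lay.loc[plk1, ["m_v_control", "m_v_drug"]] = config.plk1_multiplier
    pdk1 = lay["role"] == WellRole.PDK1.value
    lay.loc[pdk1, ["m_l_control", "m_l_drug"]] = config.pdk1_lactate_multiplier
    return lay


def _simulate_wells(lay: pd.DataFrame, config: SimulationConfig,
                    noise_rng: np.random.Generator | None,
                    plate_rng: np.random.Generator | None,
                    attenuation: float = 1.0) -> pd.DataFrame:
    """Generate the six plate instances (3 arms x 2 replicates) for a layout.

    ``noise_rng``/``plate_rng`` of None generates the noiseless realization
    (rounding still applies: counts are whole nuclei).
    """
    arm_reps = [(Arm.T0.value, 1), (Arm.T0.value, 2),
                (Arm.CONTROL.value, 1), (Arm.CONTROL.value, 2),
                (Arm.DRUG.value, 1), (Arm.DRUG.value, 2)]
    plates = np.sort(lay["plate"].unique())
    cv = config.count_cv
    sigma_c = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    frames = []
    for arm, rep in arm_reps:
        for plate in plates:
            sub = lay[lay["plate"] == plate]
            n = len(sub)
            has_cells = (sub["col"] < MEDIA_COLUMN).to_numpy()
            pe = 1.0
            if plate_rng is not None and config.plate_effect_sd > 0:
                pe = plate_rng.lognormal(mean=0.0, sigma=config.plate_effect_sd)

            t0_true = config.seed_cells * config.pre_growth * has_cells
            if arm == Arm.T0.value:
                true_count = t0_true
                absorbance = np.full(n, np.nan)
            else:
                drug = arm == Arm.DRUG.value
                growth = config.growth_control * (
                    config.drug_viability_factor if drug else 1.0)
                m_v = sub[f"m_v_{arm}"].to_numpy()
                m_l = sub[f"m_l_{arm}"].to_numpy()
                t48_bio = t0_true * growth * m_v * pe
                yield_eff = config.lactate_yield_per_cell * (
                    config.drug_lactate_factor if drug else 1.0)
                produced = yield_eff * m_l * t48_bio
                produced = apply_death_artifact(
                    produced, np.where(has_cells, m_v, np.nan),
                    t0_true * pe - t48_bio,
                    threshold=config.artifact_threshold,
                    mm_per_cell=config.artifact_mm_per_cell,
                    enabled=config.death_artifact)
                c_assay = (config.media_background_mm * has_cells_media(sub)
                           + produced) / config.dilution_factor
                absorbance = (config.curve_intercept
                              + config.curve_slope * assay_response(c_assay, attenuation))
                if noise_rng is not None and config.absorbance_sd > 0:
                    absorbance = absorbance + noise_rng.normal(
                        0.0, config.absorbance_sd, size=n)
                true_count = t48_bio
            if noise_rng is not None and sigma_c > 0:
                noise = noise_rng.lognormal(mean=-0.5 * sigma_c ** 2,
                                            sigma=sigma_c, size=n)
            else:
                noise = 1.0
            counts = np.round(true_count * noise).astype(float)

            frames.append(pd.DataFrame({
                "library_plate": plate, "arm": arm, "replicate": rep,
                "well": sub["well"].to_numpy(), "row": sub["row"].to_numpy(),
                "col": sub["col"].to_numpy(), "role": sub["role"].to_numpy(),
                "catalog_id": sub["catalog_id"].to_numpy(),
                "entrez_id": sub["entrez_id"].to_numpy(),
                "duplex": sub["duplex"].to_numpy(),
                "cell_count": counts, "absorbance": absorbance,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out[SCREEN_COLUMNS]


def has_cells_media(sub: pd.DataFrame) -> np.ndarray:
    """All wells contain media (and hence the media's background lactate)."""
    return np.ones(len(sub))


def simulate_standard_plate(config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            attenuation: float = 1.0,
                            batch: str = "primary") -> pd.DataFrame:
    """Quadruplicate standard-curve wells over the 0-3.2 mM ladder."""
    conc = np.repeat(np.asarray(config.standard_ladder, dtype=float),
                     config.n_standard_replicates)
    a = config.curve_intercept + config.curve_slope * assay_response(conc, attenuation)
    if rng is not None and config.absorbance_sd > 0:
        a = a + rng.normal(0.0, config.absorbance_sd, size=conc.size)
    return pd.DataFrame({"batch": batch, "concentration_mm": conc, "absorbance": a})


def _truth_labels(measurements: pd.DataFrame, standards: pd.DataFrame):
    # deferred import: pipeline orchestrates this module's outputs
    from .pipeline import analyze_primary
    res = analyze_primary(measurements, standards, qc_gate=False)
    cols = ["catalog_id", "entrez_id",
            "viability_hit", "glycolysis_hit",
            "viability_enhancer", "glycolysis_enhancer",
            "bin_deltat_control", "bin_deltat_drug",
            "bin_lactate_control", "bin_lactate_drug",
            "low_cell_control", "low_cell_drug"]
    return res.metrics[cols].copy()


def simulate_screen(config: SimulationConfig, seed: int = 0,
                    layout: pd.DataFrame | None = None,
                    effects: pd.DataFrame | None = None,
                    attenuation: float = 1.0,
                    label_truth: bool = True) -> SimulatedScreen:
    """Simulate a full primary screen and its ground truth.

    Identical ``(config, seed)`` reproduce byte-identical tables. The truth
    labels are obtained by running the primary analysis on the zero-noise
    realization of the same gene effects.
    """
    ss = np.random.SeedSequence(seed)
    rng_effects, rng_noise, rng_plate = (np.random.default_rng(c)
                                         for c in ss.spawn(3))
    if layout is None:
        genes = make_gene_table(config.n_genes)
        n_plates = max(1, math.ceil(len(genes) / LIBRARY_WELLS_PER_PLATE))
        layout = build_layout(n_plates, genes=genes)
    else:
        genes = (layout.loc[layout["role"] == WellRole.LIBRARY.value,
                            ["catalog_id", "entrez_id", "gene_symbol", "duplex"]]
                 .drop_duplicates("catalog_id").reset_index(drop=True))
    if effects is None:
        effects = draw_gene_effects(genes, config, rng_effects)

    lay = _merge_effects(layout, effects, config)
    measurements = _simulate_wells(lay, config, rng_noise, rng_plate, attenuation)
    standards = simulate_standard_plate(config, rng_noise, attenuation)

    noiseless = _simulate_wells(lay, config, None, None, attenuation)
    noiseless_std = simulate_standard_plate(config, None, attenuation)
    labels = _truth_labels(noiseless, noiseless_std) if label_truth else None

    truth = SyntheticTruth(seed=seed, config=config, effects=effects,
                           labels=labels, noiseless_measurements=noiseless,
                           noiseless_standards=noiseless_std)
    return SimulatedScreen(measurements=measurements, standards=standards,
                           layout=layout, truth=truth)


def make_duplex_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Expand pool-level annotation into 4 duplex entries per gene."""
    rows = []
    for _, g in genes.iterrows():
        base = str(g["catalog_id"]).rsplit("-", 1)[0]
        for d in range(1, 5):
            rows.append((f"{base}-{d:02d}", g["entrez_id"],
                         g.get("gene_symbol", ""), d))
    return pd.DataFrame(rows, columns=["catalog_id", "entrez_id",
                                       "gene_symbol", "duplex"])


def draw_duplex_efficacy(n_genes: int, rng: np.random.Generator,
                         config: SimulationConfig,
                         profile=None) -> np.ndarray:
    """Per-duplex knockdown efficacy in [0, 1]; some duplexes are inert.

    ``profile`` forces a fixed efficacy vector (length 4) for every gene,
    e.g. ``(1, 1, 0, 0)``.
    """
    if profile is not None:
        return np.tile(np.asarray(profile, dtype=float), (n_genes, 1))
    effective = rng.random((n_genes, 4)) < config.duplex_effective_prob
    lo_e, hi_e = config.duplex_effective_range
    lo_i, hi_i = config.duplex_inert_range
    eff = np.where(effective,
                   rng.uniform(lo_e, hi_e, size=(n_genes, 4)),
                   rng.uniform(lo_i, hi_i, size=(n_genes, 4)))
    return eff


def simulate_deconvolution(config: SimulationConfig,
                           pool_effects: pd.DataFrame,
                           seed: int = 0,
                           duplex_efficacy=None,
                           attenuation: float | None = None) -> SimulatedScreen:
    """Simulate the duplex-level validation screen for a set of genes.

    ``pool_effects`` carries the pool-level multipliers (rows of a primary
    screen's ``truth.effects``). Each gene contributes 4 duplexes whose
    multipliers interpolate between neutral (inert duplex) and the full pool
    phenotype: ``m_duplex = 1 - e * (1 - m_pool)``. Lactate absorbances are
    read through the attenuated assay response (``config.deconv_attenuation``
    by default), emulating the reduced dynamic range of a separate assay
    batch.
    """
    if attenuation is None:
        attenuation = config.deconv_attenuation
    ss = np.random.SeedSequence(seed)
    rng_eff, rng_noise, rng_plate = (np.random.default_rng(c) for c in ss.spawn(3))

    pool = pool_effects.reset_index(drop=True)
    duplexes = make_duplex_table(pool)
    eff = draw_duplex_efficacy(len(pool), rng_eff, config, duplex_efficacy)
    # interpolate each multiplier toward the pool phenotype
    dup_effects = duplexes.copy()
    for col in ("m_v_control", "m_v_drug", "m_l_control", "m_l_drug"):
        m_pool = np.repeat(pool[col].to_numpy(), 4)
        dup_effects[col] = 1.0 - eff.ravel() * (1.0 - m_pool)
    dup_effects["efficacy"] = eff.ravel()
    dup_effects["planted_class"] = np.repeat(pool["planted_class"].to_numpy(), 4)

    n_plates = max(1, math.ceil(len(duplexes) / LIBRARY_WELLS_PER_PLATE))
    layout = build_layout(n_plates, genes=duplexes, deconvolution=True)
    lay = _merge_effects(layout, dup_effects, config)
    measurements = _simulate_wells(lay, config, rng_noise, rng_plate, attenuation)
    standards = simulate_standard_plate(config, rng_noise, attenuation,
                                        batch="deconvolution")
    noiseless = _simulate_wells(lay, config, None, None, attenuation)
    noiseless_std = simulate_standard_plate(config, None, attenuation,
                                            batch="deconvolution")
    truth = SyntheticTruth(seed=seed, config=config, effects=dup_effects,
                           labels=None, noiseless_measurements=noiseless,
                           noiseless_standards=noiseless_std)
    return SimulatedScreen(measurements=measurements, standards=standards,
                           layout=layout, truth=truth)


def simulate_expression_profile(genes: pd.DataFrame, seed: int = 0,
                                frac_not_expressed: float = 0.12,
                                ) -> tuple[plate_model.ExpressionProfile, np.ndarray]:
    """Bimodal expression profile: expressed genes high, a silent fraction low."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(genes)
    silent = rng.random(n) < frac_not_expressed
    values = np.where(silent,
                      rng.normal(8.0, 2.0, size=n),
                      rng.normal(100.0, 25.0, size=n))
    profile = plate_model.ExpressionProfile(
        pd.Series(values, index=genes["entrez_id"].to_numpy()))
    return profile, silent
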