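"""Forward-simulator properties: determinism, identities, planted effects."""

import numpy as np
import pandas as pd
import pytest

from glycoscreen import (SimulationConfig, analyze_primary,
                         simulate_deconvolution, simulate_screen,
                         simulate_standard_plate)
from glycoscreen.synthetic_screen import (apply_death_artifact,
                                          draw_gene_effects, make_gene_table)


def neutral_config(n=60, **kw):
    base = dict(n_genes=n, effect_sd_viability=0, effect_sd_lactate=0,
                drug_interaction_sd_viability=0, drug_interaction_sd_lactate=0,
                frac_viability_hit=0, frac_glycolysis_hit=0,
                frac_viability_enhancer=0, frac_glycolysis_enhancer=0)
    base.update(kw)
    return SimulationConfig(**base).zero_noise()


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_genes=80)
        a = simulate_screen(cfg, seed=4, label_truth=False)
        b = simulate_screen(cfg, seed=4, label_truth=False)
        assert a.measurements.to_csv() == b.measurements.to_csv()
        assert a.standards.to_csv() == b.standards.to_csv()

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_genes=80)
        a = simulate_screen(cfg, seed=4, label_truth=False)
        b = simulate_screen(cfg, seed=5, label_truth=False)
        assert not a.measurements["cell_count"].equals(b.measurements["cell_count"])


class TestNeutralIdentity:
    def test_all_fold_changes_exactly_one(self):
        sim = simulate_screen(neutral_config(), seed=0, label_truth=False)
        res = analyze_primary(sim.measurements, sim.standards, qc_gate=False)
        m = res.metrics
        fc_cols = [c for c in m.columns if c.endswith("_control")
                   and c.startswith(("t48_fc", "deltat_fc", "lactate_fc"))]
        for col in fc_cols + ["t48_fc_drug", "deltat_fc_drug", "lactate_fc_drug"]:
            assert np.allclose(m[col], 1.0), col
        # an all-equal population has zero MAD: scores degenerate, no hits
        assert m["z_deltat_control"].isna().all()
        assert not m["viability_hit"].any()


class TestPlantedEffects:
    def test_pdk1_like_gene_recovered_exactly(self):
        cfg = neutral_config()
        genes = make_gene_table(cfg.n_genes)
        effects = draw_gene_effects(genes, cfg, np.random.default_rng(0))
        effects.loc[0, ["m_l_control", "m_l_drug"]] = 0.4
        sim = simulate_screen(cfg, seed=0, effects=effects, label_truth=False)
        res = analyze_primary(sim.measurements, sim.standards, qc_gate=False)
        row = res.metrics.set_index("catalog_id").loc[effects.loc[0, "catalog_id"]]
        assert row["lactate_fc_control"] == pytest.approx(0.4, abs=1e-9)

    def test_drug_arm_ic25_count_ratio(self):
        sim = simulate_screen(neutral_config(), seed=0, label_truth=False)
        m = sim.measurements
        lib = m[m["role"] == "library"]
        t48 = lib.groupby("arm")["cell_count"].mean()
        assert t48["drug"] / t48["control"] == pytest.approx(0.75, abs=1e-9)

    def test_planted_multipliers_within_ranges(self):
        cfg = SimulationConfig(n_genes=2000)
        effects = draw_gene_effects(make_gene_table(2000), cfg,
                                    np.random.default_rng(1))
        kills = effects[effects["planted_class"] == "viability_hit"]
        lo, hi = cfg.kill_multiplier_range
        assert ((kills["m_v_control"] >= lo) & (kills["m_v_control"] <= hi)).all()
        glyc = effects[effects["planted_class"] == "glycolysis_hit"]
        lo, hi = cfg.glycolysis_multiplier_range
        assert ((glyc["m_l_control"] >= lo) & (glyc["m_l_control"] <= hi)).all()


class TestStandardPlate:
    def test_noiseless_ladder_on_the_line(self):
        cfg = neutral_config()
        std = simulate_standard_plate(cfg)
        expected = cfg.curve_intercept + cfg.curve_slope * std["concentration_mm"]
        assert np.allclose(std["absorbance"], expected)
        assert (std.groupby("concentration_mm").size() == 4).all()
        assert std["concentration_mm"].max() == 3.2

    def test_zero_level_reads_intercept(self):
        cfg = neutral_config()
        std = simulate_standard_plate(cfg)
        zero = std[std["concentration_mm"] == 0]["absorbance"]
        assert np.allclose(zero, cfg.curve_intercept)

    def test_attenuation_reduces_top_standard_by_36_percent(self):
        cfg = neutral_config()
        full = simulate_standard_plate(cfg, attenuation=1.0)
        att = simulate_standard_plate(cfg, attenuation=0.64)

        def net(df):
            top = df[df["concentration_mm"] == 3.2]["absorbance"].mean()
            zero = df[df["concentration_mm"] == 0]["absorbance"].mean()
            return top - zero

        assert net(att) / net(full) == pytest.approx(0.64, abs=1e-12)


class TestDeathArtifact:
    def test_plk1_wells_show_elevated_lactate(self):
        cfg = neutral_config()
        on = simulate_screen(cfg, seed=0, label_truth=False).measurements
        off_cfg = neutral_config(death_artifact=False)
        off = simulate_screen(off_cfg, seed=0, label_truth=False).measurements
        sel = lambda df: df[(df["role"] == "control_PLK1")
                            & (df["arm"] == "control")]["absorbance"].mean()
        assert sel(on) > sel(off)
        # despite near-zero counts
        plk1 = on[(on["role"] == "control_PLK1") & (on["arm"] == "control")]
        nt = on[(on["role"] == "control_NT") & (on["arm"] == "control")]
        assert plk1["cell_count"].mean() < 0.1 * nt["cell_count"].mean()

    def test_switch_off_leaves_absorbance_unchanged(self):
        conc = np.array([1.0, 2.0])
        out = apply_death_artifact(conc, [0.05, 0.05], [800, 800], enabled=False)
        assert np.array_equal(out, conc)

    def test_bonus_proportionality(self):
        conc = np.zeros(3)
        out = apply_death_artifact(conc, [0.05, 0.05, 0.9], [100, 400, 400],
                                   threshold=0.2, mm_per_cell=0.001)
        assert out[1] == pytest.approx(4 * out[0])   # proportional to cells lost
        assert out[2] == 0.0                         # healthy well untouched


class TestDeconvolutionSimulator:
    def test_gene_count_expands_to_duplexes(self):
        cfg = neutral_config(n=50)
        pool = draw_gene_effects(make_gene_table(400), cfg,
                                 np.random.default_rng(0))
        sim = simulate_deconvolution(cfg, pool, seed=0)
        lib = sim.layout[sim.layout["role"] == "library"]
        assert len(lib) == 1600
        assert set(lib["duplex"]) == {1, 2, 3, 4}

    def test_fully_effective_duplexes_reproduce_pool(self):
        cfg = neutral_config(n=10)
        pool = draw_gene_effects(make_gene_table(10), cfg,
                                 np.random.default_rng(0))
        pool.loc[:, "m_l_control"] = 0.4
        sim = simulate_deconvolution(cfg, pool, seed=0,
                                     duplex_efficacy=(1, 1, 1, 1),
                                     attenuation=1.0)
        assert np.allclose(sim.truth.effects["m_l_control"], 0.4)

    def test_half_effective_profile(self):
        cfg = neutral_config(n=10)
        pool = draw_gene_effects(make_gene_table(10), cfg,
                                 np.random.default_rng(0))
        pool.loc[:, "m_l_control"] = 0.4
        sim = simulate_deconvolution(cfg, pool, seed=0,
                                     duplex_efficacy=(1, 1, 0, 0))
        eff = sim.truth.effects
        assert (eff[eff["duplex"].isin([1, 2])]["m_l_control"] == 0.4).all()
        assert (eff[eff["duplex"].isin([3, 4])]["m_l_control"] == 1.0).all()


class TestCalibration:
    def test_replicate_correlation_band(self):
        # default noise calibration: raw count replicate r in [0.85, 0.99]
        sim = simulate_screen(SimulationConfig(n_genes=1000), seed=0,
                              label_truth=False)
        res = analyze_primary(sim.measurements, sim.standards, qc_gate=False)
        r = res.screen_qc["pearson_count_control"]
        assert 0.85 <= r <= 0.99


class TestConfigValidation:
    def test_bad_cv_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(count_cv=1.5)

    def test_bad_attenuation_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(deconv_attenuation=0.0)
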