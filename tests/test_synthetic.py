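"""Synthetic-data generator: structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from brixomics.synthetic import (ARCHETYPES, GroundTruth, OutlierSpec,
                                 SimulationConfig, archetype_effects,
                                 plant_outliers,
                                 simulate_expression_experiment,
                                 simulate_go_annotation, simulate_probe_hits,
                                 simulate_standard_addition)


class TestSimulateExpression:
    def test_dimensions_follow_the_design(self):
        cfg = SimulationConfig(n_genes=1000, seed=0)
        exp, truth = simulate_expression_experiment(cfg)
        assert exp.values.shape == (1000, 4 * 2 * 6)
        assert len(exp.conditions) == 8
        assert truth.effects.shape == (1000, 3)

    def test_null_config_gives_flat_baselines(self):
        cfg = SimulationConfig(n_genes=50, noise_sd=0.0, baseline_sd=0.0,
                               effect_model={"flat": (1.0, 0.0)}, seed=1)
        exp, _ = simulate_expression_experiment(cfg)
        assert np.allclose(exp.values.to_numpy(), 8.0)

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(n_genes=200, seed=42)
        a, _ = simulate_expression_experiment(cfg)
        b, _ = simulate_expression_experiment(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_values_clipped_to_log2_range(self):
        cfg = SimulationConfig(n_genes=500, baseline_mean=15.0,
                               baseline_sd=3.0, seed=2)
        exp, _ = simulate_expression_experiment(cfg)
        v = exp.values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 16.0

    @pytest.mark.parametrize("archetype,expected", [
        ("flat", {"brix": False, "tissue": False, "interaction": False}),
        ("monotone_decrease", {"brix": True, "tissue": False,
                               "interaction": False}),
        ("tissue_offset", {"brix": False, "tissue": True,
                           "interaction": False}),
        ("skin_peak", {"brix": True, "tissue": True, "interaction": True}),
        ("valley", {"brix": True, "tissue": True, "interaction": True}),
    ])
    def test_archetype_effect_indicators(self, archetype, expected):
        got = archetype_effects(archetype, 2.0, (22.6, 23.2, 25.0, 36.7),
                                ("skin", "pulp"))
        assert got == expected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(brix_levels=(25.0, 22.6))
        with pytest.raises(ValueError):
            SimulationConfig(effect_model={})
        with pytest.raises(ValueError):
            SimulationConfig(effect_model={"no_such_shape": (1.0, 1.0)})


class TestPlantOutliers:
    def test_zero_fraction_leaves_matrix_unchanged(self, small_experiment):
        exp, _ = small_experiment
        spec = OutlierSpec(frac_single=0.0, frac_double=0.0)
        out, truth = plant_outliers(exp, spec, seed=0)
        pd.testing.assert_frame_equal(out.values, exp.values)
        assert truth.outlier_positions == []

    def test_planted_positions_exist_and_are_displaced(self, small_experiment):
        exp, _ = small_experiment
        spec = OutlierSpec(frac_single=0.01, frac_double=0.005,
                           displacement_sd=3.0)
        out, truth = plant_outliers(exp, spec, seed=0)
        assert truth.outlier_positions
        for gene, brix, tissue, rep in truth.outlier_positions:
            sid = exp.design[(exp.design["brix"] == brix)
                             & (exp.design["tissue"] == tissue)
                             & (exp.design["replicate"] == rep)].index[0]
            assert out.values.loc[gene, sid] != exp.values.loc[gene, sid]

    def test_displaced_value_is_usually_flaggable_at_three_sd(
            self, small_experiment):
        # a 3-SD displacement lands beyond the 1.35-SD scrutiny rule of the
        # displaced set in the typical case (the post-displacement SD grows
        # by ~sqrt(1 + 9/6), leaving the outlier at ~1.6 new-SD); individual
        # values already offset toward the mean can fall short
        exp, _ = small_experiment
        spec = OutlierSpec(frac_single=0.01, frac_double=0.0,
                           displacement_sd=3.0)
        out, truth = plant_outliers(exp, spec, seed=1)
        flaggable = 0
        for gene, brix, tissue, rep in truth.outlier_positions:
            ids = out.condition_samples(brix, tissue)
            vals = out.values.loc[gene, ids].to_numpy(dtype=float)
            reps = out.design.loc[ids, "replicate"].to_numpy()
            v = vals[reps == rep][0]
            flaggable += abs(v - vals.mean()) > 1.35 * vals.std(ddof=1)
        assert flaggable / len(truth.outlier_positions) >= 0.7

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            OutlierSpec(frac_single=1.2)
        with pytest.raises(ValueError):
            OutlierSpec(displacement_sd=0.0)


class TestSimulateGoAnnotation:
    def test_planted_term_is_overdrawn_in_the_set(self):
        table, truth = simulate_go_annotation(
            n_genes=2000, n_terms=20,
            planted_terms={"GO:0000001": (60, 5.0)}, seed=0,
            significant_set_size=200)
        sig = set(truth.significant_set)
        members = set(table.loc[table["term"] == "GO:0000001", "gene"])
        k = len(members & sig)
        expected = 60 * 200 / 2000
        assert k >= 4 * expected
        assert truth.enriched_terms == {"GO:0000001": 5.0}

    def test_all_truth_records_index_real_genes(self):
        table, truth = simulate_go_annotation(
            n_genes=500, n_terms=10, planted_terms={}, seed=1,
            significant_set_size=50)
        genes = {f"g{i:05d}" for i in range(500)}
        assert set(table["gene"]) <= genes
        assert set(truth.significant_set) <= genes

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_go_annotation(100, 5, {"GO:9999999": (10, 2.0)}, seed=0)
        with pytest.raises(ValueError):
            simulate_go_annotation(10, 2, {"GO:0000000": (50, 2.0)}, seed=0,
                                   significant_set_size=5)
        with pytest.raises(ValueError):
            simulate_go_annotation(100, 2, {"GO:0000000": (10, 1.0)}, seed=0,
                                   significant_set_size=10)


class TestSimulateProbeHits:
    def test_perfect_probes_cover_every_gene(self):
        probes, targets, hits, truth = simulate_probe_hits(
            20, mismatch_spec=(), seed=0)
        assert len(probes) == 20 * 4
        perfect = hits[hits["pident"] == 100.0]
        assert set(perfect["subject"]) == set(targets)
        assert not any(truth.crosshyb_genes.values())
        # probes really are substrings of their own target
        for pid, seq in probes.items():
            gene = pid.rsplit("_p", 1)[0]
            assert seq in targets[gene]

    def test_low_identity_hits_never_flag(self):
        # 20 mismatches over 60 nt ~ 67% identity: below the retention rule
        probes, targets, hits, truth = simulate_probe_hits(
            50, mismatch_spec=((0.2, 20),), seed=1)
        off = hits[hits["pident"] < 100.0]
        assert len(off) > 0
        assert (off["pident"] < 80.0).all()
        assert not any(truth.crosshyb_genes.values())

    def test_near_identical_offtargets_are_true_crosshyb(self):
        probes, targets, hits, truth = simulate_probe_hits(
            50, mismatch_spec=((0.2, 1),), seed=2)
        assert sum(truth.crosshyb_genes.values()) > 0

    def test_mismatch_count_bounded_by_probe_length(self):
        with pytest.raises(ValueError):
            simulate_probe_hits(10, mismatch_spec=((0.5, 60),), seed=0,
                                probe_length=60)


class TestSimulateStandardAddition:
    def test_noiseless_table_is_an_exact_line(self):
        table, truth = simulate_standard_addition(25.0, ratio_noise_cv=0.0,
                                                  seed=0)
        ratios = table["ratio"].to_numpy()
        spikes = table["spike_ng_L"].to_numpy()
        np.testing.assert_allclose(ratios, 0.02 * (25.0 + spikes))
        assert truth.true_concentration == 25.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_standard_addition(-1.0)
        with pytest.raises(ValueError):
            simulate_standard_addition(10.0, spikes=(5.0,))
        with pytest.raises(ValueError):
            simulate_standard_addition(10.0, ratio_noise_cv=-0.1)
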