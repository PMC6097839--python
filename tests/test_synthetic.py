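"""Generator contracts: gene universe, spike reference, demography, counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboteq import (
    AgingScenario,
    ConfigurationError,
    make_gene_models,
    make_spikein_reference,
    null_scenario,
)
from riboteq.normalization import spike_scale_factors
from riboteq.synthetic import (
    culture_age_distribution,
    expected_profile,
    simulate_experiment,
    simulate_profiles,
)


class TestGeneModels:
    def test_default_universe_composition(self):
        models = make_gene_models(AgingScenario())
        assert len(models) == 6553
        assert sum(m.is_rpg for m in models) == 136
        gcn4 = [m for m in models if m.is_gcn4_target]
        assert len(gcn4) == 1
        assert len(gcn4[0].uorfs) >= 2

    def test_single_gene_degenerate_case(self):
        models = make_gene_models(AgingScenario(n_genes=1, n_rpg=0, n_affected=0))
        assert len(models) == 1 and not models[0].is_rpg

    def test_rpgs_sit_in_top_abundance_quartile(self, small_experiment):
        _, _, _, truth = small_experiment
        g = truth.genes
        q75 = g["base_mrna_per_cell"].quantile(0.75)
        assert (g.loc[g["is_rpg"], "base_mrna_per_cell"] >= q75 * 0.999).all()

    def test_abundance_is_heavy_tailed(self, small_experiment):
        _, _, _, truth = small_experiment
        ab = truth.genes["base_mrna_per_cell"].sort_values()
        top_decile_share = ab.iloc[-len(ab) // 10 :].sum() / ab.sum()
        assert top_decile_share > 0.35

    def test_deterministic_given_seed(self):
        sc = AgingScenario(n_genes=50, n_rpg=5, n_affected=10, n_spikes=8, seed=3)
        a = make_gene_models(sc)
        b = make_gene_models(sc)
        assert a == b

    def test_invalid_scenario_names_field(self):
        with pytest.raises(ConfigurationError, match="n_rpg"):
            make_gene_models(AgingScenario(n_genes=10, n_rpg=11))

    def test_uorf_geometry_valid(self):
        models = make_gene_models(AgingScenario(n_genes=20, n_rpg=2, n_affected=5))
        gcn4 = next(m for m in models if m.is_gcn4_target)
        prev_end = 0
        for off, length in gcn4.uorfs:
            assert off >= prev_end
            prev_end = off + length
        assert prev_end <= gcn4.leader_nt


class TestSpikeReference:
    def test_species_count_and_span(self):
        spikes = make_spikein_reference(92, seed=0)
        assert len(spikes) == 92
        amounts = [s.molecules_per_cell_equivalent for s in spikes]
        assert max(amounts) / min(amounts) >= 1e4

    def test_deterministic(self):
        assert make_spikein_reference(10, seed=4) == make_spikein_reference(10, seed=4)

    def test_rejects_zero_species(self):
        with pytest.raises(ConfigurationError):
            make_spikein_reference(0, seed=0)


class TestCultureAgeDistribution:
    def test_halving_by_division_count(self):
        p, tail = culture_age_distribution(2)
        assert p[0] == 0.50 and p[1] == 0.25 and p[2] == 0.125
        assert tail == 0.125

    @pytest.mark.parametrize("k_max", [0, 1, 5, 30])
    def test_mass_sums_to_one_exactly(self, k_max):
        p, tail = culture_age_distribution(k_max)
        assert p.sum() + tail == 1.0

    def test_k_max_zero(self):
        p, tail = culture_age_distribution(0)
        assert list(p) == [0.5] and tail == 0.5

    def test_negative_k_max_rejected(self):
        with pytest.raises(ConfigurationError):
            culture_age_distribution(-1)


class TestSimulateExperiment:
    def test_shape_and_labels(self, small_experiment, small_scenario):
        _, spikes, cm, _ = small_experiment
        n_samples = 3 * 2 * small_scenario.replicates_per_group
        assert cm.counts.shape == (small_scenario.n_genes + len(spikes), n_samples)
        assert set(cm.samples["age"]) == {"young", "mid", "old"}
        assert set(cm.samples["assay"]) == {"rna", "ribo"}

    def test_null_scenario_truth_is_flat(self):
        sc = null_scenario(n_genes=40, n_rpg=4, n_spikes=6, seed=1)
        models = make_gene_models(sc)
        spikes = make_spikein_reference(sc.n_spikes, sc.seed)
        _, truth = simulate_experiment(models, spikes, sc)
        assert (truth.genes["true_log2fc_te_old"] == 0).all()
        assert (truth.genes["mrna_mult_old"] == 1).all()

    def test_ground_truth_ceiling_realized(self, small_experiment, small_scenario):
        _, _, _, truth = small_experiment
        assert truth.genes["te_fold_old"].max() == small_scenario.max_te_fold_reduction
        assert truth.genes["affected"].sum() == small_scenario.n_affected

    def test_mid_age_is_half_log_effect(self, small_experiment):
        _, _, _, truth = small_experiment
        g = truth.genes
        np.testing.assert_allclose(
            g["true_log2fc_te_mid"], 0.5 * g["true_log2fc_te_old"]
        )

    def test_rpg_transcript_multiplier(self, small_experiment, small_scenario):
        _, _, _, truth = small_experiment
        g = truth.genes
        expected = 1 - small_scenario.rpg_transcript_decrease_frac
        assert (g.loc[g["is_rpg"], "mrna_mult_old"] == expected).all()
        assert (
            g.loc[~g["is_rpg"], "mrna_mult_old"]
            == small_scenario.global_transcript_increase_old
        ).all()

    def test_deterministic_counts(self, small_scenario):
        models = make_gene_models(small_scenario)
        spikes = make_spikein_reference(small_scenario.n_spikes, small_scenario.seed)
        cm1, _ = simulate_experiment(models, spikes, small_scenario)
        cm2, _ = simulate_experiment(models, spikes, small_scenario)
        assert cm1.counts.equals(cm2.counts)

    def test_empty_models_rejected(self, small_scenario):
        spikes = make_spikein_reference(4, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_experiment([], spikes, small_scenario)

    def test_abundance_effect_coupling_in_truth(self):
        sc = AgingScenario(n_genes=2000, n_rpg=40, n_affected=1000,
                           n_spikes=10, seed=9)
        models = make_gene_models(sc)
        spikes = make_spikein_reference(sc.n_spikes, sc.seed)
        _, truth = simulate_experiment(models, spikes, sc)
        g = truth.genes[truth.genes["affected"]]
        rho = stats.spearmanr(
            np.log(g["base_mrna_per_cell"]), g["true_log2fc_te_old"]
        ).statistic
        # reductions are negative log2fc: coupling target with negative sign
        assert rho < 0
        assert abs(abs(rho) - sc.te_effect_abundance_coupling) < 0.15

    def test_depth_confounder_recoverable_from_spikes(self, small_experiment):
        """Spike totals track the library depth factor; gene totals do not,
        because they also absorb the global per-cell transcript increase."""
        _, spikes, cm, truth = small_experiment
        factors = spike_scale_factors(cm, spikes)
        rna = cm.samples_for(assay="rna")
        est = np.log(factors[rna])
        true = np.log(truth.depth_factors[rna])
        r_spike = stats.pearsonr(est, true).statistic
        gene_tot = np.log(cm.gene_counts()[rna].sum(axis=0))
        r_naive = stats.pearsonr(gene_tot, true).statistic
        assert r_spike > 0.95
        assert r_spike > r_naive

    def test_spike_consistency_within_sample(self, small_experiment):
        """count / (length * nominal amount) is constant across spike species
        in expectation; check the high-count species to dodge Poisson noise."""
        _, spikes, cm, _ = small_experiment
        ref = {f"spike:{s.spike_id}": s.length_kb * s.molecules_per_cell_equivalent
               for s in spikes}
        col = cm.spike_counts().iloc[:, 0]
        mass = pd.Series(ref).loc[col.index]
        big = col[col > 300]
        ratios = big / mass.loc[big.index]
        assert len(big) >= 3
        assert ratios.std() / ratios.mean() < 0.2


class TestSimulateProfiles:
    def _gcn4(self):
        models = make_gene_models(AgingScenario(n_genes=20, n_rpg=2, n_affected=5))
        return next(m for m in models if m.is_gcn4_target)

    def test_uniform_mode_flat_at_depth(self):
        sc = AgingScenario()
        model = self._gcn4()
        prof = simulate_profiles(model, "young", sc, "uniform", seed=1,
                                 depth_per_codon=2000)
        cov = prof.main_counts
        assert cov.min() > 0.8 * cov.mean()
        assert cov.max() < 1.2 * cov.mean()

    def test_gcn4_like_young_uorf_dominates(self):
        sc = AgingScenario()
        prof = simulate_profiles(self._gcn4(), "young", sc, "gcn4_like", seed=2,
                                 depth_per_codon=500)
        from riboteq.positional import uorf_main_ratio

        _, _, ratio = uorf_main_ratio(prof)
        assert ratio > 1

    def test_pause_score_matches_expectation_profile(self):
        """On the noise-free expected profile the paused-mode score is exactly
        w * L / (L + w - 1) for a single codon at weight w."""
        from riboteq.positional import pause_score

        model = self._gcn4()
        prof = expected_profile(model, "young", "paused", pause_fold=10.0)
        L = model.n_codons
        assert pause_score(prof, smooth_window=1) == pytest.approx(10 * L / (L + 9))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_profiles(self._gcn4(), "young", AgingScenario(), "wiggly", seed=0)

    def test_deterministic(self):
        sc = AgingScenario()
        model = self._gcn4()
        a = simulate_profiles(model, "old", sc, "gcn4_like", seed=7)
        b = simulate_profiles(model, "old", sc, "gcn4_like", seed=7)
        np.testing.assert_array_equal(a.main_counts, b.main_counts)
        for u, v in zip(a.uorf_counts, b.uorf_counts):
            np.testing.assert_array_equal(u, v)
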