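import numpy as np
import pytest
from scipy import stats

from gapsel.phenotype import (
    TYPE_I,
    TYPE_II,
    TYPE_III,
    classify_type,
    compute_retainability,
)
from gapsel.synthetic_data import (
    CandidateFixture,
    MarkerSpec,
    SimulationConfig,
    StorageParams,
    make_marker_panel,
    simulate_candidate_tables,
    simulate_f1_population,
    simulate_storage_series,
)


class TestMarkerSpec:
    def test_non_segregating_marker_rejected(self):
        with pytest.raises(ValueError, match="segregate"):
            MarkerSpec("m", "A:A", "A:A", a=1.0, d=0.0)

    def test_contribution_mapping(self):
        spec = MarkerSpec("m", "A:G", "A:G", a=1.0, d=0.25)
        assert spec.contribution("A:A") == -1.0
        assert spec.contribution("A:G") == 0.25
        assert spec.contribution("G:G") == 1.0

    def test_backcross_span_uses_realizable_classes(self):
        spec = MarkerSpec("m", "A:G", "A:A", a=0.4, d=0.0)
        assert spec.offspring_classes() == ["A:A", "A:G"]
        assert spec.span == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "a,d,action",
        [
            (1.0, 0.0, "additive"),
            (1.0, 0.5, "partial_dominant"),
            (1.0, 1.0, "complete_dominant"),
            (1.0, 1.5, "overdominant"),
        ],
    )
    def test_intended_action_bins(self, a, d, action):
        assert MarkerSpec("m", "A:G", "A:G", a=a, d=d).intended_action == action


class TestSimulateF1Population:
    def test_same_seed_identical_outputs(self):
        config = SimulationConfig(
            n_hybrids=50, markers=make_marker_panel(), seed=11
        )
        pop1 = simulate_f1_population(config)
        pop2 = simulate_f1_population(config)
        assert pop1.genotypes.calls.equals(pop2.genotypes.calls)
        assert pop1.phenotypes.equals(pop2.phenotypes)
        assert pop1.true_genetic_values.equals(pop2.true_genetic_values)

    def test_backcross_heterozygote_frequency(self):
        spec = MarkerSpec("m", "A:G", "A:A", a=1.0, d=0.0)
        config = SimulationConfig(n_hybrids=10_000, markers=[spec], seed=7)
        pop = simulate_f1_population(config)
        freq = (pop.genotypes.calls["m"] == "A:G").mean()
        assert freq == pytest.approx(0.5, abs=0.015)  # 3-sigma binomial bound

    def test_realised_h2_in_band(self):
        config = SimulationConfig(
            n_hybrids=5000, markers=make_marker_panel(), seed=3,
            target_h2=0.8, truncate=False,
        )
        pop = simulate_f1_population(config)
        opv = pop.phenotypes.groupby("hybrid_id")["opv"].mean()
        ratio = pop.true_genetic_values.loc[opv.index].var() / opv.var()
        assert 0.77 <= ratio <= 0.83

    def test_h2_converges_with_n(self):
        def realised(n, seed):
            config = SimulationConfig(
                n_hybrids=n, markers=make_marker_panel(), seed=seed,
                target_h2=0.8, truncate=False,
            )
            pop = simulate_f1_population(config)
            opv = pop.phenotypes.groupby("hybrid_id")["opv"].mean()
            return pop.true_genetic_values.loc[opv.index].var() / opv.var()

        small = [abs(realised(500, s) - 0.8) for s in range(5)]
        large = [abs(realised(5000, s) - 0.8) for s in range(5)]
        assert np.mean(large) < np.mean(small)

    def test_segregation_chi_square_100_replicates(self):
        f2 = MarkerSpec("f2", "A:G", "A:G", a=1.0, d=0.0)
        bc = MarkerSpec("bc", "A:G", "A:A", a=1.0, d=0.0)
        n = 10_000
        for seed in range(100):
            config = SimulationConfig(n_hybrids=n, markers=[f2, bc], seed=seed)
            pop = simulate_f1_population(config)
            counts_f2 = pop.genotypes.calls["f2"].value_counts()
            obs = [counts_f2.get(c, 0) for c in ("A:A", "A:G", "G:G")]
            p_f2 = stats.chisquare(obs, f_exp=[n / 4, n / 2, n / 4]).pvalue
            counts_bc = pop.genotypes.calls["bc"].value_counts()
            obs_bc = [counts_bc.get(c, 0) for c in ("A:A", "A:G")]
            p_bc = stats.chisquare(obs_bc, f_exp=[n / 2, n / 2]).pvalue
            assert p_f2 > 0.001 and p_bc > 0.001, f"seed {seed}"

    def test_phenotypes_truncated_to_grid(self):
        config = SimulationConfig(
            n_hybrids=500, markers=make_marker_panel(), seed=5,
            population_mean=5.5, integer_mode=True,
        )
        pop = simulate_f1_population(config)
        opv = pop.phenotypes["opv"]
        assert opv.between(0, 6).all()
        assert (opv == opv.round()).all()

    def test_multi_year_records(self):
        config = SimulationConfig(
            n_hybrids=20, markers=make_marker_panel(), seed=2, n_years=2
        )
        pop = simulate_f1_population(config)
        assert sorted(pop.phenotypes["year"].unique()) == [1, 2]
        assert len(pop.phenotypes) == 40

    def test_zero_h2_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_hybrids=10, markers=make_marker_panel(), seed=1, target_h2=0.0
            )

    def test_true_class_effects_weighted_mean_zero(self):
        config = SimulationConfig(n_hybrids=300, markers=make_marker_panel(), seed=9)
        pop = simulate_f1_population(config)
        for marker in pop.genotypes.marker_ids:
            truth = pop.true_class_effects(marker)
            counts = pop.genotypes.calls[marker].value_counts()
            weighted = sum(truth[g] * counts[g] for g in truth)
            assert weighted == pytest.approx(0.0, abs=1e-9)


class TestMakeMarkerPanel:
    def test_spans_cover_requested_range(self):
        panel = make_marker_panel(28, 0.1, 3.5)
        spans = [m.span for m in panel]
        assert len(panel) == 28
        assert min(spans) == pytest.approx(0.1)
        assert max(spans) == pytest.approx(3.5)

    def test_all_action_classes_present(self):
        actions = {m.intended_action for m in make_marker_panel()}
        assert {"additive", "partial_dominant", "complete_dominant",
                "overdominant"} <= actions


class TestSimulateStorageSeries:
    def test_type_i_starts_below_threshold(self):
        series = simulate_storage_series(TYPE_I, "firmness", seed=0)
        assert series.values[0] < 7.0

    def test_type_iii_default_closed_loop(self):
        series = simulate_storage_series(TYPE_III, "firmness", seed=1)
        record = compute_retainability(series)
        assert record.retainability == 6
        assert record.censored

    def test_type_ii_default_closed_loop(self):
        series = simulate_storage_series(TYPE_II, "firmness", seed=2)
        record = compute_retainability(series)
        assert record.retainability == 6
        assert series.values[0] - series.values[1] >= 1.0
        assert classify_type(record, series) == TYPE_II

    def test_unsatisfiable_parameters_rejected(self):
        bad = StorageParams(start=7.5, fast_drop=1.0, slow_rate=0.1, noise_sd=0.0)
        with pytest.raises(ValueError, match="cross"):
            simulate_storage_series(TYPE_II, "firmness", params=bad, seed=0)

    def test_type_i_above_threshold_rejected(self):
        bad = StorageParams(start=8.0, fast_drop=0.0, slow_rate=0.1, noise_sd=0.0)
        with pytest.raises(ValueError, match="type I"):
            simulate_storage_series(TYPE_I, "firmness", params=bad, seed=0)

    def test_crispness_defaults(self):
        series = simulate_storage_series(TYPE_III, "crispness", seed=3)
        record = compute_retainability(series)
        assert record.retainability == 6


class TestSimulateCandidateTables:
    def test_manifest_consistency(self):
        fixture = simulate_candidate_tables(n_genes=12, n_variants=20, seed=4)
        manifest = fixture.manifest
        all_ids = {iv.label for iv in fixture.genes}
        assert set(manifest["expected_survivors"]).isdisjoint(
            manifest["expected_removed"]
        )
        assert set(manifest["expected_survivors"]) | set(
            manifest["expected_removed"]
        ) == all_ids

    def test_zero_variants_zero_survivors(self):
        fixture = simulate_candidate_tables(n_genes=10, n_variants=0, seed=4)
        assert fixture.manifest["expected_survivors"] == []
        assert fixture.variants == []

    def test_write_round_trips(self, tmp_path):
        from gapsel import io_tables

        fixture = simulate_candidate_tables(n_genes=8, n_variants=10, seed=6)
        fixture.write(tmp_path)
        assert io_tables.read_bed(tmp_path / "qtls.bed") == fixture.qtls
        assert io_tables.read_bed(tmp_path / "genes.bed") == fixture.genes
        assert io_tables.read_minimal_vcf(tmp_path / "variants.vcf") == fixture.variants

    def test_same_seed_identical(self):
        f1 = simulate_candidate_tables(seed=8)
        f2 = simulate_candidate_tables(seed=8)
        assert f1.manifest == f2.manifest
        assert f1.variants == f2.variants
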