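import numpy as np
import pytest
from scipy import stats

from stagewise.errors import ConfigurationError
from stagewise.preprocess import log2_transform
from stagewise.select import _segment_areas, bounded_areas
from stagewise.synthetic import (
    SimConfig,
    default_breaks_by_shape,
    make_category_map,
    shape_profile,
    simulate_annotations,
    simulate_counts,
)


def deviation_areas_per_gene(series):
    """One deviation-from-mean area per gene (the antithetic pair's area)."""
    logged = log2_transform(series)
    mean = logged.values.mean(axis=2)
    dev = logged.values - mean[:, :, None]
    areas = np.stack(
        [_segment_areas(dev[:, :, r]) for r in range(series.n_replicates)], axis=1
    )
    return areas.max(axis=1)


class TestSimConfig:
    def test_bad_shape_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(shape_mix={"step": 0.5, "ramp": 0.2})

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(shape_mix={"zigzag": 1.0})

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_replicates=1)

    def test_term_size_exceeding_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=10, term_size=11)


class TestShapeProfiles:
    @pytest.mark.parametrize("shape", ["step", "ramp", "pulse", "decay"])
    def test_zero_at_baseline(self, shape):
        breaks = default_breaks_by_shape(6)[shape]
        for b in breaks:
            assert shape_profile(shape, b, 6)[0] == 0.0

    def test_step(self):
        np.testing.assert_array_equal(shape_profile("step", 2, 6), [0, 0, 1, 1, 1, 1])

    def test_ramp_reaches_plateau_at_break(self):
        p = shape_profile("ramp", 3, 6)
        assert p[3] == 1.0 and p[2] < 1.0 and p[5] == 1.0

    def test_pulse_rises_plateaus_and_falls(self):
        p = shape_profile("pulse", 1, 6)
        np.testing.assert_allclose(p, [0, 1, 1, 1, 0.5, 0])

    def test_decay_peaks_early(self):
        p = shape_profile("decay", 1, 6)
        assert p[1] == 1.0 and p[-1] == 0.0


class TestSimulateCounts:
    def test_no_de_when_frac_zero(self):
        _, truth = simulate_counts(SimConfig(n_genes=50, frac_de=0.0, seed=1))
        assert not truth.genes["is_de"].any()
        assert (truth.genes["break_stage"] == -1).all()
        assert (truth.genes["sign"] == 0).all()

    def test_deterministic(self):
        a_series, a_truth = simulate_counts(SimConfig(n_genes=100, seed=7))
        b_series, b_truth = simulate_counts(SimConfig(n_genes=100, seed=7))
        np.testing.assert_array_equal(a_series.values, b_series.values)
        assert a_truth.genes.equals(b_truth.genes)

    def test_seed_changes_output(self):
        a, _ = simulate_counts(SimConfig(n_genes=100, seed=1))
        b, _ = simulate_counts(SimConfig(n_genes=100, seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_counts_non_negative(self):
        series, _ = simulate_counts(SimConfig(n_genes=200, seed=3))
        assert np.all(series.values >= 0)

    def test_de_genes_have_planted_break_after_baseline(self):
        _, truth = simulate_counts(SimConfig(n_genes=300, frac_de=0.5, seed=4))
        de = truth.genes[truth.genes["is_de"]]
        assert (de["break_stage"] >= 1).all()
        assert set(de["sign"]) <= {-1, 1}

    def test_planted_mean_profile_matches_truth(self):
        config = SimConfig(n_genes=100, frac_de=0.3, effect_log2=2.0, seed=5)
        series, truth = simulate_counts(config)
        logged = log2_transform(series)
        means = logged.values.mean(axis=2)
        d = means - means[:, [0]]
        for i, (gene, row) in enumerate(truth.genes.iterrows()):
            if row["is_de"]:
                expected = 2.0 * row["sign"] * shape_profile(
                    row["shape"], int(row["break_stage"]), 6
                )
                np.testing.assert_allclose(d[i], expected, atol=1e-9)

    def test_baseline_differential_is_zero(self):
        series, _ = simulate_counts(SimConfig(n_genes=100, seed=6))
        logged = log2_transform(series)
        means = logged.values.mean(axis=2)
        np.testing.assert_allclose(means[:, 0] - means[:, 0], 0.0)

    def test_mean_log_deviation_area_matches_null(self):
        config = SimConfig(n_genes=10_000, frac_de=0.0, seed=8)
        series, _ = simulate_counts(config)
        logs = np.log(deviation_areas_per_gene(series))
        assert abs(logs.mean() - 1.09) <= 3 * 0.44 / np.sqrt(10_000)

    def test_deviation_areas_lognormal_ks(self):
        config = SimConfig(n_genes=10_000, frac_de=0.0, seed=9)
        series, _ = simulate_counts(config)
        areas = deviation_areas_per_gene(series)
        result = stats.kstest(np.log(areas), "norm", args=(1.09, 0.44))
        assert result.pvalue > 0.01

    def test_nonde_gene_area_statistic_follows_null(self):
        # the gene-level differential-profile area is itself log-normal
        config = SimConfig(n_genes=10_000, frac_de=0.0, seed=10)
        series, _ = simulate_counts(config)
        logged = log2_transform(series)
        means = logged.values.mean(axis=2)
        d = means - means[:, [0]]
        areas = bounded_areas(d)
        result = stats.kstest(np.log(areas), "norm", args=(1.09, 0.44))
        assert result.pvalue > 0.01


class TestSimulateAnnotations:
    def setup_fixture(self, purity=1.0, seed=11):
        config = SimConfig(
            n_genes=600, frac_de=0.5, n_terms=30, term_size=20,
            term_purity=purity, seed=seed,
        )
        series, truth = simulate_counts(config)
        annotations, hierarchy = simulate_annotations(config, truth)
        return config, truth, annotations, hierarchy

    def test_term_sizes(self):
        config, truth, annotations, _ = self.setup_fixture()
        leaves = [t for t in annotations.sets if t.startswith("T")]
        assert len(leaves) == config.n_terms
        assert all(len(annotations.sets[t]) == config.term_size for t in leaves)

    def test_full_purity_members_share_class(self):
        _, truth, annotations, _ = self.setup_fixture(purity=1.0)
        genes = truth.genes
        for term, row in truth.terms.iterrows():
            if not row["shape"] or term not in annotations.sets:
                continue
            members = annotations.sets[term]
            matching = [
                g
                for g in members
                if genes.loc[g, "shape"] == row["shape"]
                and genes.loc[g, "break_stage"] == row["break_stage"]
                and genes.loc[g, "sign"] == row["sign"]
            ]
            # with purity 1 every pure slot matches; fill-ins only appear
            # when the class pool is smaller than the term size
            assert len(matching) >= min(
                20, len(genes[(genes["shape"] == row["shape"])
                              & (genes["break_stage"] == row["break_stage"])
                              & (genes["sign"] == row["sign"])])
            )

    def test_hierarchy_is_dag_with_parent_unions(self):
        import networkx as nx

        _, _, annotations, hierarchy = self.setup_fixture()
        g = hierarchy.graph()
        assert nx.is_directed_acyclic_graph(g)
        for child, parent in hierarchy.edges:
            assert annotations.sets[child] <= annotations.sets[parent]

    def test_impurity_rate_binomial(self):
        config = SimConfig(
            n_genes=4000, frac_de=0.5, n_terms=100, term_size=30,
            term_purity=0.8, seed=12,
        )
        series, truth = simulate_counts(config)
        annotations, _ = simulate_annotations(config, truth)
        genes = truth.genes
        impure_counts = []
        for term, row in truth.terms.iterrows():
            if not row["shape"]:
                continue
            members = annotations.sets[term]
            impure = sum(
                1
                for g in members
                if not (
                    genes.loc[g, "shape"] == row["shape"]
                    and genes.loc[g, "break_stage"] == row["break_stage"]
                    and genes.loc[g, "sign"] == row["sign"]
                )
            )
            impure_counts.append(impure)
        mean_impure = np.mean(impure_counts)
        expected = 0.2 * config.term_size
        se = np.sqrt(config.term_size * 0.2 * 0.8 / len(impure_counts))
        # fill-ins can only push the impure count up (finite class pools),
        # never down below the planted rate by much
        assert mean_impure == pytest.approx(expected, abs=max(4 * se, 1.0))

    def test_determinism(self):
        _, _, ann_a, hier_a = self.setup_fixture(seed=13)
        _, _, ann_b, hier_b = self.setup_fixture(seed=13)
        assert ann_a.sets == ann_b.sets
        assert hier_a.edges == hier_b.edges

    def test_category_map_covers_terms(self):
        _, truth, annotations, _ = self.setup_fixture()
        cmap = make_category_map(truth)
        assert set(cmap["term_id"]) == set(truth.terms.index)
        assert (cmap["kind"] == "functional_category").all()
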