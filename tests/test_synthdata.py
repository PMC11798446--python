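import numpy as np
import pandas as pd
import pytest

from crosskey.synthdata import (
    SyntheticConfig,
    generate_expression_dataset,
    generate_literature_table,
    generate_platform_universes,
    generate_ppi_edges,
    generate_study,
    generate_survival_cohort,
)


class TestUniverses:
    def test_sizes_core_and_private_symbols(self, small_config):
        universes = generate_platform_universes(small_config)
        assert len(universes) == 3
        core = set.intersection(*universes.values())
        assert len(core) >= small_config.shared_core_size
        for p, u in universes.items():
            assert len(u) == small_config.universe_size_per_platform
            others = set().union(*(v for q, v in universes.items() if q != p))
            assert u - others, f"platform {p} has no private symbols"

    def test_core_equal_to_size_gives_identical_sets(self):
        cfg = SyntheticConfig(universe_size_per_platform=40, shared_core_size=40)
        universes = generate_platform_universes(cfg)
        sets = list(universes.values())
        assert all(s == sets[0] for s in sets)

    def test_core_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="shared core"):
            SyntheticConfig(universe_size_per_platform=30, shared_core_size=40)

    def test_planted_genes_in_every_universe(self, small_config):
        universes = generate_platform_universes(small_config)
        for u in universes.values():
            assert set(small_config.planted_de_genes) <= u


class TestExpression:
    def test_planted_effect_appears_in_group_mean_difference(self, small_config):
        values, groups, annotation = generate_expression_dataset(small_config, "P1", 1)
        probes = annotation.index[annotation == "PLNT01"]
        case_cols = groups.index[groups == "case"]
        ctrl_cols = groups.index[groups == "control"]
        diff = values.loc[probes, case_cols].mean(axis=1) - values.loc[
            probes, ctrl_cols
        ].mean(axis=1)
        # mean-difference SE is noise_sd * sqrt(2/n); 0.4 is > 3 SEs at n=20
        assert np.allclose(diff, 3.0, atol=0.4)

    def test_null_genes_center_on_zero(self, small_config):
        values, groups, annotation = generate_expression_dataset(small_config, "P1", 1)
        null_probes = annotation.index[
            (annotation != "") & ~annotation.isin(small_config.planted_de_genes)
        ]
        case_cols = groups.index[groups == "case"]
        ctrl_cols = groups.index[groups == "control"]
        diffs = (
            values.loc[null_probes, case_cols].mean(axis=1)
            - values.loc[null_probes, ctrl_cols].mean(axis=1)
        )
        assert abs(diffs.mean()) < 0.1

    def test_effect_calibration_at_large_n(self):
        """Empirical log2FC of a planted gene converges to the configured
        effect (within 0.1 at 200 samples per group)."""
        cfg = SyntheticConfig(
            universe_size_per_platform=30,
            shared_core_size=20,
            samples_per_group=200,
            seed=3,
        )
        values, groups, annotation = generate_expression_dataset(cfg, "P1", 1)
        probe = annotation.index[annotation == "PLNT02"][0]
        diff = (
            values.loc[probe, groups.index[groups == "case"]].mean()
            - values.loc[probe, groups.index[groups == "control"]].mean()
        )
        assert diff == pytest.approx(3.0, abs=0.1)

    def test_unknown_platform_rejected(self, small_config):
        with pytest.raises(KeyError):
            generate_expression_dataset(small_config, "P9", 1)

    def test_blank_fraction_and_probe_multiplicity(self, small_config):
        _, _, annotation = generate_expression_dataset(small_config, "P2", 1)
        blank_frac = (annotation == "").mean()
        assert 0.0 < blank_frac <= 0.15
        per_gene = annotation[annotation != ""].value_counts()
        assert per_gene.max() <= small_config.probes_per_gene_max

    def test_determinism(self, small_config):
        a = generate_expression_dataset(small_config, "P1", 2)
        b = generate_expression_dataset(small_config, "P1", 2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[2], b[2])


class TestPPI:
    def test_planted_clique_fully_present_with_high_confidence(self, small_config):
        edges = generate_ppi_edges(small_config)
        module = sorted(small_config.planted_module_genes)
        pairs = {
            frozenset((a, b))
            for a, b, c in edges.itertuples(index=False)
            if a in module and b in module and c >= 0.9
        }
        n = len(module)
        assert len(pairs) == n * (n - 1) // 2

    def test_no_self_loops_duplicates_and_confidence_range(self, small_config):
        edges = generate_ppi_edges(small_config)
        assert (edges["gene_a"] != edges["gene_b"]).all()
        keys = edges.apply(lambda r: frozenset((r["gene_a"], r["gene_b"])), axis=1)
        assert keys.is_unique
        assert ((edges["confidence"] > 0) & (edges["confidence"] <= 1)).all()

    def test_zero_background_probability_leaves_planted_pairs_only(self):
        cfg = SyntheticConfig(
            universe_size_per_platform=40, shared_core_size=30, background_edge_prob=0.0
        )
        edges = generate_ppi_edges(cfg)
        module = set(cfg.planted_module_genes)
        assert edges["gene_a"].isin(module).all() and edges["gene_b"].isin(module).all()


class TestSurvival:
    def test_zero_censoring_means_all_events(self):
        cfg = SyntheticConfig(
            universe_size_per_platform=30, shared_core_size=20,
            censor_rate=0.0, n_survival_samples=50,
        )
        table, _ = generate_survival_cohort(cfg)
        assert (table["event"] == 1).all()
        assert (table["time"] > 0).all()

    def test_censoring_rate_approximated(self):
        cfg = SyntheticConfig(
            universe_size_per_platform=30, shared_core_size=20,
            censor_rate=0.3, n_survival_samples=800, seed=5,
        )
        table, _ = generate_survival_cohort(cfg)
        assert (1 - table["event"]).mean() == pytest.approx(0.3, abs=0.08)

    def test_hazard_depends_on_designated_gene(self):
        """Higher expression of the designated gene should shorten event
        times when the log-hazard coefficient is positive."""
        cfg = SyntheticConfig(
            universe_size_per_platform=30, shared_core_size=20,
            survival_beta=1.5, censor_rate=0.0, n_survival_samples=600, seed=9,
        )
        table, expr = generate_survival_cohort(cfg)
        x = expr.loc[cfg.survival_gene].to_numpy()
        rho = np.corrcoef(x, np.log(table["time"]))[0, 1]
        assert rho < -0.5


class TestLiterature:
    def test_every_planted_gene_covered_and_decoys_foreign(self, small_config, small_study):
        lit = generate_literature_table(small_config)
        listed = {g for row in lit["genes"] for g in row.split(";")}
        assert set(small_config.planted_de_genes) <= listed
        universe_union = set().union(*small_study.universes.values())
        decoys = {g for g in listed if g.startswith("DECOY")}
        assert decoys and not (decoys & universe_union)

    def test_ground_truth_expected_kgs_are_the_planted_module(self, small_study):
        truth = small_study.truth
        assert set(truth.expected_kgs) == set(truth.module_genes)
        assert set(truth.expected_kgs) <= set(truth.literature_genes)


def test_study_rerun_is_byte_identical(small_config, tmp_path):
    """Identical config and seed must reproduce every written artifact."""
    from crosskey.synthdata import write_study

    a_dir, b_dir = tmp_path / "a", tmp_path / "b"
    write_study(generate_study(small_config), a_dir)
    write_study(generate_study(small_config), b_dir)
    files_a = sorted(p.name for p in a_dir.iterdir())
    assert files_a == sorted(p.name for p in b_dir.iterdir())
    for name in files_a:
        assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes(), name
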