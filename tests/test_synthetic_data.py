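"""Generator module: panel structure, sampling calibration, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridzone import (
    MtdnaConfig,
    PanelConfig,
    find_fixed_sites,
    io,
    simulate_individuals,
    simulate_mtdna,
    simulate_panel,
)
from hybridzone.fieldstats import anova_from_summary, kruskal_wallis
from hybridzone.synthetic_data import (
    EGG_GROUPS,
    ConfigError,
    EnvironmentConfig,
    GroupSummary,
    PhenotypeEffects,
    simulate_eggs,
    simulate_environment,
    simulate_phenotypes,
)


class TestPanel:
    def test_default_panel_is_seven_loci(self, default_panel):
        assert len(default_panel.loci) == 7
        assert sum(s == "private" for s in default_panel.status.values()) == 5
        assert sum(s == "variable" for s in default_panel.status.values()) == 2

    def test_frequencies_sum_to_one(self, default_panel):
        for locus in default_panel.loci:
            assert abs(default_panel.freq_a[locus].sum() - 1) < 1e-9
            assert abs(default_panel.freq_b[locus].sum() - 1) < 1e-9

    def test_private_alleles_are_exclusive(self, default_panel):
        for locus in default_panel.loci:
            if default_panel.status[locus] != "private":
                continue
            fa, fb = default_panel.freq_a[locus], default_panel.freq_b[locus]
            private_a = (fa > 0) & (fb == 0)
            private_b = (fb > 0) & (fa == 0)
            assert private_a.any() and private_b.any()

    def test_variable_loci_share_alleles_with_delta(self, default_panel):
        for locus in default_panel.loci:
            if default_panel.status[locus] != "variable":
                continue
            fa, fb = default_panel.freq_a[locus], default_panel.freq_b[locus]
            assert (fa > 0).all() and (fb > 0).all()
            assert abs(fa[0] - fb[0]) == pytest.approx(0.6)

    def test_fully_diagnostic_limit(self, diagnostic_panel):
        for locus in diagnostic_panel.loci:
            fa, fb = diagnostic_panel.freq_a[locus], diagnostic_panel.freq_b[locus]
            # no allele is shared: observing any allele identifies the species
            assert not ((fa > 0) & (fb > 0)).any()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(private_allele_freq=1.2),
            dict(variable_freq_delta=-0.1),
            dict(n_loci_private=0, n_loci_variable=0),
            dict(alleles_per_locus=1),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            PanelConfig(**bad)


class TestIndividuals:
    def test_row_and_column_counts(self, default_panel):
        table = simulate_individuals(default_panel, 25, seed=1)
        assert len(table) == 50
        for locus in default_panel.loci:
            assert f"{locus}_1" in table.columns and f"{locus}_2" in table.columns

    def test_empirical_frequencies_match_panel(self, default_panel):
        # 10,000 gene copies per locus; empirical freq within 3 binomial SE
        table = simulate_individuals(default_panel, 5000, seed=7)
        sp_a = default_panel.species[0]
        sub = table[table.species == sp_a]
        locus = default_panel.loci[0]
        copies = pd.concat([sub[f"{locus}_1"], sub[f"{locus}_2"]]).astype(int)
        n = len(copies)
        for allele, expected in zip(
            default_panel.alleles[locus], default_panel.freq_a[locus]
        ):
            observed = (copies == allele).mean()
            se = np.sqrt(max(expected * (1 - expected), 1e-12) / n)
            assert abs(observed - expected) <= 3 * se + 1e-9

    def test_hwe_heterozygosity_at_half(self):
        # two alleles at 0.5/0.5 -> expected heterozygosity 2pq = 0.5
        panel = simulate_panel(
            PanelConfig(n_loci_private=0, n_loci_variable=1, variable_freq_delta=0.0)
        )
        table = simulate_individuals(panel, 10_000, seed=3)
        locus = panel.loci[0]
        het = (table[f"{locus}_1"] != table[f"{locus}_2"]).mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(het - 0.5) <= 3 * se * 2  # both species pooled

    def test_diagnostic_panel_yields_fixed_homozygotes(self, diagnostic_panel):
        table = simulate_individuals(diagnostic_panel, 10, seed=5)
        sp_a = diagnostic_panel.species[0]
        sub = table[table.species == sp_a]
        for locus in diagnostic_panel.loci:
            private_a = diagnostic_panel.alleles[locus][
                diagnostic_panel.freq_a[locus] > 0
            ]
            assert sub[f"{locus}_1"].isin(private_a).all()
            assert (sub[f"{locus}_1"] == sub[f"{locus}_2"]).all()


class TestMtdna:
    def test_default_regions_and_lengths(self):
        alignments, truth = simulate_mtdna(MtdnaConfig(seed=11))
        lengths = {r: a.get_alignment_length() for r, a in alignments.items()}
        assert lengths == {"12s": 365, "16s": 319, "dloop": 690}
        assert sum(lengths.values()) == 1374
        assert {r: len(t) for r, t in truth.items()} == {"12s": 7, "16s": 4, "dloop": 21}

    def test_zero_diagnostics_recovered_as_empty(self):
        config = MtdnaConfig(
            diagnostic_counts={"12s": 0, "16s": 0, "dloop": 0}, seed=12
        )
        alignments, _ = simulate_mtdna(config)
        for region, aln in alignments.items():
            sites = find_fixed_sites(aln, io.species_labels_from_ids(aln), region)
            assert len(sites) == 0

    def test_roundtrip_recovery_without_background(self):
        alignments, truth = simulate_mtdna(MtdnaConfig(seed=13))
        for region, aln in alignments.items():
            sites = find_fixed_sites(aln, io.species_labels_from_ids(aln), region)
            assert sites.positions == truth[region].positions
            assert sites.states_a == truth[region].states_a
            assert sites.states_b == truth[region].states_b

    def test_excessive_diagnostic_count_rejected(self):
        with pytest.raises(ConfigError):
            MtdnaConfig(region_lengths={"r": 10}, diagnostic_counts={"r": 11})

    def test_background_polymorphism_stays_off_diagnostic_sites(self):
        config = MtdnaConfig(background_polymorphism_rate=0.02, seed=14)
        alignments, truth = simulate_mtdna(config)
        for region, aln in alignments.items():
            labels = io.species_labels_from_ids(aln)
            mat = np.array([list(str(rec.seq)) for rec in aln])
            rows_a = mat[[labels[r.id] == "acutus" for r in aln]]
            rows_b = mat[[labels[r.id] == "moreletii" for r in aln]]
            for pos, sa, sb in zip(
                truth[region].positions,
                truth[region].states_a,
                truth[region].states_b,
            ):
                assert (rows_a[:, pos] == sa).all()
                assert (rows_b[:, pos] == sb).all()


class TestPhenotypes:
    def test_subcaudal_state_separates_purebreds(self):
        table = simulate_phenotypes(["PURE_A"] * 10 + ["PURE_B"] * 10, seed=1)
        assert (table.loc[table.group == "A", "subcaudal_state"] == "absent").all()
        assert (table.loc[table.group == "B", "subcaudal_state"] == "present").all()

    def test_degenerate_single_individual_groups(self):
        labels = ["PURE_A", "PURE_B", "F1", "F2", "BC_A", "BC_B"]
        table = simulate_phenotypes(labels, seed=2)
        assert len(table) == 6

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(["NOT_A_CLASS"], seed=3)

    def test_null_effects_give_uniform_p_values(self):
        # under zero effect sizes KW p-values should be ~ uniform
        effects = PhenotypeEffects.null()
        labels = ["PURE_A"] * 15 + ["PURE_B"] * 15 + ["F1"] * 15
        p_values = []
        for rep in range(200):
            table = simulate_phenotypes(labels, effects, seed=1000 + rep)
            _, p = kruskal_wallis(table["head_wl_ratio"], table["group"])
            p_values.append(p)
        p_values = np.asarray(p_values)
        assert 0.35 < p_values.mean() < 0.65
        assert (p_values <= 0.05).mean() < 0.125


class TestEnvironment:
    def test_salinity_supports_are_disjoint(self):
        labels = ["PURE_A"] * 20 + ["PURE_B"] * 20 + ["F1"] * 20
        table = simulate_environment(labels, seed=4)
        sal_a = table.loc[table.group == "A", "salinity"]
        sal_other = table.loc[table.group != "A", "salinity"]
        assert sal_a.min() > sal_other.max()

    def test_empty_labels_give_empty_table(self):
        table = simulate_environment([], seed=5)
        assert len(table) == 0

    def test_salinity_significant_null_climates_not_after_fdr(self):
        from hybridzone.fieldstats import kruskal_wallis_table

        labels = ["PURE_A"] * 30 + ["PURE_B"] * 30 + ["F1"] * 30
        table = simulate_environment(labels, EnvironmentConfig(), seed=6)
        results = kruskal_wallis_table(
            table, ["salinity", "clim1", "clim2", "clim3", "clim4"]
        )
        by_var = {r.variable: r for r in results}
        assert by_var["salinity"].p_adjusted < 0.05
        for var in ("clim1", "clim2", "clim3", "clim4"):
            assert by_var[var].p_adjusted > 0.05


class TestEggs:
    def test_hybrid_group_mean_within_three_se(self):
        table = simulate_eggs(EGG_GROUPS, seed=8)
        hybrid = table.loc[table.group == "hybrid", "mass"]
        assert len(hybrid) == 308
        se = 20.3 / np.sqrt(308)
        assert abs(hybrid.mean() - 105.1) <= 3 * se

    def test_zero_sd_gives_constant_masses(self):
        table = simulate_eggs([GroupSummary("g", 5, 50.0, 0.0)], seed=9)
        assert (table["mass"] == 50.0).all()

    def test_summary_anova_matches_raw_anova_on_generated_data(self):
        table = simulate_eggs(EGG_GROUPS, seed=10)
        summaries = [
            GroupSummary(g, len(sub), sub["mass"].mean(), sub["mass"].std(ddof=1))
            for g, sub in table.groupby("group")
        ]
        result = anova_from_summary(summaries)
        raw = stats.f_oneway(
            *[sub["mass"].to_numpy() for _, sub in table.groupby("group")]
        )
        assert result.f == pytest.approx(raw.statistic, rel=1e-9)
        assert result.p == pytest.approx(raw.pvalue, rel=1e-9)


class TestDeterminism:
    def test_identical_seeds_reproduce_identical_tables(self, default_panel):
        t1 = simulate_individuals(default_panel, 10, seed=42)
        t2 = simulate_individuals(default_panel, 10, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv() == t2.to_csv()

    def test_different_seeds_differ(self, default_panel):
        t1 = simulate_individuals(default_panel, 10, seed=42)
        t2 = simulate_individuals(default_panel, 10, seed=43)
        assert not t1.equals(t2)

    def test_mtdna_seed_reproducibility(self):
        a1, _ = simulate_mtdna(MtdnaConfig(seed=21))
        a2, _ = simulate_mtdna(MtdnaConfig(seed=21))
        for region in a1:
            assert [str(r.seq) for r in a1[region]] == [str(r.seq) for r in a2[region]]
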