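import numpy as np
import pandas as pd
import pytest

from wetviro import abundance as ab
from wetviro import hosts
from wetviro.qsip import ape_from_densities
from wetviro.synth import (
    ConfigError,
    ScenarioConfig,
    SyntheticDataset,
    generate_community,
    generate_dataset,
    generate_mortality_inputs,
    generate_sip_profiles,
    resolve_response_mix,
)


class TestConfigValidation:
    def test_bad_mix_sum(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(response_mix={"early": 0.5, "late": 0.6,
                                         "ubiquitous": 0, "zero_and_168": 0,
                                         "other": 0})

    def test_non_increasing_times(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(time_points_h=(0, 24, 24, 48))

    def test_bad_fraction(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(frac_integrase=1.5)

    def test_bad_true_ape(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(true_ape={"votu_00000": 1.2})


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        a = generate_dataset(ScenarioConfig(n_votus=30, n_mags=6, seed=9))
        b = generate_dataset(ScenarioConfig(n_votus=30, n_mags=6, seed=9))
        pd.testing.assert_frame_equal(a.votu_catalog, b.votu_catalog)
        pd.testing.assert_frame_equal(a.virome_records, b.virome_records)
        pd.testing.assert_frame_equal(a.fraction_records, b.fraction_records)
        pd.testing.assert_frame_equal(a.fraction_abundance, b.fraction_abundance)
        assert a.truth["true_ape"] == b.truth["true_ape"]

    def test_different_seed_differs(self):
        a = generate_community(ScenarioConfig(n_votus=30, n_mags=6, seed=1))
        b = generate_community(ScenarioConfig(n_votus=30, n_mags=6, seed=2))
        assert not a.virome_records.equals(b.virome_records)


class TestEmptyCases:
    def test_zero_votus(self):
        ds = generate_community(ScenarioConfig(n_votus=0, n_mags=0))
        assert ds.votu_catalog.empty
        assert ds.virome_records.empty


class TestCommunityStructure:
    def test_every_mapping_references_catalog(self, small_dataset):
        ids = set(small_dataset.votu_catalog["id"]) | set(
            small_dataset.mag_catalog["id"]
        )
        for frame in (
            small_dataset.virome_records,
            small_dataset.metagenome_records,
            small_dataset.sip_records,
        ):
            assert set(frame["genome_id"]) <= ids

    def test_truth_ledger_covers_all_votus(self, small_dataset):
        truth = small_dataset.truth
        assert set(truth["archetype"].index) == set(small_dataset.votu_catalog["id"])
        assert set(truth["membership"]) == set(small_dataset.votu_catalog["id"])

    def test_plot_pools_overlap_partially(self, small_dataset):
        membership = small_dataset.truth["membership"]
        n_plots = [len(p) for p in membership.values()]
        assert min(n_plots) >= 1
        assert any(n < 3 for n in n_plots)
        assert any(n == 3 for n in n_plots)

    def test_relative_abundance_sums_below_one(self, small_dataset):
        m = ab.relative_abundance(small_dataset.virome_records)
        assert (m.sum(axis=0) <= 1.0 + 1e-9).all()

    def test_configured_decline_reflected_in_schedules(self):
        cfg = ScenarioConfig(n_votus=200, n_mags=0, richness_decline_frac=0.5, seed=4)
        ds = generate_community(cfg)
        sched = ds.truth["schedule"]
        per_plot = {}
        for (gid, plot), times in sched.items():
            d = per_plot.setdefault(plot, {0: 0, 168: 0})
            d[0] += 0 in times
            d[168] += 168 in times
        for plot, d in per_plot.items():
            assert 1 - d[168] / d[0] == pytest.approx(0.5, abs=0.1)


class TestResolveResponseMix:
    def test_default_mix_hits_half_decline(self):
        mix = resolve_response_mix(
            {"early": 0.35, "late": 0.15, "ubiquitous": 0.1,
             "zero_and_168": 0.1, "other": 0.3},
            0.5,
        )
        r0 = mix["early"] + mix["ubiquitous"] + mix["zero_and_168"]
        r168 = mix["late"] + mix["ubiquitous"] + mix["zero_and_168"]
        assert 1 - r168 / r0 == pytest.approx(0.5)
        assert sum(mix.values()) == pytest.approx(1.0)


class TestSipProfiles:
    def test_zero_ape_centers_equal(self):
        cfg = ScenarioConfig(
            n_votus=2, n_mags=0, n_sip_votus=2, n_sip_mags=0,
            true_ape={"votu_00000": 0.0, "votu_00001": 0.0},
            abundance_cv=0.0, density_sd=0.0, sip_weight_cv=0.0, seed=2,
        )
        ds = generate_dataset(cfg)
        from wetviro.qsip import tube_densities

        tubes = tube_densities(ds.fraction_abundance, ds.fraction_records)
        pivot = tubes.pivot_table(
            index=["genome_id", "plot", "time_h"],
            columns="treatment",
            values="w_density",
        )
        assert np.allclose(pivot["16O"], pivot["18O"])

    def test_planted_shift_encodes_ape(self):
        cfg = ScenarioConfig(
            n_votus=1, n_mags=0, n_sip_votus=1, n_sip_mags=0,
            true_ape={"votu_00000": 0.2994},
            abundance_cv=0.0, density_sd=0.0, sip_weight_cv=0.0, seed=2,
        )
        ds = generate_dataset(cfg)
        from wetviro.qsip import tube_densities

        tubes = tube_densities(ds.fraction_abundance, ds.fraction_records)
        one = tubes[(tubes["plot"] == "plot1") & (tubes["time_h"] == 24)]
        w16 = one[one["treatment"] == "16O"]["w_density"].iloc[0]
        w18 = one[one["treatment"] == "18O"]["w_density"].iloc[0]
        assert ape_from_densities(w16, w18) == pytest.approx(0.2994, abs=1e-9)

    def test_positive_dna_masses(self, small_dataset):
        assert (small_dataset.fraction_records["dna_ng"] > 0).all()


class TestMortalityInputs:
    def test_viral_dna_is_yield_times_fraction(self, small_dataset):
        inp = generate_mortality_inputs(small_dataset)
        merged = small_dataset.dna_yields.merge(
            small_dataset.viral_read_fraction, on=["plot", "time_h"]
        )
        expected = (
            (merged["yield_ng_per_g"] * merged["viral_read_fraction"])
            .groupby(merged["time_h"])
            .mean()
            .sort_index()
        )
        assert np.allclose(inp.viral_dna_ng_per_g, expected.to_numpy())

    def test_all_non_negative(self, small_dataset):
        inp = generate_mortality_inputs(small_dataset)
        assert min(inp.viral_dna_ng_per_g) >= 0
        assert min(inp.rrna_loss_rate) >= 0

    def test_cumulative_contribution_monotone(self, small_dataset):
        from wetviro.mortality import contribution_table

        table = contribution_table(generate_mortality_inputs(small_dataset))
        for _, grp in table.groupby("burst_size"):
            cumul = grp.sort_values("time_h")["cumulative_pct"].dropna()
            assert (np.diff(cumul) >= -1e-9).all()


class TestEvidenceTables:
    def test_planted_links_pass_filter(self, small_dataset):
        accepted = hosts.filter_spacer_hits(small_dataset.spacer_hits)
        linked = {h.votu_id for h in accepted}
        assert set(small_dataset.truth["hosts"]) == linked

    def test_decoys_each_violate_one_filter(self, small_dataset):
        decoys = [h for h in small_dataset.spacer_hits if h.spacer_id.startswith("decoy")]
        assert decoys
        for d in decoys:
            violations = sum(
                [d.mismatches > 1, d.gaps > 0, d.align_len != d.spacer_len]
            )
            assert violations == 1

    def test_consensus_recovers_planted_hosts(self, small_dataset):
        accepted = hosts.filter_spacer_hits(small_dataset.spacer_hits)
        by_votu: dict[str, list] = {}
        for h in accepted:
            by_votu.setdefault(h.votu_id, []).append(h.source_lineage)
        for votu, preds in by_votu.items():
            got = hosts.consensus_host(preds)
            assert got.to_string() == small_dataset.truth["hosts"][votu]
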