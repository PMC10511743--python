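import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from wetviro import abundance as ab
from wetviro.abundance import MAPPING_COLUMNS


def rec(genome, plot="plot1", time=0, assay="virome", treatment="none",
        frac=-1, reads=100, covered=900, length=1000, total=1000):
    return dict(
        zip(
            MAPPING_COLUMNS,
            (genome, plot, time, assay, treatment, frac, reads, covered, length, total),
        )
    )


def frame(rows):
    return pd.DataFrame(rows, columns=MAPPING_COLUMNS)


class TestRelativeAbundance:
    def test_simple_division(self):
        m = ab.relative_abundance(frame([rec("g1", reads=10, total=1000)]))
        assert m.loc["g1"].iloc[0] == pytest.approx(0.01)

    def test_zero_reads(self):
        m = ab.relative_abundance(frame([rec("g1", reads=0)]))
        assert m.loc["g1"].iloc[0] == 0.0

    def test_column_sum_conserved(self):
        m = ab.relative_abundance(
            frame([rec("g1", reads=300), rec("g2", reads=700)])
        )
        assert m.sum(axis=0).iloc[0] == pytest.approx(1.0)

    def test_zero_total_reads_raises_naming_sample(self):
        with pytest.raises(ValueError, match="plot1"):
            ab.relative_abundance(frame([rec("g1", reads=0, total=0)]))

    def test_entries_bounded(self, small_dataset):
        m = ab.relative_abundance(small_dataset.virome_records)
        assert ((m >= 0) & (m <= 1)).all().all()
        assert (m.sum(axis=0) <= 1 + 1e-9).all()


class TestPresenceCalls:
    def test_virome_80_percent_rule(self):
        present = frame([rec("g1", covered=850, length=1000)])
        absent = frame([rec("g1", covered=790, length=1000)])
        assert ab.presence_calls(present, "virome").loc["g1"].iloc[0]
        assert not ab.presence_calls(absent, "virome").loc["g1"].iloc[0]

    def test_sip_requires_all_three_replicates(self):
        rows = [
            rec("g1", plot=p, assay="sip_fraction", treatment="18O",
                frac=0, covered=550, length=1000)
            for p in ("plot1", "plot2")
        ]
        # only 2 of 3 replicates pass
        rows.append(
            rec("g1", plot="plot3", assay="sip_fraction", treatment="18O",
                frac=0, covered=100, length=1000)
        )
        calls = ab.presence_calls(frame(rows), "sip_fraction")
        assert not calls.loc["g1"].iloc[0]

    def test_sip_triplicate_passes(self):
        rows = [
            rec("g1", plot=p, assay="sip_fraction", treatment="18O",
                frac=0, covered=550, length=1000)
            for p in ("plot1", "plot2", "plot3")
        ]
        calls = ab.presence_calls(frame(rows), "sip_fraction")
        assert calls.loc["g1"].iloc[0]

    def test_unknown_assay_raises(self):
        with pytest.raises(ValueError):
            ab.presence_calls(frame([rec("g1")]), "amplicon")

    def test_monotone_in_cutoff(self, small_dataset):
        strict = ab.presence_calls(small_dataset.virome_records, "virome", 0.9)
        relaxed = ab.presence_calls(small_dataset.virome_records, "virome", 0.5)
        assert (relaxed | ~strict).all().all()  # strict => relaxed

    def test_invariant_covered_exceeds_length_rejected(self):
        with pytest.raises(ValueError):
            ab.presence_calls(frame([rec("g1", covered=2000, length=1000)]), "virome")


class TestRichnessSeries:
    @staticmethod
    def _presence(counts):
        times = list(range(len(counts)))
        data = {}
        for t, k in zip(times, counts):
            data[("plot1", t)] = [i < k for i in range(max(counts))]
        frame = pd.DataFrame(data)
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame

    def test_counts_and_negative_slope(self):
        series = ab.richness_series(self._presence([5, 4, 3]))
        assert list(series.per_plot["value"]) == [5, 4, 3]
        assert series.trend.slope < 0

    def test_constant_presence_flat(self):
        series = ab.richness_series(self._presence([4, 4, 4]))
        assert series.trend.slope == 0
        assert series.trend.r2 == 0

    def test_single_time_point_no_regression(self):
        series = ab.richness_series(self._presence([5]))
        assert series.trend is None
        assert list(series.per_plot["value"]) == [5]

    def test_generator_decline_recovered(self, small_dataset):
        presence = ab.presence_calls(small_dataset.virome_records, "virome")
        series = ab.richness_series(presence)
        per_time = series.per_time.set_index("time_h")["mean"]
        decline = 1 - per_time.loc[168] / per_time.loc[0]
        assert decline == pytest.approx(
            small_dataset.config.richness_decline_frac, abs=0.1
        )

    def test_ols_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.random(20) * 10
        y = 2.0 * x + rng.normal(size=20)
        got = ab.linear_trend(x, y)
        # closed-form two-variable regression
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(resid @ resid / (len(x) - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), len(x) - 2)
        assert got.slope == pytest.approx(slope)
        assert got.pvalue == pytest.approx(p)
        assert got.r2 == pytest.approx(1 - resid @ resid / ((y - y.mean()) ** 2).sum())


class TestBiomassSeries:
    @staticmethod
    def _frames(yields, fracs):
        y = pd.DataFrame(
            [{"plot": "p1", "time_h": t, "yield_ng_per_g": v} for t, v in yields]
        )
        f = pd.DataFrame(
            [{"plot": "p1", "time_h": t, "viral_read_fraction": v} for t, v in fracs]
        )
        return y, f

    def test_product(self):
        y, f = self._frames([(0, 2.0), (24, 2.0)], [(0, 0.35), (24, 0.35)])
        series = ab.biomass_series(y, f)
        assert series.per_plot["value"].iloc[0] == pytest.approx(0.7)

    def test_zero_fraction(self):
        y, f = self._frames([(0, 2.0), (24, 3.0)], [(0, 0.0), (24, 0.0)])
        series = ab.biomass_series(y, f)
        assert (series.per_plot["value"] == 0).all()

    def test_default_scenario_fourfold(self, small_dataset):
        series = ab.biomass_series(
            small_dataset.dna_yields, small_dataset.viral_read_fraction
        )
        per_time = series.per_time.set_index("time_h")["mean"]
        assert per_time.loc[168] / per_time.loc[0] >= 4.0


class TestBrayCurtisPcoa:
    def test_identical_columns_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        assert ab.bray_curtis(m).loc["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert ab.bray_curtis(m).loc["a", "b"] == 1.0

    def test_matches_scipy_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = pd.DataFrame(rng.random((6, 4)) * (rng.random((6, 4)) > 0.3))
            got = ab.bray_curtis(m)
            for i in range(4):
                for j in range(4):
                    expected = 0.0 if i == j else scipy_braycurtis(
                        m.iloc[:, i], m.iloc[:, j]
                    )
                    assert got.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_sample_flagged(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        res = ab.bray_curtis_pcoa(m)
        assert res.zero_samples == ("b",)
        assert ab.bray_curtis(m).loc["a", "b"] == 1.0

    def test_axis1_variance_matches_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.random((8, 5)), columns=list("abcde"))
        res = ab.bray_curtis_pcoa(m)
        ref = skbio_pcoa(
            DistanceMatrix(ab.bray_curtis(m).to_numpy(), ids=list("abcde")),
            method="eigh",
        )
        assert res.variance_explained[0] == pytest.approx(
            ref.proportion_explained.iloc[0], abs=1e-6
        )

    def test_coordinates_reproduce_distances_for_euclidean_embeddable(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.random((10, 4)) + 0.5)
        res = ab.bray_curtis_pcoa(m)
        d = ab.bray_curtis(m).to_numpy()
        coords = res.coordinates.to_numpy()
        approx = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        # positive-eigenvalue embedding reconstructs distances up to the
        # mass on negative eigenvalues, which must be small here
        assert np.abs(approx - d).max() < 0.1

    def test_eigenvalues_reported_descending(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((5, 6)))
        res = ab.bray_curtis_pcoa(m)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestAggregateByFlag:
    def test_sums(self):
        m = pd.DataFrame({"s1": [0.01, 0.02, 0.05]}, index=["a", "b", "c"])
        flags = {"a": True, "b": True, "c": False}
        out = ab.aggregate_by_flag(m, flags)
        assert out["abundance"].loc[True, "s1"] == pytest.approx(0.03)

    def test_missing_flag_raises(self):
        m = pd.DataFrame({"s1": [0.01]}, index=["a"])
        with pytest.raises(ValueError):
            ab.aggregate_by_flag(m, {})

    def test_class_sums_conserve_totals(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((6, 3)), index=[f"g{i}" for i in range(6)])
        flags = {f"g{i}": i % 2 for i in range(6)}
        out = ab.aggregate_by_flag(m, flags)
        assert np.allclose(out["abundance"].sum(axis=0), m.sum(axis=0))
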