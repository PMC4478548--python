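import numpy as np
import pandas as pd
import pytest

from polymap import cluster_engine as ce
from polymap import synthetic_data as sd
from tests.conftest import make_model


class TestFitClusters:
    def test_constant_theta_gives_single_component_at_value(self):
        theta = np.full(50, 0.5)
        r = np.ones(50)
        model = ce.fit_clusters("m", theta, r)
        assert model.k == 1
        assert model.components[0].mean_theta == pytest.approx(0.5, abs=1e-6)

    def test_pattern3_simulation_recovers_three_means(self):
        spec = sd.default_pattern_specs()[3]
        it, _ = sd.simulate_marker_intensities(spec, 200, seed=11)
        model = ce.fit_clusters("m", it.theta.iloc[0].to_numpy(), it.R.iloc[0].to_numpy())
        assert model.k == 3
        for comp, true_mean in zip(model.components, spec.mean_theta):
            assert comp.mean_theta == pytest.approx(true_mean, abs=0.02)

    def test_two_clusters_no_heterozygote_component(self, rng):
        theta = np.concatenate([rng.normal(0.05, 0.02, 60), rng.normal(0.95, 0.02, 60)])
        theta = np.clip(theta, 0, 1)
        model = ce.fit_clusters("m", theta, np.ones(120))
        assert model.k == 2
        assert [c.genotype for c in model.components] == ["AA", "BB"]

    def test_too_few_callable_samples_flags_failed(self):
        model = ce.fit_clusters("m", np.full(5, 0.5), np.ones(5))
        assert model.k == 0

    def test_deterministic(self, rng):
        theta = rng.uniform(0, 1, 100)
        m1 = ce.fit_clusters("m", theta, np.ones(100))
        m2 = ce.fit_clusters("m", theta, np.ones(100))
        assert [c.mean_theta for c in m1.components] == [c.mean_theta for c in m2.components]


class TestCallGenotypes:
    def test_sample_at_component_mean_gets_that_genotype(self, canonical_diploid_model):
        theta = np.array([0.05, 0.50, 0.95])
        calls, cf = ce.call_genotypes(canonical_diploid_model, theta, np.ones(3))
        assert list(calls) == ["AA", "AB", "BB"]
        assert cf == 1.0

    def test_all_samples_below_r_floor_gives_zero_call_frequency(self, canonical_diploid_model):
        theta = np.array([0.05, 0.50, 0.95])
        calls, cf = ce.call_genotypes(canonical_diploid_model, theta, np.full(3, 0.1))
        assert (calls == "NC").all() and cf == 0.0

    def test_null_allele_rate_depresses_call_frequency(self):
        spec = sd.PatternSpec(
            3, (0.05, 0.50, 0.95), (0.03, 0.03, 0.03),
            ("AA", "AB", "BB"), (0.25, 0.5, 0.25), null_rate=0.3,
        )
        it, _ = sd.simulate_marker_intensities(spec, 500, seed=5)
        theta, r = it.theta.iloc[0].to_numpy(), it.R.iloc[0].to_numpy()
        model = ce.fit_clusters("m", theta, r)
        calls, cf = ce.call_genotypes(model, theta, r)
        assert cf == pytest.approx(0.70, abs=0.05)
        assert ce.call_frequency_class(cf) == "deviant"

    def test_call_frequency_non_increasing_in_posterior_threshold(self, rng):
        spec = sd.default_pattern_specs()[5]
        it, _ = sd.simulate_marker_intensities(spec, 200, seed=2)
        theta, r = it.theta.iloc[0].to_numpy(), it.R.iloc[0].to_numpy()
        model = ce.fit_clusters("m", theta, r)
        cfs = []
        for pmin in (0.5, 0.7, 0.85, 0.95, 0.99):
            _, cf = ce.call_genotypes(model, theta, r, ce.CallingConfig(posterior_min=pmin))
            cfs.append(cf)
        assert all(a >= b for a, b in zip(cfs, cfs[1:]))


class TestCallFrequencyClass:
    @pytest.mark.parametrize(
        "cf,expected",
        [
            (0.0, "failed"),
            (0.49, "failed"),
            (0.5, "deviant"),
            (0.95, "deviant"),
            (0.99, "near_complete"),
            (0.995, "near_complete"),
            (1.0, "complete"),
        ],
    )
    def test_bins(self, cf, expected):
        assert ce.call_frequency_class(cf) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ce.call_frequency_class(1.2)


class TestSeparationScore:
    def test_single_cluster_scores_one(self):
        assert ce.separation_score(make_model("m", [(0.5, 0.03, 1.0, "AB")])) == 1.0

    def test_nearly_coincident_components_score_zero(self):
        model = make_model("m", [(0.5, 0.03, 0.5, "AA"), (0.5 + 1e-12, 0.03, 0.5, "AB")])
        assert ce.separation_score(model) < 1e-9

    def test_canonical_diploid_calibration(self, canonical_diploid_model):
        # D = 0.45 / sqrt(2*(0.03^2+0.03^2)) = 7.5; S = 7.5/(7.5+1.875) = 0.80
        assert ce.separation_score(canonical_diploid_model) == pytest.approx(0.80, abs=1e-12)

    def test_mirror_invariance(self):
        comps = [(0.1, 0.02, 0.3, "AA"), (0.4, 0.05, 0.4, "AB"), (0.8, 0.03, 0.3, "BB")]
        mirrored = [(1 - m, s, w, g) for (m, s, w, g) in reversed(comps)]
        a = ce.separation_score(make_model("m", comps))
        b = ce.separation_score(make_model("m", mirrored))
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_in_gap(self):
        prev = 0.0
        for gap in (0.05, 0.1, 0.2, 0.4):
            model = make_model("m", [(0.3, 0.03, 0.5, "AA"), (0.3 + gap, 0.03, 0.5, "AB")])
            s = ce.separation_score(model)
            assert s > prev
            prev = s


class TestClassifyMarker:
    def test_single_tight_cluster_is_monomorphic(self):
        model = make_model("m", [(0.05, 0.03, 1.0, "AA")])
        calls = np.array(["AA"] * 100, dtype=object)
        cls = ce.classify_marker(model, calls, 1.0)
        assert (cls.status, cls.pattern) == ("monomorphic", 1)

    def test_all_heterozygous_inbreds_is_intergenomic(self):
        model = make_model("m", [(0.5, 0.03, 1.0, "AB")])
        calls = np.array(["AB"] * 100, dtype=object)
        cls = ce.classify_marker(model, calls, 1.0)
        assert (cls.status, cls.pattern) == ("intergenomic", 2)

    def test_shifted_constellation_with_homozygote_at_half_is_pattern4(self):
        model = make_model(
            "m",
            [(0.10, 0.03, 0.25, "AA"), (0.30, 0.03, 0.5, "AB"), (0.50, 0.03, 0.25, "BB")],
        )
        calls = np.array(["AA"] * 25 + ["AB"] * 50 + ["BB"] * 25, dtype=object)
        cls = ce.classify_marker(model, calls, 1.0)
        assert (cls.status, cls.pattern) == ("polymorphic", 4)

    def test_canonical_marker_is_pattern3(self, canonical_diploid_model):
        calls = np.array(["AA"] * 25 + ["AB"] * 50 + ["BB"] * 25, dtype=object)
        cls = ce.classify_marker(canonical_diploid_model, calls, 1.0)
        assert (cls.status, cls.pattern) == ("polymorphic", 3)
        assert cls.separation_score == pytest.approx(0.80, abs=1e-9)

    def test_low_call_frequency_is_failed(self, canonical_diploid_model):
        calls = np.array(["AA"] * 10 + ["NC"] * 90, dtype=object)
        cls = ce.classify_marker(canonical_diploid_model, calls, 0.10)
        assert (cls.status, cls.pattern) == ("failed", None)
        assert cls.call_frequency_class == "failed"

    def test_pattern6_demotion_config(self):
        spec = sd.default_pattern_specs()[6]
        it, _ = sd.simulate_marker_intensities(spec, 200, seed=3)
        theta, r = it.theta.iloc[0].to_numpy(), it.R.iloc[0].to_numpy()
        config = ce.CallingConfig(demote_pattern6=True)
        model = ce.fit_clusters("m", theta, r, config)
        calls, cf = ce.call_genotypes(model, theta, r, config)
        cls = ce.classify_marker(model, calls, cf, config=config)
        assert cls.status in ("failed", "polymorphic")
        if cls.status == "failed":
            assert cls.pattern is None


class TestClassificationSummary:
    def test_published_style_counts(self):
        # one dataset with CSIRO's counts, a second holding the remainder
        # of the array totals so the Total row reproduces the overall rate
        def rows(dataset, failed, mono, inter, poly):
            return (
                [{"dataset": dataset, "status": "failed"}] * failed
                + [{"dataset": dataset, "status": "monomorphic"}] * mono
                + [{"dataset": dataset, "status": "intergenomic"}] * inter
                + [{"dataset": dataset, "status": "polymorphic"}] * poly
            )

        csiro = rows("CSIRO", 2048, 4325, 772, 10085)
        rest = rows("rest", 7857 - 2048, 10314 - 4325, 6065 - 772, 38822 - 10085)
        table = ce.classification_summary(pd.DataFrame(csiro + rest))
        csiro_row = table[table["dataset"] == "CSIRO"].iloc[0]
        assert csiro_row["total"] == 17230
        assert csiro_row["success_rate_pct"] == 58.53
        assert csiro_row["failed_pct"] == 11.89
        total_row = table[table["dataset"] == "Total"].iloc[0]
        assert total_row["total"] == 63058
        assert total_row["success_rate_pct"] == 61.57
        assert total_row["failed_pct"] == 12.46

    def test_empty_input_no_division_error(self):
        table = ce.classification_summary(pd.DataFrame(columns=["dataset", "status"]))
        assert list(table["dataset"]) == ["Total"]
        assert table.iloc[0]["success_rate_pct"] == 0.0


def test_run_pipeline_concordance_on_pattern3_markers():
    """End-to-end: simulated pattern-3 genotypes are re-called faithfully."""
    specs = sd.default_pattern_specs()
    composition = {3: 1.0}
    it, truth = sd.simulate_marker_panel(30, 200, seed=9, composition=composition)
    records, genotypes = ce.run_pipeline(it)
    agree = (genotypes.calls.to_numpy() == truth.genotypes.to_numpy()).mean()
    assert agree >= 0.98
    assert all(cls.pattern == 3 for _, cls in records)
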