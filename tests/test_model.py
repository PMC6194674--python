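"""One-vs-rest labelling, classifier building, prediction and proxy."""

import numpy as np
import pandas as pd
import pytest

from fecalsource import (
    ASVTable,
    SourceLabelMap,
    SourceTrackingModel,
    call_band,
    make_binary_labels,
    match_and_renormalize,
)
from tests.conftest import TINY_PARAMS


class TestLabels:
    def test_composite_source_merges_members(self):
        labels = SourceLabelMap({"cow1": "Cow", "deer1": "Deer", "pig1": "Pig"})
        y = make_binary_labels(labels, "Ruminant", ["cow1", "deer1", "pig1"])
        assert y.tolist() == [1, 1, 0]

    def test_base_source_one_vs_rest(self):
        labels = SourceLabelMap({"a": "Pig", "b": "Sewage", "c": "Sewage"})
        assert make_binary_labels(labels, "Sewage", ["a", "b", "c"]).tolist() == [0, 1, 1]

    def test_degenerate_classes_rejected(self):
        labels = SourceLabelMap({"p1": "Pig", "p2": "Pig"})
        with pytest.raises(ValueError, match="negative class empty"):
            make_binary_labels(labels, "Pig", ["p1", "p2"])
        with pytest.raises(KeyError):
            labels.members("Sewage")

    def test_composites_dropped_when_members_missing(self):
        labels = SourceLabelMap({"p1": "Pig", "s1": "Sewage"})
        assert labels.all_sources == ["Pig", "Sewage"]


class TestCallBands:
    @pytest.mark.parametrize(
        "p,band",
        [
            (0.88, "positive"),
            (0.501, "positive"),
            (0.50, "marginal_high"),  # strict majority required
            (0.47, "marginal_high"),
            (0.45, "marginal_high"),
            (0.449, "marginal_low"),
            (0.40, "marginal_low"),
            (0.399, "negative"),
            (0.0, "negative"),
            (1.0, "positive"),
        ],
    )
    def test_band_thresholds(self, p, band):
        assert call_band(p) == band

    def test_bands_partition_unit_interval(self, rng):
        for p in rng.random(200):
            assert call_band(p) in {"positive", "marginal_high", "marginal_low", "negative"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            call_band(1.2)


class TestMatchAndRenormalize:
    def test_counts_renormalize_over_matched(self, tiny_fit, tiny_panel):
        clf = tiny_fit.classifiers["Cow"]
        a0, a1 = clf.selected_asvs[:2]
        counts = pd.Series({"x1": 30, "x2": 10, "x3": 7})
        seqs = {"x1": clf.asv_sequences[a0], "x2": clf.asv_sequences[a1], "x3": "G" * 60}
        vec, matched = match_and_renormalize(counts, seqs, clf)
        assert matched == 40
        assert vec[0] == pytest.approx(0.75) and vec[1] == pytest.approx(0.25)
        assert vec[2:].sum() == 0

    def test_no_match_gives_zero_vector(self, tiny_fit):
        clf = tiny_fit.classifiers["Cow"]
        vec, matched = match_and_renormalize(
            pd.Series({"x": 100}), {"x": "T" * 60}, clf
        )
        assert matched == 0 and not vec.any()

    def test_input_order_irrelevant(self, tiny_fit):
        clf = tiny_fit.classifiers["Pig"]
        seqs = {f"x{i}": clf.asv_sequences[a] for i, a in enumerate(clf.selected_asvs[:3])}
        counts = pd.Series({"x0": 5, "x1": 10, "x2": 15})
        v1, _ = match_and_renormalize(counts, seqs, clf)
        v2, _ = match_and_renormalize(counts[::-1], seqs, clf)
        np.testing.assert_array_equal(v1, v2)


class TestFittedClassifiers:
    def test_separable_panel_has_zero_oob_error(self, tiny_fit):
        assert (tiny_fit.oob_errors == 0).all()

    def test_selected_asvs_are_planted_signatures(self, tiny_fit, tiny_panel):
        """Selection never picks shared-pool or background noise ASVs, and
        the plurality of each signature set is planted for that source.

        With only three sources, another host's preferred ASV can be a
        legitimate discriminator (informative by absence), so the strict
        own-source criterion applies at full panel scale, not here.
        """
        roles = tiny_panel.annotations
        for source, clf in tiny_fit.classifiers.items():
            selected_roles = roles.loc[clf.selected_asvs, "role"]
            assert set(selected_roles) <= {"exclusive", "preferred"}, source
            planted = tiny_panel.planted_signatures(source)
            own = len(set(clf.selected_asvs) & planted) / len(clf.selected_asvs)
            assert own >= 0.5, f"{source}: only {own:.0%} of selected ASVs are its own"

    def test_pure_source_sample_called_positive(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(55)
        counts = pd.Series(tiny_panel.draw_sample("Sewage", 4000, rng), index=tiny_panel.asv_ids)
        pred = tiny_fit.predict_source(counts, tiny_panel.asv_sequences, "Sewage", "probe")
        assert pred.call_band == "positive"
        assert pred.vote_probability > 0.5

    def test_zero_vector_routes_negative(self, tiny_fit):
        clf = tiny_fit.classifiers["Cow"]
        p = clf.vote_probabilities(np.zeros((1, len(clf.selected_asvs))))[0]
        assert call_band(p) == "negative"

    def test_pure_freshwater_background_never_positive(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(56)
        counts = pd.DataFrame(
            [tiny_panel.draw_sample("Freshwater", 4000, rng)],
            index=["lake"], columns=tiny_panel.asv_ids,
        )
        report = tiny_fit.predict(ASVTable(counts, dict(tiny_panel.asv_sequences)))
        assert (report.band == "negative").all()

    def test_summary_shape(self, tiny_fit):
        summary = tiny_fit.summary()
        assert set(summary.index) == set(tiny_fit.sources)
        assert (summary.n_trees == TINY_PARAMS.n_train_replicates * TINY_PARAMS.n_train_trees).all()

    def test_ensemble_pools_all_replicates(self, tiny_fit):
        clf = tiny_fit.classifiers["Cow"]
        assert len(clf.forests) == TINY_PARAMS.n_train_replicates


class TestDeterminism:
    def test_same_seed_reproduces_fit_exactly(self, tiny_training):
        fecal, labels = tiny_training
        model = SourceTrackingModel(fecal, labels, params=TINY_PARAMS, sources=["Cow"])
        r1, r2 = model.fit(seed=3), model.fit(seed=3)
        c1, c2 = r1.classifiers["Cow"], r2.classifiers["Cow"]
        assert c1.selected_asvs == c2.selected_asvs
        pd.testing.assert_series_equal(c1.mdg, c2.mdg)
        probe = np.random.default_rng(1).dirichlet(np.ones(len(c1.selected_asvs)), size=4)
        np.testing.assert_array_equal(c1.vote_probabilities(probe), c2.vote_probabilities(probe))

    def test_different_seed_changes_votes(self, tiny_training):
        fecal, labels = tiny_training
        model = SourceTrackingModel(fecal, labels, params=TINY_PARAMS, sources=["Cow"])
        c1 = model.fit(seed=3).classifiers["Cow"]
        c2 = model.fit(seed=4).classifiers["Cow"]
        assert c1.seed != c2.seed


class TestProxy:
    def test_disjoint_classifiers_split_by_counts(self, tiny_fit, tiny_panel):
        cow = tiny_fit.classifiers["Cow"]
        sew = tiny_fit.classifiers["Sewage"]
        cow_excl = [a for a in cow.selected_asvs if a not in sew.selected_asvs][0]
        sew_excl = [a for a in sew.selected_asvs if a not in cow.selected_asvs][0]
        counts = pd.Series({"a": 60, "b": 40})
        seqs = {"a": cow.asv_sequences[cow_excl], "b": sew.asv_sequences[sew_excl]}
        sub = type(tiny_fit)(tiny_fit.model, {"Cow": cow, "Sewage": sew}, 0)
        report = sub.proportion_proxy(counts, seqs, "mix")
        assert report.proxy["Cow"] == pytest.approx(60.0)
        assert report.proxy["Sewage"] == pytest.approx(40.0)

    def test_proxies_sum_to_hundred(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(77)
        counts = pd.Series(
            tiny_panel.draw_sample("Cow", 4000, rng) + tiny_panel.draw_sample("Pig", 4000, rng),
            index=tiny_panel.asv_ids,
        )
        report = tiny_fit.proportion_proxy(counts, tiny_panel.asv_sequences, "mix")
        assert sum(report.proxy.values()) == pytest.approx(100.0, abs=1e-6)

    def test_scale_invariance(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(78)
        counts = pd.Series(tiny_panel.draw_sample("Pig", 4000, rng), index=tiny_panel.asv_ids)
        r1 = tiny_fit.proportion_proxy(counts, tiny_panel.asv_sequences)
        r2 = tiny_fit.proportion_proxy(counts * 17, tiny_panel.asv_sequences)
        for s in r1.proxy:
            assert r1.proxy[s] == pytest.approx(r2.proxy[s])

    def test_no_matching_sequences_flagged(self, tiny_fit):
        report = tiny_fit.proportion_proxy(pd.Series({"x": 9}), {"x": "T" * 60})
        assert report.no_match
        assert all(v == 0 for v in report.proxy.values())

    def test_union_denominator_mode(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(79)
        counts = pd.Series(tiny_panel.draw_sample("Cow", 4000, rng), index=tiny_panel.asv_ids)
        multi = tiny_fit.proportion_proxy(counts, tiny_panel.asv_sequences)
        union = tiny_fit.proportion_proxy(counts, tiny_panel.asv_sequences, denominator="union")
        # union denominator counts shared reads once, so percentages can top 100
        assert sum(multi.proxy.values()) == pytest.approx(100.0, abs=1e-6)
        assert union.denominator <= multi.denominator


class TestPredictReport:
    def test_cow_spike_triggers_cow_and_composite(self, tiny_panel, tiny_training):
        # Ruminant needs a second member: relabel one Pig sample set as Deer-like
        fecal, labels = tiny_training
        rng = np.random.default_rng(91)
        counts = pd.DataFrame(
            [tiny_panel.draw_sample("Cow", 4000, rng)], index=["spiked"],
            columns=tiny_panel.asv_ids,
        )
        model = SourceTrackingModel(fecal, labels, params=TINY_PARAMS)
        results = model.fit(seed=2)
        report = results.predict(ASVTable(counts, dict(tiny_panel.asv_sequences)))
        cow_row = report[(report.source == "Cow")].iloc[0]
        assert cow_row.band == "positive"

    def test_report_layout(self, tiny_fit, tiny_panel):
        rng = np.random.default_rng(92)
        counts = pd.DataFrame(
            [tiny_panel.draw_sample("Pig", 4000, rng)], index=["u1"],
            columns=tiny_panel.asv_ids,
        )
        report = tiny_fit.predict(ASVTable(counts, dict(tiny_panel.asv_sequences)))
        assert list(report.columns) == [
            "sample", "source", "vote_pct", "band", "proxy_pct", "matched_reads"
        ]
        assert len(report) == len(tiny_fit.sources)
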