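"""Unit and property tests for SILAC ratio computation and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonrnp import silac
from exonrnp.errors import NoAnchorError


def peptide_frame(rows):
    return pd.DataFrame(rows, columns=silac.PEPTIDE_COLUMNS)


class TestPeptideRatios:
    def test_direct_division(self):
        df = peptide_frame([("PEPK", "P", "x_vs_y", 2000.0, 1000.0),
                            ("PEPR", "P", "x_vs_y", 1000.0, 1000.0)])
        ratios, dropped = silac.peptide_ratios(df)
        assert list(ratios["ratio"]) == [2.0, 1.0]
        assert dropped.empty

    @pytest.mark.parametrize("light,heavy,reason", [
        (0.0, 500.0, "zero-channel"),
        (500.0, 0.0, "zero-channel"),
        (np.nan, 500.0, "missing-channel"),
        (500.0, np.nan, "missing-channel"),
    ])
    def test_unusable_peptides_logged_not_silently_dropped(self, light, heavy, reason):
        df = peptide_frame([("PEPK", "P", "x_vs_y", light, heavy)])
        ratios, dropped = silac.peptide_ratios(df)
        assert ratios.empty
        assert list(dropped["reason"]) == [reason]


class TestAggregation:
    @pytest.mark.parametrize("ratios,expected", [
        ([2.0, 2.0, 2.0], 2.0),
        ([1.0, 2.0, 4.0], 2.0),   # median of log2 {0,1,2} -> 2^1
        ([8.0], 8.0),
    ])
    def test_log2_median(self, ratios, expected):
        df = pd.DataFrame({"protein": "P", "complex_pair": "x_vs_y", "ratio": ratios})
        agg = silac.aggregate_protein_ratios(df)
        assert agg.loc[0, "raw_ratio"] == pytest.approx(expected)
        assert agg.loc[0, "n_peptides"] == len(ratios)

    def test_mean_option(self):
        df = pd.DataFrame({"protein": "P", "complex_pair": "x_vs_y",
                           "ratio": [1.0, 2.0, 4.0, 8.0]})
        agg = silac.aggregate_protein_ratios(df, method="mean")
        # mean of log2 {0,1,2,3} = 1.5
        assert agg.loc[0, "raw_ratio"] == pytest.approx(2.0 ** 1.5)


class TestAnchorNormalize:
    def _table(self, ratios):
        return pd.DataFrame({"protein": list(ratios), "complex_pair": "x_vs_y",
                             "raw_ratio": list(ratios.values()), "n_peptides": 3})

    def test_equal_anchors(self):
        out = silac.anchor_normalize(self._table({"P": 3.0, "CBP20": 1.5, "CBP80": 1.5}))
        by = out.set_index("protein")["normalized_ratio"]
        assert by["P"] == pytest.approx(2.0)
        assert by["CBP20"] == pytest.approx(1.0)

    def test_geometric_mean_of_unequal_anchors(self):
        out = silac.anchor_normalize(self._table({"P": 3.0, "CBP20": 1.0, "CBP80": 2.25}))
        assert out.set_index("protein")["normalized_ratio"]["P"] == pytest.approx(2.0)

    def test_missing_anchors_is_hard_error(self):
        with pytest.raises(NoAnchorError, match="no anchor"):
            silac.anchor_normalize(self._table({"P": 3.0, "Q": 1.5}))

    def test_single_anchor_warns_but_proceeds(self):
        with pytest.warns(UserWarning, match="one anchor"):
            out = silac.anchor_normalize(self._table({"P": 3.0, "CBP20": 1.5}))
        assert out.set_index("protein")["normalized_ratio"]["P"] == pytest.approx(2.0)

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=3, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_anchor_geometric_mean_is_one_after_normalization(self, ratios):
        names = ["CBP20", "CBP80"] + [f"P{i}" for i in range(len(ratios) - 2)]
        out = silac.anchor_normalize(self._table(dict(zip(names, ratios))))
        anchors = out.loc[out["protein"].isin(["CBP20", "CBP80"]), "normalized_ratio"]
        assert np.exp(np.mean(np.log(anchors))) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, scale):
        base = self._table({"P": 3.0, "Q": 0.4, "CBP20": 1.2, "CBP80": 0.9})
        scaled = base.assign(raw_ratio=base["raw_ratio"] * scale)
        a = silac.anchor_normalize(base)["normalized_ratio"]
        b = silac.anchor_normalize(scaled)["normalized_ratio"]
        assert np.allclose(a, b, rtol=1e-10)


class TestFoldChange:
    def _norm_table(self, values):
        return pd.DataFrame({"protein": list(values),
                             "normalized_ratio": list(values.values())})

    def test_direct_mixture_identity_and_orientation(self):
        comp = silac.fold_change(self._norm_table({"P": 4.0}), "active", "repressed")
        assert comp.numerator == "active" and comp.denominator == "repressed"
        assert comp.table.loc[0, "fold_change"] == pytest.approx(4.0)

    def test_reversal_is_reciprocal_and_swaps_classes(self):
        comp = silac.fold_change(self._norm_table({"P": 4.0, "Q": 0.25, "R": 1.0}),
                                 "active", "repressed")
        rev = comp.reversed()
        by = rev.table.set_index("protein")
        assert by.loc["P", "fold_change"] == pytest.approx(0.25)
        assert by.loc["P", "enrichment_class"] == silac.DEPLETED
        assert by.loc["Q", "enrichment_class"] == silac.ENRICHED
        assert by.loc["R", "enrichment_class"] == silac.UNCHANGED

    def test_ratio_of_ratios_examples(self):
        num = self._norm_table({"P": 4.0, "Q": 2.4, "OnlyNum": 5.0})
        den = self._norm_table({"P": 1.0, "Q": 0.8})
        comp, omitted = silac.ratio_of_ratios(num, den)
        by = comp.table.set_index("protein")["fold_change"]
        assert by["P"] == pytest.approx(4.0)
        assert by["Q"] == pytest.approx(3.0)
        assert list(omitted["protein"]) == ["OnlyNum"]

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_ratio_of_ratios_cancellation(self, x):
        t = self._norm_table({"P": x})
        comp, _ = silac.ratio_of_ratios(t, t)
        assert comp.table.loc[0, "fold_change"] == pytest.approx(1.0, abs=1e-9)


class TestEnrichmentClassification:
    @pytest.mark.parametrize("fc,expected", [
        (2.5, silac.ENRICHED),
        (1.0, silac.UNCHANGED),
        (0.4, silac.DEPLETED),
        (2.0, silac.UNCHANGED),   # strict: "greater than two-fold"
        (0.5, silac.UNCHANGED),
    ])
    def test_two_fold_rule(self, fc, expected):
        assert silac.classify_enrichment(fc) == expected

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            silac.classify_enrichment(0.0)


class TestReferenceChannelAbundance:
    def test_identity_when_light_equals_heavy(self):
        rows = [(p, s, 100.0, 100.0) for p in ("P", "CBP20", "CBP80")
                for s in ("repressed", "active", "edc")]
        df = pd.DataFrame(rows, columns=["protein", "state",
                                         "intensity_light", "intensity_heavy"])
        out = silac.reference_channel_abundance(df)
        assert np.allclose(out["abundance"], 1.0)

    def test_state_specific_loading_inflation_removed(self):
        # active state loaded 2x: anchors carry the same inflation, so
        # normalization divides it out of every protein in that state
        rows = []
        for p, true in (("P", 4.0), ("CBP20", 1.0), ("CBP80", 1.0)):
            rows.append((p, "repressed", 100.0 * true, 100.0))
            rows.append((p, "active", 100.0 * true * 2.0, 100.0))
        df = pd.DataFrame(rows, columns=["protein", "state",
                                         "intensity_light", "intensity_heavy"])
        out = silac.reference_channel_abundance(df).set_index(["protein", "state"])
        assert out.loc[("P", "active"), "abundance"] == pytest.approx(4.0)
        assert out.loc[("CBP20", "active"), "abundance"] == pytest.approx(1.0)
        comp = silac.abundance_fold_change(
            silac.reference_channel_abundance(df).reset_index(), "active", "repressed")
        assert comp.table.set_index("protein")["fold_change"]["P"] == pytest.approx(1.0)

    def test_protein_without_reference_is_insufficient_evidence(self):
        df = pd.DataFrame([("P", "active", 100.0, np.nan),
                           ("CBP20", "active", 100.0, 100.0),
                           ("CBP80", "active", 100.0, 100.0)],
                          columns=["protein", "state",
                                   "intensity_light", "intensity_heavy"])
        out = silac.reference_channel_abundance(df).set_index("protein")
        assert out.loc["P", "evidence"] == silac.INSUFFICIENT


class TestConsistencyFilter:
    def _comp(self, values):
        t = pd.DataFrame({"protein": list(values), "fold_change": list(values.values())})
        t["enrichment_class"] = "unchanged"
        return silac.ComplexComparison("x_vs_y", "x", "y", t)

    def test_intersection_and_agreement(self):
        out = silac.consistency_filter(self._comp({"P": 3.1, "Q": 0.5}),
                                       self._comp({"P": 2.4, "R": 9.0}))
        assert list(out["protein"]) == ["P"]
        assert bool(out.loc[0, "agreement"])

    def test_disagreement_flagged(self):
        out = silac.consistency_filter(self._comp({"P": 3.0}), self._comp({"P": 0.3}))
        assert not bool(out.loc[0, "agreement"])

    def test_empty_overlap_warns(self):
        with pytest.warns(UserWarning, match="no proteins shared"):
            out = silac.consistency_filter(self._comp({"P": 2.0}), self._comp({"Q": 2.0}))
        assert out.empty


def test_monotonicity_of_normalized_ratio():
    """Raising one protein's light intensities never lowers its normalized ratio."""
    def run(light_scale):
        rows = []
        for p, light in (("P", 300.0 * light_scale), ("CBP20", 100.0), ("CBP80", 100.0)):
            for i in range(3):
                rows.append((f"pep{i}K", p, "x_vs_y", light, 100.0))
        df = pd.DataFrame(rows, columns=silac.PEPTIDE_COLUMNS)
        res = silac.quantify_experiment(df)
        return res["ratios"]["x_vs_y"].set_index("protein")["normalized_ratio"]["P"]

    values = [run(s) for s in (0.5, 1.0, 2.0, 5.0)]
    assert all(b > a for a, b in zip(values, values[1:]))
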