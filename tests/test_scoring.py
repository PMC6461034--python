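"""Phosphosignals, evidence components, the integrated score, and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from inka import scoring
from inka.knowledgebases import KnowledgeBase

positive = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False)
nonneg = st.floats(min_value=0, max_value=1e9, allow_nan=False)


@pytest.mark.parametrize(
    "count, n_phospho, expected", [(3, 2, 6), (0, 5, 0), (5, 1, 5)]
)
def test_kinase_centric_phosphosignal(count, n_phospho, expected):
    assert scoring.phosphosignal_kinase_centric(count, n_phospho) == expected


@pytest.mark.parametrize(
    "count, n_phospho, n_sites, expected", [(3, 2, 3, 2.0), (4, 1, 1, 4.0), (2, 3, 2, 3.0)]
)
def test_substrate_centric_phosphosignal(count, n_phospho, n_sites, expected):
    assert scoring.phosphosignal_substrate_centric(count, n_phospho, n_sites) == expected


class TestScoreAndSkew:
    def test_geometric_mean(self):
        assert scoring.inka_score(4, 9) == 6.0

    def test_skew_anchor_values(self):
        assert scoring.skew(7, 0) == 0.0
        assert scoring.skew(0, 7) == 1.0
        assert scoring.skew(10, 10) == 0.5

    def test_skew_undefined_without_any_evidence(self):
        assert np.isnan(scoring.skew(0, 0))

    def test_negative_evidence_is_fatal(self):
        with pytest.raises(ValueError):
            scoring.inka_score(-1, 2)
        with pytest.raises(ValueError):
            scoring.skew(-1, 2)

    def test_ratio_formula_hits_the_same_anchors(self):
        for f in ("sqrt", "ratio"):
            assert scoring.skew(7, 0, formula=f) == 0.0
            assert scoring.skew(0, 7, formula=f) == 1.0
            assert scoring.skew(10, 10, formula=f) == 0.5

    @given(positive, positive)
    def test_skew_complement_symmetry(self, a, b):
        assert scoring.skew(a, b) + scoring.skew(b, a) == pytest.approx(1.0)
        assert scoring.inka_score(a, b) == pytest.approx(scoring.inka_score(b, a))

    @given(nonneg)
    def test_score_of_equal_evidence_is_the_evidence(self, c):
        assert scoring.inka_score(c, c) == pytest.approx(c)


def small_kb():
    relations = pd.DataFrame(
        {
            "kinase_symbol": ["KINA", "KINA", "KINB"],
            "substrate_symbol": ["SUBX", "SUBY", "SUBX"],
            "position": [10, 20, 10],
            "residue": ["Y", "Y", "Y"],
            "source": ["PSP", "NWK", "PSP"],
            "prediction_score": [np.nan, 3.0, np.nan],
        }
    )
    loops = pd.DataFrame(
        {"gene_symbol": ["KINA"], "peptide_sequence": ["LOOPK"]}
    )
    return KnowledgeBase(relations, loops, frozenset({"KINA", "KINB", "KINC"}))


def small_merged():
    # SUBX:Y10 carried by two peptides; KINA has its loop peptide observed
    return pd.DataFrame(
        {
            "gene_symbol": ["KINA", "SUBX", "SUBX", "SUBY", "OTHER"],
            "peptide_sequence": ["LOOPK", "PEP1K", "PEP2K", "PEP3K", "PEP4K"],
            "n_phospho": [1, 1, 1, 2, 1],
            "accession": ["A1", "A2", "A2", "A3", "A4"],
            "position": [400, 10, 10, 20, 99],
            "residue": ["Y", "Y", "Y", "Y", "Y"],
            "localization_probability": [0.9] * 5,
            "n_inferred_sites": [1, 1, 1, 2, 1],
            "s1": [5.0, 2.0, 1.0, 4.0, 7.0],
        }
    )


class TestComponents:
    def test_non_catalog_gene_absent_from_kinome_component(self):
        table = scoring.build_component("kinome", small_merged(), small_kb(), "s1")
        assert "OTHER" not in set(table.contributions["kinase_symbol"])
        assert set(table.contributions["kinase_symbol"]) == {"KINA"}

    def test_site_signal_sums_over_peptides(self):
        # SUBX:Y10 from peptides with signals 2.0 and 1.0 -> 3.0 credited to KINA
        table = scoring.build_component("psp", small_merged(), small_kb(), "s1")
        assert table.aggregated["KINA"] == pytest.approx(3.0)

    def test_shared_site_credited_fully_to_each_kinase(self):
        table = scoring.build_component("psp", small_merged(), small_kb(), "s1")
        # KINB shares SUBX:Y10 and receives the full site signal, no splitting
        assert table.aggregated["KINB"] == pytest.approx(3.0)

    def test_division_by_inferred_sites(self):
        # SUBY:Y20: count 4, 2 phospho, 2 inferred sites -> 4*2/2 = 4.0
        table = scoring.build_component("nwk", small_merged(), small_kb(), "s1")
        assert table.aggregated["KINA"] == pytest.approx(4.0)

    def test_aggregated_equals_contribution_sum(self):
        for comp in scoring.COMPONENTS:
            table = scoring.build_component(comp, small_merged(), small_kb(), "s1")
            grouped = table.contributions.groupby("kinase_symbol")["phosphosignal"].sum()
            pd.testing.assert_series_equal(
                table.aggregated, grouped.sort_index(), check_names=False
            )

    def test_unknown_component_is_fatal(self):
        with pytest.raises(ValueError):
            scoring.build_component("nope", small_merged(), small_kb(), "s1")

    def test_activation_loop_is_subset_of_kinome(self, toy_bundle):
        _, kb, merged = toy_bundle
        scores = scoring.score_sample(merged, kb, "sample1")
        assert (scores["c_activation_loop"] <= scores["c_kinome"] + 1e-12).all()


class TestScoreTable:
    def test_zero_substrate_evidence_zeroes_the_score(self):
        scores = scoring.score_sample(small_merged(), small_kb(), "s1")
        # KINA: c_kin = 5*1 (kinome) + 5*1 (loop) = 10; c_sub = 3 + 4 = 7
        assert scores.loc["KINA", "c_kin"] == pytest.approx(10.0)
        assert scores.loc["KINA", "c_sub"] == pytest.approx(7.0)
        assert scores.loc["KINA", "inka"] == pytest.approx(np.sqrt(70.0))
        # KINB has substrate evidence only -> zero integrated score
        assert scores.loc["KINB", "c_kin"] == 0.0
        assert scores.loc["KINB", "inka"] == 0.0

    def test_out_of_scope_flag(self):
        scores = scoring.score_sample(small_merged(), small_kb(), "s1")
        assert not scores.loc["KINA", "out_of_scope"]
        # KINC is in the catalog but not the relation tables; unobserved here
        assert "KINC" not in scores.index


class TestRanking:
    def _scores(self, inka_values, **cols):
        n = len(inka_values)
        base = {
            "c_kinome": [1.0] * n,
            "c_activation_loop": [0.0] * n,
            "c_psp": [1.0] * n,
            "c_nwk": [0.0] * n,
            "c_kin": [1.0] * n,
            "c_sub": [1.0] * n,
            "inka": list(inka_values),
            "skew": [0.5] * n,
            "out_of_scope": [False] * n,
            "raw_total": [5.0] * n,
            "n_nonzero_evidence": [3] * n,
        }
        base.update(cols)
        return pd.DataFrame(base, index=[f"K{i:02d}" for i in range(n)])

    def test_plot_set_uses_ten_percent_of_max(self):
        ranking = scoring.rank_inka(self._scores([100, 50, 10, 9.9]))
        assert len(ranking.plot_set) == 3

    def test_bar_graph_caps_at_twenty(self):
        ranking = scoring.rank_inka(self._scores(list(range(1, 26))))
        assert len(ranking.bar_graph) == 20
        assert ranking.main["rank"].tolist() == list(range(1, 26))

    def test_plot_fraction_zero_keeps_all_positive(self):
        ranking = scoring.rank_inka(self._scores([100, 50, 10, 9.9]), plot_fraction=0.0)
        assert len(ranking.plot_set) == 4

    def test_out_of_scope_needs_two_spectral_counts(self):
        scores = self._scores(
            [0.0, 0.0],
            c_sub=[0.0, 0.0],
            out_of_scope=[True, True],
            raw_total=[1.0, 2.0],
        )
        ranking = scoring.rank_inka(scores)
        assert list(ranking.out_of_scope.index) == ["K01"]

    def test_intensity_mode_uses_nonzero_evidence_rows(self):
        scores = self._scores(
            [0.0, 0.0],
            c_sub=[0.0, 0.0],
            out_of_scope=[True, True],
            n_nonzero_evidence=[1, 2],
        )
        ranking = scoring.rank_inka(scores, quant_mode="intensity")
        assert list(ranking.out_of_scope.index) == ["K01"]

    def test_ties_break_alphabetically(self):
        ranking = scoring.rank_inka(self._scores([5.0, 5.0, 1.0]))
        assert list(ranking.main.index[:2]) == ["K00", "K01"]

    def test_empty_table_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            ranking = scoring.rank_inka(self._scores([]))
        assert ranking.main.empty and ranking.out_of_scope.empty


@given(st.floats(min_value=0.01, max_value=100, allow_nan=False))
def test_scale_equivariance(k):
    """Multiplying all counts by k scales every score by k, fixing skew/ranks."""
    merged = small_merged()
    kb = small_kb()
    base = scoring.score_sample(merged, kb, "s1")
    scaled_input = merged.assign(s1=merged["s1"] * k)
    scaled = scoring.score_sample(scaled_input, kb, "s1")
    assert np.allclose(scaled["inka"], base["inka"] * k, rtol=1e-9)
    assert np.allclose(
        scaled["skew"].fillna(-1), base["skew"].fillna(-1), rtol=1e-9
    )
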