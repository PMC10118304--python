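import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panedit.protein import (
    InternalStopError,
    coevolution_pair_summary,
    composition_by_class,
    hydrophobic_fraction,
    survey_rank,
    translate,
)
from panedit.seqio import CdsRecord, ProteinRecord


class TestTranslate:
    @pytest.mark.parametrize(
        "rna,aa",
        [("UUUUUA", "FL"), ("UGA", "W"), ("UANUUU", "XF"), ("AUGUGAUUU", "MWF")],
    )
    def test_table4_translation(self, rna, aa):
        assert translate(CdsRecord(id="x", seq=rna)).seq == aa

    def test_terminal_stop_dropped(self):
        assert translate(CdsRecord(id="x", seq="UUUUAA")).seq == "F"

    def test_internal_stop_strict(self):
        with pytest.raises(InternalStopError):
            translate(CdsRecord(id="x", seq="UAAUUU"))

    def test_internal_stop_override(self):
        assert translate(CdsRecord(id="x", seq="UAAUUU"), allow_internal_stops=True).seq == "XF"

    def test_standard_code_differs_on_uga(self):
        with pytest.raises(InternalStopError):
            translate(CdsRecord(id="x", seq="UGAUUU"), code_table=1)

    def test_frame_offset_respected(self):
        assert translate(CdsRecord(id="x", seq="GUUUUUA", frame_offset=1)).seq == "FL"


class TestHydrophobicFraction:
    @pytest.mark.parametrize("seq,frac", [("FLSA", 0.5), ("FFFF", 1.0), ("SSSS", 0.0)])
    def test_fractions(self, seq, frac):
        assert hydrophobic_fraction(ProteinRecord(id="p", seq=seq)) == frac

    def test_x_excluded_from_denominator(self):
        assert hydrophobic_fraction(ProteinRecord(id="p", seq="FXXX")) == 1.0

    def test_all_x_errors(self):
        with pytest.raises(ValueError):
            hydrophobic_fraction(ProteinRecord(id="p", seq="XX"))


class TestSurveyRank:
    def test_dense_ranks_with_ties(self):
        prots = [
            ProteinRecord(id="a", seq="FFFFFFFFFS"),  # 0.9
            ProteinRecord(id="b", seq="FFFFFSSSSS"),  # 0.5
            ProteinRecord(id="c", seq="SSSSSFFFFF"),  # 0.5
        ]
        r = survey_rank(prots, queries=["b"])
        assert r.ranks == {"a": 1, "b": 2, "c": 2}
        assert r.query_ranks["b"] == 2

    def test_single_query_at_max_ranks_first(self):
        prots = [ProteinRecord(id="q", seq="FFFF"), ProteinRecord(id="b", seq="SSSS")]
        assert survey_rank(prots, queries=["q"]).query_ranks["q"] == 1

    def test_duplicate_ids_error(self):
        prots = [ProteinRecord(id="a", seq="FF"), ProteinRecord(id="a", seq="SS")]
        with pytest.raises(ValueError, match="duplicate"):
            survey_rank(prots)

    def test_mean_sd_match_direct_formulas(self, rng):
        prots = [
            ProteinRecord(id=f"p{i}", seq="".join(rng.choice(list("FLIVSARG"), size=60)))
            for i in range(20)
        ]
        r = survey_rank(prots)
        assert r.mean == pytest.approx(np.mean(r.fractions))
        assert r.sd == pytest.approx(np.std(r.fractions))


class TestCompositionByClass:
    def test_simple_classes(self):
        table = composition_by_class(
            ProteinRecord(id="p", seq="LLSS"),
            classification={aa: "order" if aa == "L" else "disorder"
                            for aa in "ACDEFGHIKLMNPQRSTVWY"},
        )
        assert table.class_totals == pytest.approx({"order": 0.5, "disorder": 0.5})

    def test_default_map_c_is_order_promoting(self):
        table = composition_by_class(ProteinRecord(id="p", seq="CCCC"))
        assert table.class_totals["order"] == pytest.approx(1.0)

    def test_incomplete_classification_errors(self):
        with pytest.raises(ValueError, match="cover"):
            composition_by_class(ProteinRecord(id="p", seq="LL"), classification={"L": "order"})

    def test_frequencies_sum_to_one_excluding_x(self):
        table = composition_by_class(ProteinRecord(id="p", seq="LFXXSA"))
        assert sum(table.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert table.x_fraction == pytest.approx(2 / 6)

    @given(st.permutations(list("ACDEFGHIKLMNPQRSTVWY")))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_invariant_under_shuffling(self, letters):
        seq = "".join(letters)
        a = composition_by_class(ProteinRecord(id="p", seq=seq))
        b = composition_by_class(ProteinRecord(id="p", seq=seq[::-1]))
        assert a.frequencies == b.frequencies


class TestCoevolutionSummary:
    def test_single_adjacent_hydrophobic_pair(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.9
        s = coevolution_pair_summary(m, ProteinRecord(id="p", seq="LVS"))
        assert (s.n_pairs, s.hydrophobic_pair_fraction) == (1, 1.0)

    def test_all_zero_scores(self):
        s = coevolution_pair_summary(np.zeros((4, 4)), ProteinRecord(id="p", seq="LVSA"))
        assert s.n_pairs == 0 and s.hydrophobic_pair_fraction is None

    def test_threshold_above_all(self):
        m = np.full((3, 3), 0.9)
        s = coevolution_pair_summary(m, ProteinRecord(id="p", seq="LVS"), threshold=1.1)
        assert s.n_pairs == 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            coevolution_pair_summary(np.zeros((3, 3)), ProteinRecord(id="p", seq="LVSA"))

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            coevolution_pair_summary(m, ProteinRecord(id="p", seq="LVS"))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        m = rng.random((n, n))
        m = (m + m.T) / 2
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        prot = ProteinRecord(id="p", seq=seq)
        s = coevolution_pair_summary(m, prot, threshold=0.8, max_dist=5)
        hydro = set("FLIVMWY")
        n_pairs = n_h = 0
        for i in range(n):
            for j in range(n):
                if i < j and j - i <= 5 and m[i, j] > 0.8:
                    n_pairs += 1
                    if seq[i] in hydro and seq[j] in hydro:
                        n_h += 1
        assert s.n_pairs == n_pairs
        expected_frac = n_h / n_pairs if n_pairs else None
        assert s.hydrophobic_pair_fraction == expected_frac
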