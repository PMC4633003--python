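import numpy as np
import pandas as pd
import pytest

from fvri.core import ValidationError
from fvri.engine import FvriConfig, score_frames
from fvri.lesions import (
    AgreementTable,
    agreement_table,
    assess_lesions,
    classical_index,
    classify_classical,
    composition_by_class,
    detect_lesion_spans,
    detect_lesions,
    find_references,
    select_mla_frame,
)
from fvri.normal_model import FALCAO2015_DEFAULT
from fvri.simulate import SimulationConfig, ThetaMixture, simulate_cohort


def exhaustive_spans_oracle(burdens, cutoff=40.0, min_run=3):
    """Enumerate every maximal qualifying run by checking all (s, e) pairs."""
    n = len(burdens)
    spans = []
    for s in range(n):
        for e in range(s + min_run - 1, n):
            if all(burdens[i] > cutoff for i in range(s, e + 1)):
                left_ok = s == 0 or burdens[s - 1] <= cutoff
                right_ok = e == n - 1 or burdens[e + 1] <= cutoff
                if left_ok and right_ok:
                    spans.append((s, e))
    return spans


class TestDetectLesions:
    def test_two_lesions_in_mixed_profile(self):
        burdens = [30, 45, 50, 41, 35, 42, 43, 60, 20]
        assert detect_lesion_spans(burdens) == [(1, 3), (5, 7)]

    def test_short_run_is_not_a_lesion(self):
        assert detect_lesion_spans([45, 50]) == []

    def test_uniform_high_burden_is_one_maximal_lesion(self):
        assert detect_lesion_spans([41] * 10) == [(0, 9)]

    def test_matches_exhaustive_enumeration_on_random_profiles(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(1, 30))
            burdens = rng.uniform(20, 60, n)
            assert detect_lesion_spans(burdens) == exhaustive_spans_oracle(burdens)

    def test_lesion_records_span_and_length(self, scored_artery_builder):
        artery = scored_artery_builder([30, 45, 50, 41, 35, 42, 43, 60, 20])
        lesions = detect_lesions(artery)
        assert [(l.start, l.end) for l in lesions] == [(1, 3), (5, 7)]
        assert lesions[0].length_mm == pytest.approx(0.6)  # 2 frame gaps * 0.3 mm


class TestMlaSelection:
    def test_minimum_lumen_selected(self, scored_artery_builder):
        artery = scored_artery_builder([45, 46, 47], lumens=[5.0, 4.2, 4.8])
        assert select_mla_frame(artery, (0, 2)) == 1

    def test_tie_breaks_to_most_proximal(self, scored_artery_builder):
        artery = scored_artery_builder([45, 46, 47], lumens=[4.2, 4.2, 5.0])
        assert select_mla_frame(artery, (0, 2)) == 0

    def test_matches_brute_force_minimum(self, scored_artery_builder):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            lumens = rng.uniform(3.0, 9.0, n)
            artery = scored_artery_builder([50.0] * n, lumens=lumens)
            picked = select_mla_frame(artery, (0, n - 1))
            assert lumens[picked] == min(lumens)


class TestReferences:
    def test_immediate_neighbors(self, scored_artery_builder):
        artery = scored_artery_builder([30, 45, 50, 41, 35, 42, 43, 60, 20])
        assert find_references(artery, (1, 3)) == (0, 4)

    def test_lesion_at_pullback_start_lacks_proximal(self, scored_artery_builder):
        artery = scored_artery_builder([45, 50, 41, 20])
        assert find_references(artery, (0, 2)) == (None, 3)

    def test_lesion_at_pullback_end_lacks_distal(self, scored_artery_builder):
        artery = scored_artery_builder([20, 45, 50, 41])
        assert find_references(artery, (1, 3)) == (0, None)


class TestClassicalIndex:
    @pytest.mark.parametrize(
        "mla, prox, dist, expected",
        [
            (13.0, 14.0, 14.0, 13.0 / 14.0),
            (14.0, 14.0, 14.0, 1.0),
            (14.0, 12.0, 16.0, 1.0),
        ],
    )
    def test_direct_evaluation(self, mla, prox, dist, expected):
        assert classical_index(mla, prox, dist) == pytest.approx(expected, abs=1e-12)

    def test_reference_swap_invariance(self):
        assert classical_index(13.0, 11.0, 16.0) == classical_index(13.0, 16.0, 11.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            classical_index(13.0, 0.0, 14.0)

    @pytest.mark.parametrize(
        "index, expected",
        [
            (0.88, "intermediate"),  # inclusive lower bound
            (1.00, "intermediate"),  # inclusive upper bound
            (1.0001, "positive"),
            (0.8799, "negative"),
        ],
    )
    def test_classical_categories(self, index, expected):
        assert classify_classical(index) == expected


class TestAssessLesions:
    def test_uniform_eem_gives_intermediate_classical_class(
        self, scored_artery_builder
    ):
        # EEM fixed at 12 everywhere -> classical index exactly 1
        artery = scored_artery_builder([30, 45, 50, 41, 35])
        lesions = assess_lesions(artery)
        assert len(lesions) == 1
        row = lesions.iloc[0]
        assert row["has_references"]
        assert row["classical_index"] == pytest.approx(1.0, abs=1e-12)
        assert row["classical_class"] == "intermediate"

    def test_boundary_lesion_excluded_from_classical_analysis(
        self, scored_artery_builder
    ):
        artery = scored_artery_builder([45, 50, 41, 20])
        lesions = assess_lesions(artery)
        assert len(lesions) == 1
        assert not lesions.iloc[0]["has_references"]
        assert np.isnan(lesions.iloc[0]["classical_index"])

    def test_lesion_fvri_comes_from_mla_frame(self, scored_artery_builder):
        artery = scored_artery_builder(
            [30, 45, 55, 41, 35], lumens=[8.0, 6.0, 4.0, 6.5, 8.0]
        )
        lesions = assess_lesions(artery)
        row = lesions.iloc[0]
        assert row["mla_lumen_mm2"] == 4.0
        mla_frame = artery[artery["lumen_area_mm2"] == 4.0].iloc[0]
        assert row["fvri"] == pytest.approx(mla_frame["fvri"])
        assert row["fvri_class"] == mla_frame["remodeling_class"]

    def test_mean_lesion_fvri_increases_with_theta(self):
        means = []
        for theta in (0.2, 0.7, 1.05):
            mix = ThetaMixture(weights=(1.0,), means=(theta,), sds=(1e-6,))
            cfg = SimulationConfig(
                seed=4040, n_patients=5, theta=mix, lumen_noise_cv=0.0
            )
            sim = simulate_cohort(cfg)
            scored = score_frames(sim.cohort, FALCAO2015_DEFAULT, FvriConfig())
            lesions = assess_lesions(scored)
            means.append(lesions["fvri"].mean())
        assert means[0] < means[1] < means[2]


class TestAgreementTable:
    def test_published_counts_reproduce_published_marginals(self, table3_counts):
        table = AgreementTable.from_counts(table3_counts)
        assert table.n == 618
        assert table.row_pct["complete_compensatory"] == pytest.approx(35.1, abs=0.05)
        assert table.row_pct["incomplete_compensatory"] == pytest.approx(41.3, abs=0.05)
        assert table.row_pct["negative"] == pytest.approx(22.3, abs=0.05)
        assert table.row_pct["ectatic"] == pytest.approx(1.3, abs=0.05)
        assert table.col_pct["negative"] == pytest.approx(22.0, abs=0.05)
        assert table.col_pct["intermediate"] == pytest.approx(34.6, abs=0.05)
        assert table.col_pct["positive"] == pytest.approx(43.4, abs=0.05)

    def test_published_concordance_from_rounded_cell_percentages(self, table3_counts):
        table = AgreementTable.from_counts(table3_counts)
        # the printed 38.1% concordance is the sum of the three printed
        # (1-decimal) concordant cell percentages 8.3 + 12.8 + 17.0
        printed = (
            round(table.cell_pct[0, 0], 1)
            + round(table.cell_pct[1, 1], 1)
            + round(table.cell_pct[2, 2], 1)
        )
        assert printed == pytest.approx(38.1, abs=1e-9)
        assert table.named_pairs_agreement_pct == pytest.approx(
            100.0 * (51 + 79 + 105) / 618, abs=1e-9
        )
        assert table.overall_agreement_pct == pytest.approx(
            100.0 * (51 + 79 + 105 + 6) / 618, abs=1e-9
        )

    def test_marginals_sum_to_total(self, table3_counts):
        table = AgreementTable.from_counts(table3_counts)
        assert sum(table.row_counts.values()) == table.n
        assert sum(table.col_counts.values()) == table.n

    def test_perfect_agreement_gives_full_concordance_and_kappa_one(self):
        counts = np.array([[40, 0, 0], [0, 50, 0], [0, 0, 60], [0, 0, 0]])
        table = AgreementTable.from_counts(counts)
        assert table.overall_agreement_pct == 100.0
        assert table.kappa == pytest.approx(1.0, abs=1e-12)

    def test_uniform_table_gives_zero_kappa(self):
        table = AgreementTable.from_counts(np.full((4, 3), 100))
        assert table.kappa == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            AgreementTable.from_counts(np.zeros((4, 3)))
        with pytest.raises(ValidationError):
            agreement_table(
                pd.DataFrame(
                    {"has_references": [False], "classical_class": [None],
                     "fvri_class": ["negative"], "fvri": [0.7],
                     "classical_index": [np.nan]}
                )
            )

    def test_from_assessments_matches_class_frequencies(self, scored_artery_builder):
        arteries = [
            scored_artery_builder(
                [30, 45, 50, 41, 35], artery_id=f"P001-A{i}", patient_id="P001"
            )
            for i in range(3)
        ]
        lesions = assess_lesions(pd.concat(arteries, ignore_index=True))
        table = agreement_table(lesions)
        usable = lesions[lesions["has_references"]]
        for cls, count in table.row_counts.items():
            assert count == int((usable["fvri_class"] == cls).sum())


class TestCompositionByClass:
    @staticmethod
    def lesion_table(groups, values):
        df = pd.DataFrame({"fvri_class": groups, "fibrous_pct": values})
        for col in ("fibrofatty_pct", "necrotic_pct", "dense_calcium_pct"):
            df[col] = np.nan
        return df

    def test_identical_groups_give_f_zero_p_one(self):
        table = self.lesion_table(
            ["negative"] * 3 + ["ectatic"] * 3, [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        )
        res = composition_by_class(table)
        assert res["fibrous"]["f"] == pytest.approx(0.0, abs=1e-12)
        assert res["fibrous"]["p"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_f_statistic(self):
        # groups [1,2,3] vs [4,5,6]: SSB=13.5, SSW/df=1 -> F = 13.5
        table = self.lesion_table(
            ["negative"] * 3 + ["ectatic"] * 3, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        )
        res = composition_by_class(table)
        assert res["fibrous"]["f"] == pytest.approx(13.5, abs=1e-9)

    def test_missing_composition_skipped_with_warning(self):
        table = self.lesion_table(["negative"] * 3 + ["ectatic"] * 3, [np.nan] * 6)
        with pytest.warns(UserWarning, match="skipped"):
            res = composition_by_class(table)
        assert res == {}

    def test_small_groups_excluded_from_anova(self):
        table = self.lesion_table(
            ["negative", "negative", "negative", "ectatic"], [1.0, 2.0, 3.0, 9.0]
        )
        with pytest.warns(UserWarning):
            res = composition_by_class(table)
        assert res == {}
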