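"""Selection rule, binary scorecards, dose-response oracle agreement and
dense ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxscreen import (
    ScoreCard,
    build_scorecard,
    cards_to_table,
    default_truth_library,
    quantify_screen,
    reference_scorecard,
    score_binary,
    score_dose_response,
    select_first_screen,
    simulate_screen,
    total_and_rank,
    SimConfig,
)

DOSES = [1.0, 5.0, 25.0, 125.0]
LINES = ["A", "B", "C", "D"]


def grid(values):
    """4x4 delta grid, cell lines x ascending doses."""
    return pd.DataFrame(np.asarray(values, float), index=LINES, columns=DOSES)


def dose_response_oracle(deltas, assay, epsilon, tolerance):
    """Independent literal per-cell loop implementing the scoring rule:
    a cell scores 1 iff its directional call holds and its signed magnitude
    has not shrunk from the next-lower dose beyond the tolerance (lowest
    dose: directional call alone).  Missing cells — and cells whose
    next-lower neighbour is missing — conservatively score 0."""
    sign = 1.0 if assay == "migration" else -1.0
    out = pd.DataFrame(0, index=deltas.index, columns=deltas.columns)
    for line in deltas.index:
        for j, dose in enumerate(deltas.columns):
            d = sign * deltas.loc[line, dose]
            if not np.isfinite(d) or d <= epsilon:
                continue
            if j == 0:
                out.loc[line, dose] = 1
            else:
                prev = sign * deltas.loc[line, deltas.columns[j - 1]]
                if np.isfinite(prev) and d >= prev - tolerance:
                    out.loc[line, dose] = 1
    return out


class TestSelectFirstScreen:
    def _effects(self, rows):
        return pd.DataFrame(
            rows,
            columns=["compound_id", "cell_line", "dose_um", "delta_migration", "toxic"],
        )

    def test_positive_at_both_doses_selected(self):
        eff = self._effects([("a", "L", 5.0, 0.1, False), ("a", "L", 50.0, 0.1, False)])
        assert select_first_screen(eff, epsilon=0.0) == ["a"]

    def test_sign_flip_between_doses_not_selected(self):
        eff = self._effects([("a", "L", 5.0, 0.1, False), ("a", "L", 50.0, -0.1, False)])
        assert select_first_screen(eff, epsilon=0.0) == []

    def test_toxic_compound_excluded(self):
        eff = self._effects([("a", "L", 5.0, 0.3, False), ("a", "L", 50.0, 0.3, True)])
        assert select_first_screen(eff, epsilon=0.0) == []

    def test_missing_dose_excluded_with_warning(self, caplog):
        eff = self._effects([("a", "L", 5.0, 0.3, False)])
        with caplog.at_level("WARNING"):
            assert select_first_screen(eff, epsilon=0.0) == []
        assert "missing dose" in caplog.text

    def test_zero_noise_library_recovers_planted_enhancers_exactly(self):
        truths = default_truth_library(seed=21)
        ds = simulate_screen(SimConfig(seed=21, noise_sd=0.0), truths)
        eff = quantify_screen(ds)
        sel = select_first_screen(eff[eff.screen == 1])
        planted = {t.compound_id for t in truths if t.class_label == "enhancer"}
        assert set(sel) == planted


class TestScoreBinary:
    def test_all_positive_migration_saturates_at_16(self):
        mat = score_binary(grid(np.full((4, 4), 0.2)), "migration", epsilon=0.0)
        assert int(mat.to_numpy().sum()) == 16

    def test_all_zero_with_positive_epsilon_scores_zero(self):
        mat = score_binary(grid(np.zeros((4, 4))), "migration", epsilon=0.01)
        assert int(mat.to_numpy().sum()) == 0

    def test_ros_scored_for_decreases(self):
        d = grid(np.full((4, 4), -0.3))
        assert int(score_binary(d, "ros", 0.0).to_numpy().sum()) == 16
        assert int(score_binary(-d, "ros", 0.0).to_numpy().sum()) == 0

    def test_fourteen_positive_cells_score_fourteen(self):
        """A grid positive in exactly 14 of 16 cells scores 14 — the
        migration subscore structure of the top reference-scorecard row."""
        vals = np.full((4, 4), 0.2)
        vals[0, 0] = -0.05
        vals[3, 3] = 0.0
        mat = score_binary(grid(vals), "migration", epsilon=0.0)
        assert int(mat.to_numpy().sum()) == 14

    def test_missing_cells_score_zero_with_warning(self, caplog):
        vals = np.full((4, 4), 0.2)
        vals[1, 2] = np.nan
        with caplog.at_level("WARNING"):
            mat = score_binary(grid(vals), "migration", epsilon=0.0)
        assert int(mat.to_numpy().sum()) == 15
        assert "missing" in caplog.text

    def test_monotonicity_raising_delta_never_lowers_subscore(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            vals = rng.normal(0, 0.1, (4, 4))
            before = int(score_binary(grid(vals), "migration", 0.02).to_numpy().sum())
            bumped = vals + rng.uniform(0, 0.2, (4, 4))
            after = int(score_binary(grid(bumped), "migration", 0.02).to_numpy().sum())
            assert after >= before


class TestScoreDoseResponse:
    def test_strict_monotone_saturates_both_assays_at_32(self):
        inc = grid([[0.1, 0.2, 0.3, 0.4]] * 4)
        dec = -inc
        s = int(score_dose_response(inc, "migration", 0.0).to_numpy().sum())
        s += int(score_dose_response(dec, "ros", 0.0).to_numpy().sum())
        assert s == 32

    def test_all_zero_scores_zero(self):
        z = grid(np.zeros((4, 4)))
        assert int(score_dose_response(z, "migration", 0.01).to_numpy().sum()) == 0

    def test_agrees_with_brute_force_oracle_on_random_grids(self):
        """Elementwise agreement with the independent per-cell loop on
        1,000 random mixed grids, both assays."""
        rng = np.random.default_rng(42)
        for i in range(1000):
            vals = rng.normal(0, 0.15, (4, 4))
            if i % 3 == 0:  # sprinkle missing cells
                vals[rng.integers(4), rng.integers(4)] = np.nan
            eps = float(rng.uniform(0, 0.05))
            tol = float(rng.uniform(0, 0.05))
            d = grid(vals)
            for assay in ("migration", "ros"):
                got = score_dose_response(d, assay, eps, tol)
                want = dose_response_oracle(d, assay, eps, tol)
                pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_descending_doses_rejected(self):
        d = grid(np.zeros((4, 4)))
        d = d[d.columns[::-1]]
        with pytest.raises(Exception, match="ascending"):
            score_dose_response(d, "migration")


def card(cid, mig, ros_, dr, name=None):
    return ScoreCard(compound_id=cid, common_name=name or cid,
                     migration_subscore=mig, ros_subscore=ros_, doseresp_subscore=dr)


class TestTotalAndRank:
    def test_component_sum_and_top_rank(self):
        cards = [card("vitc", 14, 9, 19), card("other", 10, 6, 6)]
        ranked = total_and_rank(cards)
        assert ranked[0].compound_id == "vitc"
        assert ranked[0].total == 42
        assert ranked[0].rank == 1

    def test_tied_totals_share_rank_and_next_distinct_advances_by_one(self):
        ranked = total_and_rank(
            [card("a", 14, 9, 19), card("b", 14, 10, 17),
             card("c", 13, 14, 13), card("d", 14, 10, 16), card("e", 9, 8, 12)]
        )
        assert [c.total for c in ranked] == [42, 41, 40, 40, 29]
        assert [c.rank for c in ranked] == [1, 2, 3, 3, 4]

    def test_single_card_ranks_first(self):
        assert total_and_rank([card("solo", 0, 0, 0)])[0].rank == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        cards = [card(f"c{i}", int(rng.integers(17)), int(rng.integers(17)),
                      int(rng.integers(33))) for i in range(12)]
        base = {c.compound_id: c.rank for c in total_and_rank(list(cards))}
        for _ in range(5):
            rng.shuffle(cards)
            again = {c.compound_id: c.rank for c in total_and_rank(list(cards))}
            assert again == base

    def test_dense_rank_matches_pandas_cross_check(self):
        rng = np.random.default_rng(8)
        cards = [card(f"c{i}", int(rng.integers(17)), int(rng.integers(17)),
                      int(rng.integers(33))) for i in range(30)]
        ranked = total_and_rank(cards)
        table = cards_to_table(ranked)
        expected = table["total_max64"].rank(method="dense", ascending=False)
        assert (table["rank"] == expected.astype(int)).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 16), st.integers(0, 16),
                              st.integers(0, 32)), min_size=1, max_size=20))
    def test_score_conservation_and_bounds(self, subs):
        cards = [card(f"c{i}", m, r, d) for i, (m, r, d) in enumerate(subs)]
        ranked = total_and_rank(cards)
        for c in ranked:
            assert c.total == c.migration_subscore + c.ros_subscore + c.doseresp_subscore
            assert 0 <= c.total <= 64
        # ranks are 1..n_distinct_totals with no gaps
        ranks = [c.rank for c in ranked]
        assert ranks[0] == 1
        assert all(b - a in (0, 1) for a, b in zip(ranks, ranks[1:]))


class TestReferenceScorecard:
    """Checks against the shipped reference scorecard (printed component
    scores of the 18 ranked compounds)."""

    def test_component_sums_reproduce_printed_totals(self):
        ref = reference_scorecard()
        consistent = ref[ref.common_name != "GSH"]  # known printed inconsistency
        sums = (consistent.migration_max16 + consistent.ros_max16
                + consistent.dose_response_max32)
        assert (sums == consistent.total_max64).all()
        for name, total in [("Vitamin C", 42), ("Vitamin E", 41),
                            ("Protocatechuic acid", 40), ("β-Carotene", 29),
                            ("Canthaxanthin", 24)]:
            assert int(ref[ref.common_name == name].total_max64.iloc[0]) == total

    def test_dense_ranking_reproduces_printed_rank_labels(self):
        ref = reference_scorecard()
        cards = [
            ScoreCard(compound_id=r.common_name, common_name=r.common_name,
                      migration_subscore=int(r.migration_max16),
                      ros_subscore=int(r.ros_max16),
                      doseresp_subscore=int(r.total_max64 - r.migration_max16
                                            - r.ros_max16))
            for r in ref.itertuples()
        ]
        ranked = total_and_rank(cards)
        got = {c.compound_id: c.rank for c in ranked}
        want = dict(zip(ref.common_name, ref["rank"]))
        assert got == want
        # two compounds at total 40 share rank 3; next (29) takes rank 4
        at40 = [c.rank for c in ranked if c.total == 40]
        assert at40 == [3, 3]
        assert [c.rank for c in ranked if c.total == 29] == [4]


class TestBuildScorecard:
    def test_planted_antioxidant_enhancers_occupy_top_ranks(self, default_screen,
                                                            default_effects):
        s1 = default_effects[default_effects.screen == 1]
        s2 = default_effects[default_effects.screen == 2]
        sel = select_first_screen(s1)
        lines = sorted(s2.cell_line.unique())
        cards = [build_scorecard(s2, cid, lines, DOSES) for cid in sel]
        ranked = total_and_rank(cards)
        truth = default_screen.truth.set_index("compound_id")["class_label"]
        top_half = ranked[: len(ranked) // 2]
        assert all(truth[c.compound_id] == "enhancer" for c in top_half)

    def test_significance_gate_only_tightens(self, default_effects):
        s2 = default_effects[default_effects.screen == 2]
        lines = sorted(s2.cell_line.unique())
        cid = s2.compound_id.iloc[0]
        plain = build_scorecard(s2, cid, lines, DOSES)
        gated = build_scorecard(s2, cid, lines, DOSES, significance_gate=True)
        assert gated.total <= plain.total
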