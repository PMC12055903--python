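"""Session validation, BWS score aggregation and split-half reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bwsnorms import design as dz
from bwsnorms import scoring
from bwsnorms import synthetic_world as sw
from conftest import brute_force_bws


def _check(tuple_id="c001"):
    chain = [dz.WordItem(w) for w in ["object", "food", "baked-goods", "muffin"]]
    return dz.make_attention_check(chain, tuple_id, seed=0)


class TestValidateSession:
    def test_extreme_picks_pass(self):
        check = _check()
        assert scoring.validate_session({"c001": ("muffin", "object")}, {"c001": check})

    def test_non_strict_intermediate_picks_pass(self):
        """Any higher-ranked best over lower-ranked worst passes."""
        check = _check()
        assert scoring.validate_session({"c001": ("baked-goods", "object")}, {"c001": check})
        assert scoring.validate_session({"c001": ("muffin", "food")}, {"c001": check})

    def test_rank_inversion_fails(self):
        check = _check()
        assert not scoring.validate_session({"c001": ("food", "baked-goods")}, {"c001": check})

    def test_any_single_failure_excludes(self):
        checks = {"c001": _check("c001"), "c002": _check("c002")}
        answers = {"c001": ("muffin", "object"), "c002": ("object", "muffin")}
        assert not scoring.validate_session(answers, checks)

    def test_missing_answer_counts_as_fail(self):
        checks = {"c001": _check("c001"), "c002": _check("c002")}
        answers = {"c001": ("muffin", "object")}
        assert not scoring.validate_session(answers, checks, assigned=["c001", "c002"])


class TestExclusionRate:
    @pytest.mark.parametrize(
        "excluded,total,expected",
        [(39, 560, 6.96), (0, 100, 0.0), (1, 3, 33.33), (560, 560, 100.0)],
    )
    def test_rate_rounded_to_two_decimals(self, excluded, total, expected):
        assert scoring.exclusion_rate(excluded, total) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            scoring.exclusion_rate(0, 0)
        with pytest.raises(ValueError):
            scoring.exclusion_rate(5, 3)


class TestMinMaxScale:
    def test_affine_example(self):
        assert np.allclose(scoring.minmax_scale([2, 4, 6]), [0, 0.5, 1])

    def test_unit_vector_attaining_bounds_unchanged(self):
        v = np.array([0.0, 0.3, 0.7, 1.0])
        assert np.allclose(scoring.minmax_scale(v), v)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.integers(-10**6, 10**6), min_size=3, max_size=20, unique=True
        )
    )
    def test_rank_order_preserved(self, values):
        scaled = scoring.minmax_scale(values)
        assert sps.spearmanr(values, scaled).statistic == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scoring.minmax_scale([3.0, 3.0, 3.0])


def _judgment_set(rows):
    return scoring.JudgmentSet(
        records=pd.DataFrame(
            [
                {
                    "session_id": f"s{i}",
                    "rater_id": f"r{i}",
                    "list_id": "l1",
                    "tuple_id": t,
                    "is_check": 0,
                    "best": b,
                    "worst": w,
                }
                for i, (t, b, w) in enumerate(rows)
            ]
        )
    )


class TestBwsScores:
    def test_hand_counted_toy_example(self):
        """Two judgments over {A,B,C,D}: raw 1, 0, -0.5, -0.5."""
        items = {"t1": ("A", "B", "C", "D")}
        judgments = _judgment_set([("t1", "A", "D"), ("t1", "A", "C")])
        out = scoring.bws_scores(judgments, items)
        assert out.loc["A", "raw"] == 1.0
        assert out.loc["B", "raw"] == 0.0
        assert out.loc["C", "raw"] == -0.5
        assert out.loc["D", "raw"] == -0.5
        assert out.loc["A", "score"] == 1.0
        assert out.loc["B", "score"] == pytest.approx(1 / 3)
        assert out.loc["C", "score"] == 0.0

    def test_weighted_raw_scores_sum_to_zero(self):
        """Each judgment contributes one +1 and one -1."""
        items = {"t1": ("A", "B", "C", "D"), "t2": ("C", "D", "E", "F")}
        judgments = _judgment_set(
            [("t1", "A", "B"), ("t2", "F", "C"), ("t2", "C", "E"), ("t1", "D", "A")]
        )
        out = scoring.bws_scores(judgments, items, rescale=False)
        assert (out["raw"] * out["appearances"]).sum() == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_tally(self, data):
        """Oracle equivalence on instances with <= 6 words, <= 10 judgments."""
        words = list("ABCDEF")[: data.draw(st.integers(4, 6))]
        n_tuples = data.draw(st.integers(1, 3))
        items = {}
        rows = []
        for t in range(n_tuples):
            members = data.draw(
                st.lists(st.sampled_from(words), min_size=3, max_size=4, unique=True)
            )
            items[f"t{t}"] = tuple(members)
        n_judgments = data.draw(st.integers(1, 10))
        for j in range(n_judgments):
            tid = data.draw(st.sampled_from(sorted(items)))
            pair = data.draw(
                st.lists(st.sampled_from(items[tid]), min_size=2, max_size=2, unique=True)
            )
            rows.append((tid, pair[0], pair[1]))
        expected = brute_force_bws(rows, items)
        out = scoring.bws_scores(_judgment_set(rows), items, rescale=False)
        assert set(out.index) == set(expected)
        for word, raw in expected.items():
            assert out.loc[word, "raw"] == pytest.approx(raw)

    def test_invalid_sessions_excluded_from_scoring(self):
        items = {"t1": ("A", "B", "C", "D")}
        judgments = _judgment_set([("t1", "A", "D"), ("t1", "D", "A")])
        judgments.valid = pd.Series({"s0": True, "s1": False})
        out = scoring.bws_scores(judgments, items, rescale=False)
        assert out.loc["A", "raw"] == 1.0

    def test_downstream_spearman_identical_raw_vs_scaled(self, attentive_study, small_world):
        """Min-max rescaling never changes rank-based statistics."""
        ts, judgments = attentive_study
        out = scoring.bws_scores(judgments, ts.items_map())
        latent = small_world.specificity.loc[out.index]
        assert (
            sps.spearmanr(out["raw"], latent).statistic
            == pytest.approx(sps.spearmanr(out["score"], latent).statistic)
        )

    def test_best_equals_worst_rejected(self):
        with pytest.raises(ValueError, match="best == worst"):
            _judgment_set([("t1", "A", "A")])


class TestSplitHalfReliability:
    def test_duplicated_sessions_give_perfect_reliability(self):
        """Each tuple holds two identical records, so every split yields
        identical half-scores."""
        items = {"t1": ("A", "B", "C", "D"), "t2": ("A", "B", "C", "E")}
        base = [("t1", "A", "D"), ("t2", "E", "A")]
        judgments = _judgment_set(base + base)
        rel = scoring.split_half_reliability(judgments, items, n_iter=20, seed=0)
        assert rel.pearson_mean == pytest.approx(1.0)
        assert rel.spearman_mean == pytest.approx(1.0)
        assert rel.pearson_sd == pytest.approx(0.0)

    def test_attentive_simulation_reliable(self, attentive_study):
        ts, judgments = attentive_study
        rel = scoring.split_half_reliability(judgments, ts.items_map(), n_iter=30, seed=1)
        assert rel.spearman_mean >= 0.9
        assert rel.pearson_mean >= 0.9

    def test_careless_raters_unreliable(self):
        world = sw.sample_world(60, seed=30)
        lexicon = [dz.WordItem(w) for w in world.words]
        ts = dz.generate_tuples(lexicon, k=4, factor=2, seed=31)
        raters = sw.make_raters(10, careless_rate=1.0, seed=32)
        judgments = sw.simulate_judgments(ts, world, raters, per_tuple=10, seed=33)
        rel = scoring.split_half_reliability(judgments, ts.items_map(), n_iter=30, seed=34)
        assert abs(rel.spearman_mean) < 0.2

    def test_per_pool_breakdown(self, attentive_study):
        ts, judgments = attentive_study
        pools = {t.tuple_id: ("even" if int(t.tuple_id[1:]) % 2 == 0 else "odd")
                 for t in ts.tuples}
        rel = scoring.split_half_reliability(
            judgments, ts.items_map(), n_iter=5, seed=2, tuple_pools=pools
        )
        assert sorted(rel.per_pool.index) == ["even", "odd"]
        assert (rel.per_pool["spearman_mean"] > 0.8).all()

    def test_tuple_with_single_session_rejected(self):
        items = {"t1": ("A", "B", "C", "D")}
        judgments = _judgment_set([("t1", "A", "D")])
        with pytest.raises(ValueError, match="fewer than 2"):
            scoring.split_half_reliability(judgments, items, n_iter=2, seed=0)


class TestValidateSessions:
    def test_exclusion_of_failing_sessions(self):
        check = _check()
        records = pd.DataFrame(
            [
                {"session_id": "s1", "rater_id": "r1", "list_id": "l1",
                 "tuple_id": "c001", "is_check": 1, "best": "muffin", "worst": "object"},
                {"session_id": "s2", "rater_id": "r2", "list_id": "l1",
                 "tuple_id": "c001", "is_check": 1, "best": "object", "worst": "muffin"},
            ]
        )
        judgments = scoring.JudgmentSet(records=records)
        valid = scoring.validate_sessions(judgments, {"c001": check})
        assert valid.to_dict() == {"s1": True, "s2": False}
        assert judgments.valid is not None

    def test_session_without_check_records_fails_when_assigned(self):
        check = _check()
        records = pd.DataFrame(
            [{"session_id": "s1", "rater_id": "r1", "list_id": "l1",
              "tuple_id": "t9", "is_check": 0, "best": "A", "worst": "B"}]
        )
        judgments = scoring.JudgmentSet(records=records)
        valid = scoring.validate_sessions(
            judgments, {"c001": check}, assigned_by_list={"l1": ["c001"]}
        )
        assert not valid.loc["s1"]


class TestJudgmentsIO:
    def test_csv_roundtrip(self, tmp_path):
        judgments = _judgment_set([("t1", "A", "B"), ("t1", "C", "A")])
        scoring.write_judgments(judgments, tmp_path / "j.csv")
        back = scoring.read_judgments(tmp_path / "j.csv")
        pd.testing.assert_frame_equal(back.records, judgments.records)
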