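"""Scoring bins, SDI arithmetic, pooling, tertiles, and the Welch screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxtrace import scoring


class TestScoreBins:
    @pytest.mark.parametrize(
        "count,score",
        [(0, 0), (1, 1), (3, 1), (6, 1), (7, 2), (11, 2), (12, 3), (40, 3)],
    )
    def test_cell_count_bins(self, count, score):
        assert scoring.score_from_cell_count(count) == score

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            scoring.score_from_cell_count(-1)

    @pytest.mark.parametrize(
        "code,score", [("0", 0), ("+", 1), ("++", 2), ("+++", 3), ("++ ", 2), (" +", 1)]
    )
    def test_fiber_codes_with_whitespace_normalization(self, code, score):
        assert scoring.parse_fiber_code(code) == score

    def test_unknown_fiber_code_names_token(self):
        with pytest.raises(ValueError, match=r"\+\+\+\+"):
            scoring.parse_fiber_code("++++")


class TestComputeSDI:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([3, 3, 3], 1.0),
            ([0, 0, 0, 0], 0.0),
            ([1, 2, 3, 0], 6 / 12),
            ([1], 1 / 3),
        ],
    )
    def test_direct_formula(self, scores, expected):
        assert scoring.compute_sdi(scores).sdi == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="NT"):
            scoring.compute_sdi([])

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="0,1,2,3"):
            scoring.compute_sdi([1, 4])

    def test_exhaustive_brute_force_oracle(self):
        """Tally-based SDI equals sum(scores)/(3*NT) for every score vector, NT<=6."""
        for nt in range(1, 7):
            for vec in itertools.product(range(4), repeat=nt):
                rec = scoring.compute_sdi(vec)
                assert rec.sdi == pytest.approx(sum(vec) / (3 * nt), abs=1e-15)
                assert rec.n1 + rec.n2 + rec.n3 <= rec.nt == nt

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance(self, scores):
        shuffled = list(reversed(sorted(scores)))
        assert scoring.compute_sdi(scores).sdi == scoring.compute_sdi(shuffled).sdi

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=12),
        st.data(),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_single_section_score(self, scores, data):
        i = data.draw(st.integers(0, len(scores) - 1))
        if scores[i] == 3:
            return
        bumped = list(scores)
        bumped[i] += 1
        assert scoring.compute_sdi(bumped).sdi > scoring.compute_sdi(scores).sdi

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_zero_section_dilutes_unless_already_zero(self, scores):
        before = scoring.compute_sdi(scores).sdi
        after = scoring.compute_sdi(scores + [0]).sdi
        if before == 0:
            assert after == 0
        else:
            assert after < before


class TestPooling:
    def test_single_value_identity(self):
        df = pd.DataFrame({"region": ["A"], "sdi": [0.4]})
        assert scoring.pool_sdi(df)["pooled_sdi"].iloc[0] == pytest.approx(0.4)

    def test_mean_pooling(self):
        df = pd.DataFrame({"region": ["A", "A"], "sdi": [0.2, 0.4]})
        assert scoring.pool_sdi(df)["pooled_sdi"].iloc[0] == pytest.approx(0.3)

    def test_idempotent_on_constant(self):
        df = pd.DataFrame({"region": ["A"] * 3, "sdi": [1.0, 1.0, 1.0]})
        assert scoring.pool_sdi(df)["pooled_sdi"].iloc[0] == 1.0

    def test_median_option_and_unknown_rule(self):
        df = pd.DataFrame({"region": ["A"] * 3, "sdi": [0.0, 0.1, 0.8]})
        assert scoring.pool_sdi(df, how="median")["pooled_sdi"].iloc[0] == 0.1
        with pytest.raises(ValueError):
            scoring.pool_sdi(df, how="mode")


class TestTertiles:
    def test_one_region_per_class(self):
        pooled = pd.DataFrame(
            {"region": ["a", "b", "c"], "pooled_sdi": [0.0, 0.5, 1.0]}
        )
        out, bounds = scoring.classify_tertiles(pooled)
        assert dict(zip(out.region, out.tertile)) == {
            "a": "very sparse",
            "b": "sparse",
            "c": "dense",
        }
        assert bounds["lower"] < bounds["upper"]

    def test_degenerate_all_equal_warns_single_class(self):
        pooled = pd.DataFrame({"region": list("abcd"), "pooled_sdi": [0.3] * 4})
        with pytest.warns(UserWarning, match="degenerate"):
            out, _ = scoring.classify_tertiles(pooled)
        assert out["tertile"].nunique() == 1

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        pooled = pd.DataFrame(
            {"region": [f"r{i}" for i in range(30)], "pooled_sdi": rng.random(30)}
        )
        out, _ = scoring.classify_tertiles(pooled)
        assert len(out) == 30
        counts = out["tertile"].value_counts()
        assert counts.sum() == 30
        # each class non-empty and roughly a third for a continuous sample
        assert set(counts.index) == {"dense", "sparse", "very sparse"}

    def test_fewer_than_three_regions_rejected(self):
        pooled = pd.DataFrame({"region": ["a", "b"], "pooled_sdi": [0.1, 0.9]})
        with pytest.raises(ValueError):
            scoring.classify_tertiles(pooled)


def _records(region, male, female):
    rows = []
    for i, v in enumerate(male):
        rows.append({"animal": f"M{i}", "sex": "M", "region": region, "sdi": v})
    for i, v in enumerate(female):
        rows.append({"animal": f"F{i}", "sex": "F", "region": region, "sdi": v})
    return pd.DataFrame(rows)


class TestSexScreen:
    def test_identical_groups_give_t_zero_p_one(self):
        df = _records("A", [0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res, _ = scoring.sex_difference_screen(df)
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_against_hand_computed_welch(self):
        """Closed-form Welch t for male {0.18,0.20,0.22} vs female {0,0,0}."""
        m = [0.18, 0.20, 0.22]
        f = [0.0, 0.0, 0.0]
        vm = np.var(m, ddof=1)
        vf = 0.0
        t_expect = (np.mean(m) - 0.0) / math.sqrt(vm / 3 + vf / 3)
        df_expect = (vm / 3 + vf / 3) ** 2 / ((vm / 3) ** 2 / 2)
        res, _ = scoring.sex_difference_screen(_records("A", m, f))
        assert res["t"].iloc[0] == pytest.approx(t_expect, rel=1e-10)
        assert res["df"].iloc[0] == pytest.approx(df_expect, rel=1e-10)
        assert 0 < res["p"].iloc[0] < 0.05

    def test_exclusion_rule_lists_regions_separately(self):
        df = pd.concat(
            [_records("A", [0.1, 0.2], [0.1, 0.3]), _records("B", [0.5], [0.1, 0.2])]
        )
        res, excluded = scoring.sex_difference_screen(df, min_obs=2)
        assert list(res["region"]) == ["A"]
        assert list(excluded["region"]) == ["B"]
        assert "fewer than 2" in excluded["reason"].iloc[0]

    def test_zero_variance_equal_means_reported_nan(self):
        df = _records("A", [0.2, 0.2], [0.2, 0.2])
        res, _ = scoring.sex_difference_screen(df)
        assert np.isnan(res["t"].iloc[0])


def test_compute_sdi_table_groups_and_carries_sex():
    rows = []
    for region, scores in (("PVH", [3, 3]), ("LH", [0, 1, 0])):
        for i, s in enumerate(scores):
            rows.append(
                {
                    "animal": "M1",
                    "sex": "M",
                    "region": region,
                    "modality": "cells",
                    "section_index": i,
                    "score": s,
                }
            )
    out = scoring.compute_sdi_table(pd.DataFrame(rows))
    by_region = dict(zip(out.region, out.sdi))
    assert by_region["PVH"] == 1.0
    assert by_region["LH"] == pytest.approx(1 / 9)
    assert set(out["sex"]) == {"M"}
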