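"""Harmonization, the interaction model, and estimated linear trends."""

import numpy as np
import pandas as pd
import pytest

from oxtrace import concordance as cc
from oxtrace import synthetic as sy


@pytest.fixture
def small_mapping():
    return {
        "BNST": {
            "sdi_label": "BNST",
            "receptor_labels": ["BNST_ant", "BNST_post"],
            "category": "striatum_pallidum",
        },
        "RE": {"sdi_label": "RE", "receptor_labels": ["RE"], "category": "thalamus"},
        "PVH": {"sdi_label": "PVH", "receptor_labels": ["PVH"], "category": "hypothalamus"},
    }


@pytest.fixture
def small_tables():
    sdi = pd.DataFrame(
        {"region": ["BNST", "RE", "PVH", "OnlyFiber"], "pooled_sdi": [0.6, 0.4, 0.9, 0.2]}
    )
    receptor = pd.DataFrame(
        {"region": ["BNST_ant", "BNST_post", "RE", "PVH", "OnlyRec"],
         "score": [3.0, 4.0, 2.0, 1.0, 4.0]}
    )
    return sdi, receptor


class TestHarmonize:
    def test_subregion_scores_averaged(self, small_tables, small_mapping):
        table, _ = cc.harmonize(*small_tables, small_mapping)
        bnst = table.set_index("region").loc["BNST"]
        assert bnst.receptor_score == pytest.approx(3.5)
        assert bnst.included

    def test_unmatched_regions_excluded_with_reason(self, small_tables, small_mapping):
        table, _ = cc.harmonize(*small_tables, small_mapping)
        t = table.set_index("region")
        assert not t.loc["OnlyFiber", "included"]
        assert t.loc["OnlyFiber", "exclusion_reason"] == "no receptor counterpart"
        assert not t.loc["OnlyRec", "included"]
        assert t.loc["OnlyRec", "exclusion_reason"] == "no fiber-SDI counterpart"
        # included=False iff a reason is recorded
        assert (
            (table.exclusion_reason != "") == ~table.included
        ).all()

    def test_empty_mapping_audit_all_excluded(self, small_tables):
        table, audit = cc.harmonize(*small_tables, {})
        assert audit["sdi_matched"] == audit["receptor_matched"] == 0
        assert not table.included.any()

    def test_audit_conserves_rows(self, small_tables, small_mapping):
        sdi, receptor = small_tables
        _, audit = cc.harmonize(sdi, receptor, small_mapping)
        assert audit["sdi_matched"] + audit["sdi_excluded"] == len(sdi)
        assert audit["receptor_matched"] + audit["receptor_excluded"] == len(receptor)

    def test_unknown_mapping_label_rejected(self, small_tables, small_mapping):
        small_mapping["RE"]["receptor_labels"] = ["NoSuchRegion"]
        with pytest.raises(KeyError, match="NoSuchRegion"):
            cc.harmonize(*small_tables, small_mapping)


def _noiseless_table(slopes, intercepts=None, n=6):
    cats = [(f"cat{i}", s, 0.2 if intercepts is None else intercepts[i])
            for i, s in enumerate(slopes)]
    return sy.gen_concordance_table(
        sy.ConcordanceSimParams(categories=tuple(cats), regions_per_category=n,
                                noise_sd=0.0, seed=13)
    )


class TestInteractionModel:
    def test_identical_slopes_no_interaction(self):
        table = _noiseless_table([0.05, 0.05, 0.05])
        model = cc.fit_interaction_model(table, categories=("cat0", "cat1", "cat2"))
        assert model["interaction_F"] <= 1e-10
        assert model["interaction_p"] == pytest.approx(1.0)

    def test_distinct_slopes_strong_interaction(self):
        table = _noiseless_table([0.13, 0.0, 0.0, 0.0, 0.0])
        model = cc.fit_interaction_model(
            table, categories=tuple(f"cat{i}" for i in range(5))
        )
        assert np.isfinite(model["interaction_F"])
        assert model["interaction_F"] > 0
        assert model["interaction_p"] < 1e-6

    def test_single_region_category_rejected_by_name(self):
        table = _noiseless_table([0.1, 0.2], n=5)
        lone = pd.DataFrame(
            [{"region": "x", "category": "lonely", "receptor_score": 2.0,
              "pooled_sdi": 0.5, "included": True, "exclusion_reason": ""}]
        )
        table = pd.concat([table, lone], ignore_index=True)
        with pytest.raises(ValueError, match="lonely"):
            cc.fit_interaction_model(table, categories=("cat0", "cat1", "lonely"))

    def test_default_excludes_hindbrain(self):
        table = _noiseless_table([0.1, 0.2])
        table.loc[table.category == "cat0", "category"] = "thalamus"
        table.loc[table.category == "cat1", "category"] = "hypothalamus"
        hind = table.iloc[:3].copy()
        hind["category"] = "hindbrain"
        model = cc.fit_interaction_model(pd.concat([table, hind], ignore_index=True))
        assert "hindbrain" not in model["categories"]


class TestTrends:
    def test_noiseless_slopes_recovered_exactly(self):
        table = _noiseless_table([0.13, -0.04])
        model = cc.fit_interaction_model(table, categories=("cat0", "cat1"))
        trends = cc.estimate_trends(model).set_index("category")["trend"]
        assert trends["cat0"] == pytest.approx(0.13, abs=1e-10)
        assert trends["cat1"] == pytest.approx(-0.04, abs=1e-10)

    def test_trend_equals_subset_regression_slope(self):
        table = sy.gen_concordance_table(
            sy.ConcordanceSimParams(
                categories=(("a", 0.1, 0.3), ("b", -0.05, 0.5)),
                regions_per_category=10, noise_sd=0.04, seed=31,
            )
        )
        model = cc.fit_interaction_model(table, categories=("a", "b"))
        trends = cc.estimate_trends(model).set_index("category")["trend"]
        for cat in ("a", "b"):
            grp = table[table.category == cat]
            slope = np.polyfit(grp.receptor_score, grp.pooled_sdi, 1)[0]
            assert trends[cat] == pytest.approx(slope, abs=1e-10)

    def test_invariant_to_reference_category(self):
        table = sy.gen_concordance_table(
            sy.ConcordanceSimParams(
                categories=(("alpha", 0.08, 0.3), ("beta", -0.02, 0.5), ("gamma", 0.0, 0.4)),
                regions_per_category=8, noise_sd=0.03, seed=17,
            )
        )
        m1 = cc.fit_interaction_model(table, categories=("alpha", "beta", "gamma"))
        relabeled = table.copy()
        relabeled["category"] = relabeled["category"].map(
            {"alpha": "z_alpha", "beta": "beta", "gamma": "gamma"}
        )
        m2 = cc.fit_interaction_model(relabeled, categories=("z_alpha", "beta", "gamma"))
        t1 = cc.estimate_trends(m1).set_index("category")["trend"]
        t2 = cc.estimate_trends(m2).set_index("category")["trend"]
        assert m1["reference_category"] != m2["reference_category"]
        assert t1["alpha"] == pytest.approx(t2["z_alpha"], abs=1e-10)
        assert t1["beta"] == pytest.approx(t2["beta"], abs=1e-10)

    def test_both_orientations_fit(self):
        table = sy.gen_concordance_table(sy.ConcordanceSimParams(seed=9))
        for orientation in ("sdi_on_receptor", "receptor_on_sdi"):
            model = cc.fit_interaction_model(table, orientation=orientation)
            trends = cc.estimate_trends(model)
            assert len(trends) == 5
            assert (trends.se >= 0).all()
            assert trends.p.between(0, 1).all()

    def test_pure_noise_trends_centered_on_zero(self):
        """Over replicates with zero slope, |mean trend| stays under 2x mean SE."""
        trends, ses = [], []
        for seed in range(200):
            table = sy.gen_concordance_table(
                sy.ConcordanceSimParams(
                    categories=(("a", 0.0, 0.4), ("b", 0.0, 0.4)),
                    regions_per_category=8, noise_sd=0.05, seed=seed,
                )
            )
            model = cc.fit_interaction_model(table, categories=("a", "b"))
            out = cc.estimate_trends(model)
            trends.append(out.trend.to_numpy())
            ses.append(out.se.to_numpy())
        mean_trend = np.mean(trends, axis=0)
        mean_se = np.mean(ses, axis=0)
        assert (np.abs(mean_trend) < 2 * mean_se).all()

    def test_trend_recovery_at_published_thalamus_slope(self):
        """Mean recovered slope over 200 tables within 0.02 of beta=0.13."""
        recovered = []
        for seed in range(200):
            table = sy.gen_concordance_table(
                sy.ConcordanceSimParams(
                    categories=(("thalamus", 0.13, 0.1), ("cortex", 0.0, 0.2)),
                    regions_per_category=15, noise_sd=0.05, seed=seed,
                )
            )
            model = cc.fit_interaction_model(table, categories=("thalamus", "cortex"))
            t = cc.estimate_trends(model).set_index("category")["trend"]
            recovered.append(t["thalamus"])
        assert abs(np.mean(recovered) - 0.13) < 0.02
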