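"""DSSA: fitness scores, Welch significance, BH q-values, consensus filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen.datagen import PlantedTruth, PoolDesign, generate_pool
from poolscreen.dssa import (
    TreatmentCondition,
    consensus_filter,
    consensus_genes,
    dssa_table,
    fitness_scores,
    significance,
)
from poolscreen.fixtures import load_paper_fixture
from poolscreen.normalize import regroup_tags

COND = TreatmentCondition("HQ", "25", 5)


def _values(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows, index=["c1", "c2", "t1", "t2"]).T


class TestScores:
    def test_mean_difference(self, toy_design):
        v = _values({"s1": [10.0, 10.0, 8.0, 8.0]})
        assert fitness_scores(v, toy_design, COND)["s1"] == -2.0

    def test_identical_groups_zero(self, toy_design):
        v = _values({"s1": [9.0, 9.5, 9.0, 9.5]})
        assert fitness_scores(v, toy_design, COND)["s1"] == 0.0

    def test_missing_condition_raises(self, toy_design):
        v = _values({"s1": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(KeyError):
            fitness_scores(v, toy_design, TreatmentCondition("CAT", "25", 5))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=4))
    def test_antisymmetric_under_label_swap(self, vals):
        design = pd.DataFrame(
            {"compound": ["control", "control", "HQ", "HQ"],
             "dose": ["control", "control", "25", "25"],
             "generation": 5, "replicate": [1, 2, 1, 2]},
            index=pd.Index(["c1", "c2", "t1", "t2"], name="chip"),
        )
        swapped = pd.DataFrame(
            {"compound": ["HQ", "HQ", "control", "control"],
             "dose": ["25", "25", "control", "control"],
             "generation": 5, "replicate": [1, 2, 1, 2]},
            index=pd.Index(["c1", "c2", "t1", "t2"], name="chip"),
        )
        v = _values({"s1": vals})
        a = fitness_scores(v, design, COND)["s1"]
        b = fitness_scores(v, swapped, COND)["s1"]
        assert a == pytest.approx(-b, abs=1e-12)

    def test_planted_score_concentrates_on_truth(self):
        # planted -3 log2 with noise 0.1: score within +-0.2 in >=95% of runs
        hits = 0
        for s in range(100):
            d = PoolDesign(n_strains=20, generations=(5,), chip_sd=0.0,
                           noise_sd=0.1, seed=500 + s)
            planted = (PlantedTruth("strain00000", {"100": 0.6}),)
            m, chips, _ = generate_pool(d, planted)
            sc = fitness_scores(regroup_tags(m), chips, TreatmentCondition("HQ", "100", 5))
            hits += abs(sc["strain00000"] + 3.0) < 0.2
        assert hits >= 95


class TestSignificance:
    def test_degenerate_equal_constant_p1(self, toy_design):
        v = _values({"s1": [5.0, 5.0, 5.0, 5.0]})
        out = significance(v, toy_design, COND)
        assert out.loc["s1", "p_value"] == 1.0

    def test_type_one_error_calibrated_at_screen_design(self):
        # complete null at 3 treated vs 12 control chips: the moderated test
        # keeps the fraction p<0.05 inside the binomial 99% CI at 2000 strains
        d = PoolDesign(n_strains=2000, generations=(5,), chip_sd=0.0, seed=9)
        m, chips, _ = generate_pool(d)
        out = significance(regroup_tags(m), chips, TreatmentCondition("HQ", "100", 5))
        frac = (out["p_value"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - half < frac < 0.05 + half

    def test_plain_welch_tail_inflation_documented(self):
        # without moderation the 3-vs-12 Welch statistic has ~2-3 df and runs
        # mildly hot; its size must stay inside the documented band
        d = PoolDesign(n_strains=2000, generations=(5,), chip_sd=0.0, seed=9)
        m, chips, _ = generate_pool(d)
        out = significance(regroup_tags(m), chips, TreatmentCondition("HQ", "100", 5),
                           moderated=False)
        frac = (out["p_value"] < 0.05).mean()
        assert 0.03 < frac < 0.10

    def test_power_on_strong_effect(self):
        # one planted strain at -4 log2, noise 0.2: q<0.05 in >=99/100 runs
        q_hits = 0
        for s in range(100):
            d = PoolDesign(n_strains=200, generations=(5,), chip_sd=0.0,
                           noise_sd=0.2, seed=1500 + s)
            planted = (PlantedTruth("strain00000", {"100": 0.8}),)
            m, chips, _ = generate_pool(d, planted)
            out = significance(regroup_tags(m), chips, TreatmentCondition("HQ", "100", 5))
            q_hits += out.loc["strain00000", "q_value"] < 0.05
        assert q_hits >= 99

    def test_bh_matches_stepup_oracle(self, rng):
        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 11))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_more_effect_more_hits(self):
        hits = []
        for defect in (0.1, 0.3, 0.6):
            total = 0
            for s in range(5):
                d = PoolDesign(n_strains=150, generations=(5,), chip_sd=0.0,
                               noise_sd=0.3, seed=2500 + s)
                planted = tuple(
                    PlantedTruth(f"strain{i:05d}", {"100": defect}) for i in range(15)
                )
                m, chips, _ = generate_pool(d, planted)
                out = significance(regroup_tags(m), chips, TreatmentCondition("HQ", "100", 5))
                total += int(out["significant"].sum())
            hits.append(total)
        assert hits[0] <= hits[1] <= hits[2]


class TestConsensus:
    @pytest.mark.parametrize("table_id,expected", [("T2", 31), ("T3", 33), ("T4", 12)])
    def test_fixture_counts(self, table_id, expected):
        fx = load_paper_fixture(table_id)
        assert len(consensus_genes(fx, k_min=3, sign="any")) == expected

    def test_negative_only_excludes_resistant(self):
        fx = load_paper_fixture("T3")
        any_mode = set(consensus_genes(fx, sign="any"))
        neg_mode = set(consensus_genes(fx, sign="negative_only"))
        assert "YKL133C" in any_mode and "YKL133C" not in neg_mode

    def test_long_format_counting(self):
        rows = []
        for cond in range(6):
            for strain, sig in (("a", True), ("b", cond < 2)):
                rows.append(("HQ", f"c{cond}", strain, -1.0, sig))
        t = pd.DataFrame(rows, columns=["compound", "condition", "strain", "score", "significant"])
        out = consensus_filter(t, k_min=3)
        assert bool(out.loc["a", "consensus"]) and not bool(out.loc["b", "consensus"])
        assert out.loc["b", "n_significant_conditions"] == 2

    def test_bad_sign_mode(self):
        with pytest.raises(ValueError):
            consensus_filter(load_paper_fixture("T4"), sign="positive")
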