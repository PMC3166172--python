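"""Mixed dose models: recovery, LRT behavior, Holm, Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from poolscreen.datagen import PoolDesign, PlantedTruth, generate_pool
from poolscreen.dosemodel import (
    fit_dose_models,
    fit_gene_model,
    holm_correct,
    kruskal_wallis,
    lrt_dose,
)
from poolscreen.normalize import regroup_tags


def _labels(n_control=12, n_per_dose=3):
    doses = ["control"] * n_control + [d for d in ("25", "50", "100") for _ in range(n_per_dose)]
    chips = np.arange(len(doses))
    tags = np.array(["UP"] * len(doses) + ["DOWN"] * len(doses))
    return np.concatenate([chips, chips]), tags, np.array(doses * 2)


class TestFit:
    def test_noiseless_delta_identified(self):
        chips, tags, doses = _labels()
        y = 10.0 + 0.5 * (tags == "DOWN")
        fit = fit_gene_model(y, chips, tags, doses, full=True)
        assert fit.delta == pytest.approx(0.5, abs=1e-9)
        assert fit.mu == pytest.approx(10.0, abs=1e-9)
        assert fit.sigma_res == pytest.approx(0.0, abs=1e-6)

    def test_null_betas_near_zero(self):
        chips, tags, doses = _labels()
        rng = np.random.default_rng(4)
        betas = []
        for _ in range(20):
            y = 10.0 + 0.2 * (tags == "DOWN") + rng.normal(0, 0.1, len(tags))
            f = fit_gene_model(y, chips, tags, doses)
            betas.extend(f.beta.values())
        assert np.median(np.abs(betas)) < 0.1

    def test_recovers_dose_effects_with_chip_noise(self):
        chips, tags, doses = _labels()
        truth = {"25": -1.0, "50": -2.0, "100": -3.0}
        rng = np.random.default_rng(8)
        err = {d: [] for d in truth}
        for _ in range(50):
            chip_eff = rng.normal(0, 0.2, chips.max() + 1)
            y = (10.0 + chip_eff[chips] + 0.5 * (tags == "DOWN")
                 + np.array([truth.get(d, 0.0) for d in doses])
                 + rng.normal(0, 0.2, len(tags)))
            f = fit_gene_model(y, chips, tags, doses)
            for d in truth:
                err[d].append(f.beta[d] - truth[d])
        for d in truth:
            assert abs(np.median(err[d])) < 0.3


class TestLRT:
    def test_constant_data_lrt_zero(self):
        chips, tags, doses = _labels()
        y = np.full(len(tags), 7.0)
        lrt, p = lrt_dose(y, chips, tags, doses)
        assert lrt == 0.0 and p == 1.0

    def test_location_invariance(self):
        chips, tags, doses = _labels()
        rng = np.random.default_rng(12)
        y = 10.0 + rng.normal(0, 0.3, len(tags))
        a = lrt_dose(y, chips, tags, doses)[0]
        b = lrt_dose(y + 123.4, chips, tags, doses)[0]
        assert a == pytest.approx(b, abs=1e-6)

    def test_power_on_strong_dose_effect(self):
        chips, tags, doses = _labels()
        truth = np.array([{"control": 0.0, "25": -1.0, "50": -2.0, "100": -3.0}[d] for d in doses])
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            y = 10.0 + truth + rng.normal(0, 0.2, len(tags))
            _, p = lrt_dose(y, chips, tags, doses)
            hits += p < 1e-6
        assert hits >= 99


class TestHolm:
    def test_hand_oracle(self):
        np.testing.assert_allclose(holm_correct(np.array([0.04, 0.01, 0.02])),
                                   [0.04, 0.03, 0.04])

    def test_single_and_saturated(self):
        assert holm_correct(np.array([0.01]))[0] == 0.01
        assert (holm_correct(np.ones(5)) == 1.0).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            holm_correct(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bounded_by_raw_and_bonferroni(self, p):
        p = np.array(p)
        adj = holm_correct(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= np.minimum(p * len(p), 1.0) + 1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 15))
            _, ref, _, _ = multipletests(p, method="holm")
            np.testing.assert_allclose(holm_correct(p), ref, atol=1e-12)


class TestKruskalWallis:
    def test_hand_oracle(self):
        # groups {1,2} vs {3,4}: H = 2.4 by the rank formula
        vals = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=["c1", "c2", "t1", "t2"])
        design = pd.DataFrame(
            {"compound": ["control"] * 2 + ["HQ"] * 2,
             "dose": ["control"] * 2 + ["25"] * 2,
             "generation": 5, "replicate": [1, 2, 1, 2]},
            index=pd.Index(["c1", "c2", "t1", "t2"], name="chip"),
        )
        out = kruskal_wallis(vals, design, "HQ", 5, dose_levels=("25",))
        assert out["H"].iloc[0] == pytest.approx(2.4)

    def test_total_tie_gives_zero(self, toy_design):
        vals = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], columns=["c1", "c2", "t1", "t2"])
        out = kruskal_wallis(vals, toy_design, "HQ", 5, dose_levels=("25",))
        assert out["H"].iloc[0] == 0.0

    def test_matches_scipy(self, chip_level):
        vals, design = chip_level
        out = kruskal_wallis(vals, design, "HQ", 5)
        for g in vals.index[:40]:
            groups = [
                vals.loc[g, design.index[design["dose"] == lab]].to_numpy()
                for lab in ("control", "25", "50", "100")
            ]
            ref = stats.kruskal(*groups).statistic
            assert out.loc[g, "H"] == pytest.approx(ref, abs=1e-10)

    def test_single_group_raises(self):
        vals = pd.DataFrame([[1.0, 2.0]], columns=["c1", "c2"])
        design = pd.DataFrame(
            {"compound": ["control"] * 2, "dose": ["control"] * 2,
             "generation": 5, "replicate": [1, 2]},
            index=pd.Index(["c1", "c2"], name="chip"),
        )
        with pytest.raises(ValueError):
            kruskal_wallis(vals, design, "HQ", 5)

    def test_null_p_close_to_exact_permutation_reference(self):
        # the chi-square approximation at 12/3/3/3 is only approximate; check
        # the H null distribution itself against a permutation reference
        d = PoolDesign(n_strains=2000, generations=(5,), chip_sd=0.0, seed=14)
        m, chips, _ = generate_pool(d)
        vals = regroup_tags(m)
        out = kruskal_wallis(vals, chips, "HQ", 5)
        rng = np.random.default_rng(0)
        base = np.arange(21)
        labels = np.array(["control"] * 12 + ["25"] * 3 + ["50"] * 3 + ["100"] * 3)
        ref = []
        for _ in range(4000):
            y = rng.normal(size=21)
            ranks = stats.rankdata(y)
            h = 0.0
            for lab in ("control", "25", "50", "100"):
                sel = labels == lab
                h += ranks[sel].sum() ** 2 / sel.sum()
            ref.append(12.0 / (21 * 22) * h - 3 * 22)
        ks = stats.ks_2samp(out["H"], ref)
        assert ks.statistic < 0.05


def test_ranking_concordant_with_kw(small_pool):
    # genes with monotone planted dose effects: LRT and KW order them alike
    design = PoolDesign(n_strains=120, generations=(5,), seed=77)
    planted = tuple(
        PlantedTruth(f"strain{i:05d}",
                     {"25": 0.05 * (i % 8), "50": 0.075 * (i % 8), "100": 0.1 * (i % 8)})
        for i in range(60)
    )
    m, chips, _ = generate_pool(design, planted)
    fit = fit_dose_models(m, chips, "HQ", 5)
    kw = kruskal_wallis(regroup_tags(m), chips, "HQ", 5)
    rho = stats.spearmanr(fit["lrt"], kw.loc[fit.index, "H"]).statistic
    assert rho >= 0.8


def test_fit_table_shape_and_flags(small_pool):
    _, planted, m, chips, _ = small_pool
    fit = fit_dose_models(m, chips, "HQ", 5)
    assert {"mu", "delta", "beta25", "beta50", "beta100", "sigma_chip",
            "sigma_res", "lrt", "p_raw", "p_holm", "selected"} <= set(fit.columns)
    assert (fit["p_holm"] >= fit["p_raw"] - 1e-12).all()
    assert (fit["lrt"] >= 0).all()
    # the ten strains planted at -2 log2 should dominate the selections
    sel = set(fit.index[fit["selected"]])
    truth = {p.strain_id for p in planted}
    assert len(truth & sel) >= 9
    assert len(sel - truth) <= max(2, len(sel) // 10)


def test_masked_measurements_fallback(small_pool):
    _, _, m, chips, _ = small_pool
    m2 = m.iloc[:40].copy()
    m2.iloc[3, 5] = np.nan
    fit = fit_dose_models(m2, chips, "HQ", 5)
    assert np.isfinite(fit["lrt"]).all()
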