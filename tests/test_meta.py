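"""Harmonization, inverse-variance pooling, novelty and hit calling."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from modscreen import meta, simulate
from modscreen.config import SimConfig


class TestTruncateP:
    def test_boundaries_and_interior(self):
        assert meta.truncate_p(0.0) == 1e-300
        assert meta.truncate_p(0.5) == 0.5
        assert meta.truncate_p(1.0) == 1.0 - 1e-16

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            meta.truncate_p(-0.1)
        with pytest.raises(ValueError):
            meta.truncate_p(1.1)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, derandomize=True)
    def test_monotone_non_decreasing(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert meta.truncate_p(lo) <= meta.truncate_p(hi)


def make_table(effects, pvals):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(effects))],
        "effect": effects,
        "p_raw": pvals,
    })


class TestHarmonize:
    def test_beta_standardized_within_screen(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(5, 3, 100), rng.uniform(size=100))
        h = meta.harmonize_screen(table)
        assert h["beta"].mean() == pytest.approx(0, abs=1e-12)
        assert h["beta"].std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_z_and_se_reproduce_reported_evidence(self):
        """beta = Phi^-1(0.975), p = 0.05 must give z = beta and se = 1."""
        rng = np.random.default_rng(1)
        effects = np.concatenate([[1.959964], rng.normal(size=50)])
        pvals = np.concatenate([[0.05], rng.uniform(size=50)])
        h = meta.harmonize_screen(make_table(effects, pvals), beta_mode="raw_effect")
        assert h.loc["g0", "z"] == pytest.approx(1.959964, abs=1e-5)
        assert h.loc["g0", "se"] == pytest.approx(1.0, abs=1e-5)

    def test_p_zero_guarded_by_floor(self):
        h = meta.harmonize_screen(make_table([1.0, -1.0, 0.5, 2.0],
                                             [0.0, 0.5, 0.5, 0.5]))
        assert np.isfinite(h.loc["g0", "z"])
        assert np.isfinite(h.loc["g0", "se"]) and h.loc["g0", "se"] > 0

    def test_already_standardized_effects_pass_through(self):
        rng = np.random.default_rng(2)
        effects = rng.normal(size=200)
        effects = (effects - effects.mean()) / effects.std()
        h = meta.harmonize_screen(make_table(effects, rng.uniform(size=200)))
        np.testing.assert_allclose(h["beta"].to_numpy(), effects, atol=1e-12)

    def test_sign_of_z_follows_beta(self):
        rng = np.random.default_rng(3)
        h = meta.harmonize_screen(make_table(rng.normal(size=100),
                                             rng.uniform(size=100)))
        nonzero = h["beta"] != 0
        assert (np.sign(h.loc[nonzero, "z"]) == np.sign(h.loc[nonzero, "beta"])).all()

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            meta.harmonize_screen(make_table([1.0, 1.0, 1.0], [0.5, 0.5, 0.5]))


class TestFixedEffectPool:
    def test_two_identical_screens_closed_form(self):
        r = meta.fixed_effect_pool(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert r["beta_pooled"] == pytest.approx(1.0)
        assert r["se_pooled"] == pytest.approx(1 / np.sqrt(2))
        assert r["q_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_disagreement_q(self):
        # (2, 1) and (0, 1): pooled 1, Q = 1*(2-1)^2 + 1*(0-1)^2 = 2, df 1
        r = meta.fixed_effect_pool(np.array([2.0, 0.0]), np.array([1.0, 1.0]))
        assert r["beta_pooled"] == pytest.approx(1.0)
        assert r["q_stat"] == pytest.approx(2.0)
        assert r["q_df"] == 1

    def test_k_identical_screens_se_scaling(self):
        for k in (2, 3, 5):
            r = meta.fixed_effect_pool(np.full(k, 0.7), np.full(k, 1.3))
            assert r["beta_pooled"] == pytest.approx(0.7)
            assert r["se_pooled"] == pytest.approx(1.3 / np.sqrt(k))

    def test_matches_weighted_least_squares_intercept(self, rng):
        """Brute-force WLS intercept fit is the independent oracle."""
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            beta = rng.normal(size=k)
            se = rng.uniform(0.1, 2.0, size=k)
            r = meta.fixed_effect_pool(beta, se)
            w = 1.0 / se**2
            X = np.ones((k, 1))
            wls = np.linalg.solve(
                X.T @ (w[:, None] * X), X.T @ (w * beta))[0]
            assert abs(r["beta_pooled"] - wls) < 1e-10
            resid_q = np.sum(w * (beta - wls) ** 2)
            assert abs(r["q_stat"] - resid_q) < 1e-10

    def test_se_pooled_never_exceeds_min_constituent(self, rng):
        beta = rng.normal(size=(200, 4))
        se = rng.uniform(0.2, 2.0, size=(200, 4))
        r = meta.fixed_effect_pool(beta, se)
        assert (r["se_pooled"] <= se.min(axis=1) + 1e-12).all()

    def test_se_pooled_decreases_with_added_screens(self):
        prev = np.inf
        for k in range(2, 7):
            r = meta.fixed_effect_pool(np.zeros(k), np.ones(k))
            assert r["se_pooled"] < prev
            prev = r["se_pooled"]

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            meta.fixed_effect_pool(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            meta.fixed_effect_pool(np.array([1.0]), np.array([1.0]))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_metafor_fixed_effect(self, tmp_path, rng):
        """R metafor rma(method='FE') as a fully independent implementation."""
        script = tmp_path / "fe.R"
        script.write_text(
            'suppressMessages(library(metafor))\n'
            'args <- commandArgs(trailingOnly=TRUE)\n'
            'd <- read.table(args[1], header=TRUE)\n'
            'fit <- rma(yi=d$beta, sei=d$se, method="FE")\n'
            'cat(sprintf("%.12g %.12g %.12g\\n", coef(fit), fit$se, fit$QE))\n'
        )
        for trial in range(3):
            k = int(rng.integers(2, 6))
            beta = rng.normal(size=k)
            se = rng.uniform(0.2, 1.5, size=k)
            tsv = tmp_path / f"d{trial}.tsv"
            pd.DataFrame({"beta": beta, "se": se}).to_csv(tsv, sep="\t", index=False)
            out = subprocess.run(["Rscript", str(script), str(tsv)],
                                 capture_output=True, text=True, check=True)
            b_r, se_r, q_r = map(float, out.stdout.split())
            r = meta.fixed_effect_pool(beta, se)
            assert r["beta_pooled"] == pytest.approx(b_r, rel=1e-9)
            assert r["se_pooled"] == pytest.approx(se_r, rel=1e-9)
            assert r["q_stat"] == pytest.approx(q_r, rel=1e-9)


class TestBH:
    def test_step_up_by_hand(self):
        # p = {0.01, 0.02, 0.03, 0.04}: adjusted all 0.04
        np.testing.assert_allclose(
            meta.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        assert (meta.bh_adjust(p) >= p - 1e-15).all()


def harmonized_screens(cfg):
    tables, truth = simulate.gen_screen_tables(cfg)
    return {t["screen_id"].iloc[0]: meta.harmonize_screen(t) for t in tables}, truth


class TestRunMeta:
    def test_three_screens_all_gives_four_combinations(self, small_screens_cfg):
        screens, _ = harmonized_screens(small_screens_cfg)
        res = meta.run_meta(screens)
        assert len(res) == 4
        assert set(res) == {
            "screen_0+screen_1", "screen_0+screen_2",
            "screen_1+screen_2", "screen_0+screen_1+screen_2"}

    def test_gene_absent_from_one_screen_excluded(self, small_screens_cfg):
        screens, _ = harmonized_screens(small_screens_cfg)
        dropped = screens["screen_0"].index[0]
        screens["screen_0"] = screens["screen_0"].drop(index=dropped)
        res = meta.run_meta(screens, combinations=[("screen_0", "screen_1")])
        assert dropped not in res["screen_0+screen_1"].index
        assert len(res["screen_0+screen_1"]) == small_screens_cfg.n_genes - 1

    def test_fdr_never_below_p(self, small_screens_cfg):
        screens, _ = harmonized_screens(small_screens_cfg)
        res = meta.run_meta(screens)
        for df in res.values():
            assert (df["fdr_meta"] >= df["p_meta"] - 1e-15).all()

    def test_i2_invariant(self, small_screens_cfg):
        screens, _ = harmonized_screens(small_screens_cfg)
        df = meta.run_meta(screens)["screen_0+screen_1+screen_2"]
        q, qdf = df["q_stat"].to_numpy(), df["q_df"].to_numpy()
        expected = np.where(q > 0, np.maximum(0, (q - qdf) / q), 0)
        np.testing.assert_allclose(df["i2"].to_numpy(), expected)
        assert (df["q_stat"] >= 0).all()


class TestNovelty:
    def test_rule_applied_as_stated(self):
        m = pd.DataFrame({"fdr_meta": [0.01, 0.01]}, index=["a", "b"])
        fdrs = {"s1": pd.Series([0.2, 0.01], index=["a", "b"]),
                "s2": pd.Series([0.3, 0.3], index=["a", "b"])}
        flags = meta.assess_novelty(m, fdrs, alpha=0.05)
        assert flags["a"]            # not significant in any constituent
        assert not flags["b"]        # significant in s1 → not novel

    def test_vectorized_equals_brute_force_on_toy_set(self, rng):
        genes = [f"g{i}" for i in range(50)]
        m = pd.DataFrame({"fdr_meta": rng.uniform(size=50)}, index=genes)
        fdrs = {s: pd.Series(rng.uniform(size=50), index=genes)
                for s in ("s1", "s2", "s3")}
        flags = meta.assess_novelty(m, fdrs, alpha=0.05)
        for g in genes:
            expected = all(fdrs[s][g] >= 0.05 for s in fdrs) and m.loc[g, "fdr_meta"] < 0.05
            assert flags[g] == expected


class TestClassifyHits:
    def make_meta(self, deltas, novel):
        return pd.DataFrame({
            "beta_pooled": deltas, "is_novel": novel,
        }, index=[f"g{i}" for i in range(len(deltas))])

    def test_directionality_rule(self):
        m = self.make_meta([1.5, 0.5, -1.0, 3.0], [True, True, True, False])
        d = meta.classify_hits(m, population_reference=0.0, lfc_threshold=1.0)
        assert list(d) == ["up", "none", "down", "none"]

    def test_boundary_inclusive_both_directions(self):
        m = self.make_meta([1.0, -1.0], [True, True])
        d = meta.classify_hits(m, population_reference=0.0, lfc_threshold=1.0)
        assert list(d) == ["up", "down"]

    def test_default_reference_is_population_mean(self):
        m = self.make_meta([10.0, 11.5, 8.5], [True, True, True])
        # mean is 10; deltas are 0, +1.5, -1.5
        d = meta.classify_hits(m, lfc_threshold=1.0)
        assert list(d) == ["none", "up", "down"]
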