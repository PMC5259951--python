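"""Probe ratios, moderated testing, BH correction and classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import polygamma

from xscnd.calling import (
    CNDCaller,
    bh_adjust,
    call_cnd,
    classify,
    fit_variance_prior,
    intersect_species,
    probe_log2_ratios,
    trigamma_inverse,
)
from xscnd.calling import test_probesets as run_probeset_tests  # alias: keep pytest from collecting it
from xscnd.datamodel import CNE, CNR, NEUTRAL, ValidationError

from conftest import make_matrix


def _ratio_table(per_gene: dict[str, np.ndarray], n_probes: int, n_reps: int = 2):
    """Build a tidy ratio table from per-gene (probes x reps) arrays."""
    rows = []
    for gene, arr in per_gene.items():
        arr = np.asarray(arr, dtype=float).reshape(n_probes, n_reps)
        for p in range(n_probes):
            for r in range(n_reps):
                rows.append((gene, p + 1, r + 1, arr[p, r]))
    return pd.DataFrame(rows, columns=["probeset_id", "probe_index", "replicate", "log2_ratio"])


class TestProbeRatios:
    def _pair(self, h, x):
        probes = [("psA", 1), ("psA", 2), ("psB", 1)]
        home = make_matrix(
            {"h1": h, "h2": h}, [("h1", "home", 1), ("h2", "home", 2)], probes
        )
        het = make_matrix(
            {"x1": x, "x2": x}, [("x1", "het", 1), ("x2", "het", 2)], probes
        )
        return home, het

    def test_equal_matrices_give_zero_ratios(self):
        home, het = self._pair([10, 20, 30], [10, 20, 30])
        out = probe_log2_ratios(home, het)
        np.testing.assert_allclose(out["log2_ratio"], 0.0)
        assert len(out) == 6  # 3 probes x 2 replicate pairings

    def test_fourfold_signal_gives_ratio_two(self):
        home, het = self._pair([10, 20, 30], [40, 80, 120])
        out = probe_log2_ratios(home, het)
        np.testing.assert_allclose(out["log2_ratio"], 2.0)

    def test_matches_elementwise_log_oracle(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(10, 100, 3)
        x = rng.uniform(10, 100, 3)
        home, het = self._pair(list(h), list(x))
        out = probe_log2_ratios(home, het)
        oracle = np.log2(x / h)
        for rep in (1, 2):
            got = out[out["replicate"] == rep].sort_values("probe_index")
            sub = got[got["probeset_id"] == "psA"]["log2_ratio"].to_numpy()
            np.testing.assert_allclose(sub, oracle[:2], rtol=1e-12)

    def test_mismatched_probe_universe_rejected(self):
        home, het = self._pair([10, 20, 30], [10, 20, 30])
        het.values = het.values.iloc[:2]
        het.mask = het.mask.iloc[:2]
        with pytest.raises(ValidationError, match="universe"):
            probe_log2_ratios(home, het)


class TestModeratedTest:
    def test_all_zero_ratios_give_null_result(self):
        table = _ratio_table({f"g{i}": np.zeros(22) for i in range(5)}, 11)
        tested = run_probeset_tests(table)
        np.testing.assert_allclose(tested["log2_fc"], 0.0)
        np.testing.assert_allclose(tested["p_raw"], 1.0)

    def test_strong_consistent_shift_is_significant(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": rng.normal(0, 0.2, 22) for i in range(40)}
        genes["hit"] = 1.0 + rng.normal(0, 0.01, 22)
        tested = run_probeset_tests(_ratio_table(genes, 11)).set_index("probeset_id")
        assert tested.loc["hit", "log2_fc"] == pytest.approx(1.0, abs=0.02)
        assert tested.loc["hit", "p_raw"] < 1e-8

    def test_too_few_probes_reported_as_na(self):
        table = pd.concat(
            [
                _ratio_table({"ok": np.random.default_rng(1).normal(0, 0.2, 22)}, 11),
                _ratio_table({"tiny": [0.1, 0.2, 0.3, 0.4]}, 2),
            ]
        )
        tested = run_probeset_tests(table).set_index("probeset_id")
        assert np.isnan(tested.loc["tiny", "p_raw"])
        assert np.isfinite(tested.loc["ok", "p_raw"])

    def test_unmoderated_test_matches_ols_with_probe_blocks(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(0.3, 0.25, 22)
        table = _ratio_table({"g0": arr}, 11)
        tested = run_probeset_tests(table, moderate=False).set_index("probeset_id")
        # independent route: OLS with probe as a categorical blocking factor
        df = table.copy()
        df["probe"] = df["probe_index"].astype(str)
        fit = smf.ols("log2_ratio ~ C(probe)", data=df).fit()
        grand_mean = df["log2_ratio"].mean()
        s2 = fit.mse_resid
        se = np.sqrt(s2 / len(df))
        t_oracle = grand_mean / se
        p_oracle = 2 * stats.t.sf(abs(t_oracle), fit.df_resid)
        assert tested.loc["g0", "t"] == pytest.approx(t_oracle, rel=1e-9)
        assert tested.loc["g0", "p_raw"] == pytest.approx(p_oracle, rel=1e-9)

    def test_null_pvalues_are_roughly_uniform(self):
        rng = np.random.default_rng(12)
        genes = {f"g{i}": rng.normal(0, 0.25, 22) for i in range(600)}
        tested = run_probeset_tests(_ratio_table(genes, 11))
        ks = stats.kstest(tested["p_raw"], "uniform")
        assert ks.pvalue > 0.005


class TestVariancePrior:
    def test_trigamma_inverse_inverts_trigamma(self):
        for x in (0.2, 1.0, 5.0, 40.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_prior_recovered_from_simulated_variances(self):
        rng = np.random.default_rng(21)
        d, d0, s0_sq = 11, 8.0, 0.05
        sigma2 = s0_sq * d0 / rng.chisquare(d0, size=20000)
        s2 = sigma2 * rng.chisquare(d, size=20000) / d
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)

    def test_homogeneous_variances_give_large_d0(self):
        rng = np.random.default_rng(22)
        s2 = 0.05 * rng.chisquare(11, size=5000) / 11
        d0_hat, s0_hat = fit_variance_prior(s2, 11)
        assert d0_hat > 100
        assert s0_hat == pytest.approx(0.05, rel=0.1)


class TestBenjaminiHochberg:
    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    def test_matches_step_up_oracle(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        # textbook step-up: sort, scale by m/i, cumulative min from the right
        m = len(p)
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, oracle, rtol=1e-12)

    def test_four_ladder_pvalues_all_adjust_to_the_top(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


class TestClassification:
    def test_strong_expansion_is_cne(self):
        # fold-change / adjusted-p pattern of a doubled gene family member
        assert classify(1.69, 0.00) == CNE

    def test_just_below_threshold_is_neutral(self):
        assert classify(0.99, 0.001) == NEUTRAL

    def test_threshold_boundary_is_inclusive(self):
        assert classify(1.0, 0.1) == CNE
        assert classify(-1.0, 0.1) == CNR

    def test_call_cnd_excludes_uncallable_genes_from_bh(self):
        tested = pd.DataFrame(
            {
                "probeset_id": ["a", "b", "c"],
                "log2_fc": [1.5, -1.5, 0.2],
                "p_raw": [0.01, np.nan, 0.04],
            }
        )
        calls = call_cnd(tested).set_index("probeset_id")
        assert calls.loc["a", "cnd_class"] == CNE
        assert calls.loc["b", "cnd_class"] is None
        # BH over the two callable genes only: 0.01*2/1 = 0.02, 0.04*2/2 = 0.04
        assert calls.loc["a", "p_adj"] == pytest.approx(0.02)
        assert calls.loc["c", "p_adj"] == pytest.approx(0.04)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            call_cnd(pd.DataFrame(columns=["probeset_id", "log2_fc", "p_raw"]))

    def test_classes_are_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(31)
        tested = pd.DataFrame(
            {
                "probeset_id": [f"g{i}" for i in range(300)],
                "log2_fc": rng.normal(0, 1.2, 300),
                "p_raw": rng.uniform(0, 1, 300) ** 3,
            }
        )
        calls = call_cnd(tested)
        assert set(calls["cnd_class"]) <= {CNE, CNR, NEUTRAL}
        assert calls["cnd_class"].notna().all()


class TestIntersection:
    def _calls(self, mapping):
        return pd.DataFrame(
            {"probeset_id": list(mapping), "cnd_class": list(mapping.values())}
        )

    def test_identical_sets_intersect_to_themselves(self):
        calls = self._calls({"a": CNE, "b": CNR, "c": NEUTRAL})
        cne, cnr = intersect_species(calls, calls)
        assert cne == {"a"} and cnr == {"b"}

    def test_disjoint_sets_are_empty(self):
        a = self._calls({"a": CNE, "b": NEUTRAL})
        b = self._calls({"a": NEUTRAL, "b": CNE})
        cne, cnr = intersect_species(a, b)
        assert cne == set() and cnr == set()

    def test_random_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(7)
        ids = [f"g{i}" for i in range(200)]
        cls_a = rng.choice([CNE, CNR, NEUTRAL], 200)
        cls_b = rng.choice([CNE, CNR, NEUTRAL], 200)
        a = pd.DataFrame({"probeset_id": ids, "cnd_class": cls_a})
        b = pd.DataFrame({"probeset_id": ids, "cnd_class": cls_b})
        cne, cnr = intersect_species(a, b)
        oracle_cne = {i for i, x, y in zip(ids, cls_a, cls_b) if x == y == CNE}
        oracle_cnr = {i for i, x, y in zip(ids, cls_a, cls_b) if x == y == CNR}
        assert cne == oracle_cne and cnr == oracle_cnr


class TestCallerEstimator:
    def test_fit_predict_round_trip(self):
        rng = np.random.default_rng(41)
        genes = {f"g{i}": rng.normal(0, 0.2, 22) for i in range(30)}
        genes["up"] = 1.6 + rng.normal(0, 0.05, 22)
        caller = CNDCaller()
        pred = caller.fit_predict(_ratio_table(genes, 11))
        assert pred.loc["up"] == CNE
        assert caller.d0_ > 0 and caller.s0_sq_ > 0
        assert set(caller.results_.columns) >= {
            "probeset_id", "log2_fc", "p_raw", "p_adj", "cnd_class"
        }

    def test_get_params_supports_grid_style_cloning(self):
        caller = CNDCaller(alpha=0.05)
        params = caller.get_params()
        assert params["alpha"] == 0.05
        caller.set_params(up=0.5)
        assert caller.up == 0.5
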