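import dataclasses
import warnings

import numpy as np
import pytest

from transferpep import (PSMTable, SimulationConfig, build_oracle,
                         estimate_group_pep_combined,
                         estimate_group_pep_separate,
                         estimate_group_pep_transfer, fit_group_alternative,
                         pep_to_fdr, sample_derived_null, simulate_dataset)
from transferpep.exceptions import EstimationError, InsufficientDataError


class TestPepToFdr:
    def test_constant_pep_gives_constant_fdr(self):
        out = pep_to_fdr([0.2] * 5, [5, 4, 3, 2, 1])
        assert np.allclose(out, 0.2)

    def test_running_means(self):
        out = pep_to_fdr([0.1, 0.5, 0.9], [10, 5, 1])
        assert np.allclose(out, [0.1, 0.3, 0.5])

    def test_order_invariance(self, rng):
        peps = rng.random(50)
        scores = rng.normal(size=50)
        base = pep_to_fdr(peps, scores)
        perm = rng.permutation(50)
        assert np.allclose(pep_to_fdr(peps[perm], scores[perm])[np.argsort(perm)],
                           base[np.argsort(np.arange(50))])

    def test_empty(self):
        assert pep_to_fdr([], []).size == 0


def _whole_group(table: PSMTable) -> PSMTable:
    df = table.df.copy()
    df["in_group"] = True
    return PSMTable(df)


class TestCombinedAndSeparate:
    def test_separate_equals_combined_when_group_is_everything(self):
        cfg = SimulationConfig(n_total=3000, n_group_correct=5)
        ds = simulate_dataset(cfg, seed=21)
        table = _whole_group(ds.table)
        a = estimate_group_pep_combined(table)
        b = estimate_group_pep_separate(table)
        assert np.array_equal(a.df["pep"].to_numpy(), b.df["pep"].to_numpy())

    def test_separate_needs_enough_group_data(self, rng):
        n = 200
        table = PSMTable.from_arrays(
            [f"p{i}" for i in range(n)], rng.normal(size=n),
            ["target"] * 100 + ["decoy"] * 100,
            [True] * 10 + [False] * 90 + [True] * 5 + [False] * 95)
        with pytest.raises(InsufficientDataError, match="transfer"):
            estimate_group_pep_separate(table)

    def test_no_group_targets_returns_empty_with_warning(self, rng):
        n = 200
        table = PSMTable.from_arrays(
            [f"p{i}" for i in range(n)], rng.normal(size=n),
            ["target"] * 100 + ["decoy"] * 100, [False] * n)
        with pytest.warns(RuntimeWarning, match="no group target"):
            res = estimate_group_pep_combined(table)
        assert len(res.df) == 0

    def test_peps_and_ifdr_in_unit_interval(self, default_dataset):
        res = estimate_group_pep_combined(default_dataset.table)
        assert res.df["pep"].between(0, 1).all()
        assert res.df["ifdr"].between(0, 1).all()
        # the tail mean can never exceed the running max of pep
        assert (res.df["ifdr"] <= np.maximum.accumulate(
            res.df["pep"].to_numpy()) + 1e-12).all()


class TestFitGroupAlternative:
    def test_recovers_small_alternative_fraction(self, default_config):
        """3900 null scores from the derived f_G0 plus 100 correct scores:
        the EM run against the exact weighted null recovers pi_G1 = 0.025."""
        oracle = build_oracle(default_config)
        rng = np.random.default_rng(42)
        nulls = sample_derived_null(3900, "G", oracle, rng)
        alts = rng.normal(9.0, np.sqrt(6.0), 100)
        scores = np.concatenate([nulls, alts])
        wn = lambda x: (3900 / 4000) * oracle.f_g0(x)
        gm = fit_group_alternative(scores, wn)
        assert gm.converged
        assert gm.pi_g1 == pytest.approx(100 / 4000, abs=0.01)

    def test_all_null_group_collapses(self, default_config):
        oracle = build_oracle(default_config)
        rng = np.random.default_rng(7)
        scores = sample_derived_null(2000, "G", oracle, rng)
        wn = lambda x: oracle.f_g0(x)    # pi_G0 = 1
        gm = fit_group_alternative(scores, wn)
        assert gm.pi_g1 <= 0.01

    def test_single_target_above_null_support(self, default_config):
        oracle = build_oracle(default_config)
        gm = fit_group_alternative(np.array([55.0]),
                                   lambda x: oracle.weighted_null(x))
        assert gm.theta_g[0] == pytest.approx(1.0, abs=1e-6)


class TestTransfer:
    def test_whole_table_group_reduces_to_combined(self):
        """With G = all PSMs, gamma == 1 and lambda == 1 are exactly
        constant, so the transfer estimator reduces to the combined one
        (run at a tight tolerance to reach the joint EM fixed point).

        Agreement is to ~1e-4, not machine precision: the combined EM
        evaluates its kernel alternative leave-one-out while the reduced
        pi-only EM uses the fitted density verbatim, shifting the fixed
        point by O(K_h(0)/n)."""
        cfg = SimulationConfig(n_total=3000, n_group_correct=5)
        ds = simulate_dataset(cfg, seed=13)
        table = _whole_group(ds.table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = estimate_group_pep_combined(table, max_iter=3000, tol=1e-10)
            b = estimate_group_pep_transfer(table, max_iter=3000, tol=1e-10)
        d = b.model_diagnostics.diagnostics
        assert d["mode"] == ("equal", "equal")
        pa = a.df.set_index("psm_id")["pep"]
        pb = b.df.set_index("psm_id")["pep"]
        assert np.max(np.abs(pa - pb.loc[pa.index])) < 1e-3

    def test_forced_transfer_mode_recovers_pi_g0(self, default_dataset):
        """In forced (f_G0 != f0, f_G1 = f1) mode the transfer-null
        integral recovers pi_G0 = b*pi0/pi_G (2-sigma MC tolerance)."""
        res = estimate_group_pep_transfer(default_dataset.table,
                                          force_null="transfer",
                                          force_alt="equal")
        d = res.model_diagnostics.diagnostics
        expected = 0.4 * 0.65 / d["pi_g"]
        assert d["pi_g0_transfer_integral"] == pytest.approx(expected,
                                                             abs=0.05)

    def test_transfer_mode_dispatch_recorded(self, default_dataset):
        res = estimate_group_pep_transfer(default_dataset.table,
                                          force_null="transfer",
                                          force_alt="separate")
        d = res.model_diagnostics.diagnostics
        assert d["mode"] == ("transfer", "separate")
        assert d["gamma_slope"] < 0
        assert res.df["pep"].between(0, 1).all()

    def test_transfer_without_group_decoys_conflicts(self, rng):
        n = 400
        table = PSMTable.from_arrays(
            [f"p{i}" for i in range(n)], rng.normal(size=n),
            ["target"] * 200 + ["decoy"] * 200,
            [True] * 20 + [False] * 180 + [False] * 200)
        with pytest.raises(EstimationError):
            estimate_group_pep_transfer(table, force_null="transfer")

    def test_transfer_needs_a_group_target(self, rng):
        n = 400
        table = PSMTable.from_arrays(
            [f"p{i}" for i in range(n)], rng.normal(size=n),
            ["target"] * 200 + ["decoy"] * 200,
            [False] * 200 + [True] * 20 + [False] * 180)
        with pytest.raises(InsufficientDataError):
            estimate_group_pep_transfer(table)

    def test_separate_and_transfer_agree_for_large_groups(self):
        """With many group-correct scores both estimators converge to the
        theoretical PEP; their top-1% MSEs agree within a factor of 2."""
        from transferpep import mse_by_ratio
        cfg = SimulationConfig(n_group_correct=500)
        mses = {"separate": [], "transfer": []}
        for seed in (101, 102, 103):
            ds = simulate_dataset(cfg, seed=seed)
            g = ds.table.group_target_scores
            theo = ds.oracle.pep_g(g)
            for name, fn in [
                    ("separate", estimate_group_pep_separate),
                    ("transfer", lambda t: estimate_group_pep_transfer(
                        t, force_null="transfer", force_alt="separate"))]:
                res = fn(ds.table)
                est = res.df.set_index("psm_id") \
                    .loc[ds.table.group_target_ids, "pep"].to_numpy(float)
                mses[name].append(mse_by_ratio(est, theo, g)[0.01])
        a, b = np.mean(mses["separate"]), np.mean(mses["transfer"])
        assert max(a, b) / min(a, b) < 2.0
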