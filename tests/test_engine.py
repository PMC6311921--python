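"""Permutation engine against the loop-based oracle, plus structural
reductions and counting-rule contracts."""

import numpy as np
import pytest
from scipy import stats

from pcombine import (
    NullEnsemble,
    PartitionScheme,
    permuted_pvalues,
    run_all,
    run_artp,
    run_fct,
    run_gcp,
    run_rpcmp,
    run_tpm,
)
from pcombine.combiners import DEFAULT_PARTITIONS
from pcombine.engine import results_table

from _naive import (
    naive_artp_run,
    naive_fct_run,
    naive_gcp_run,
    naive_rpcmp_run,
    naive_tpm_run,
)


def _rankings(values):
    return np.argsort(np.argsort(values))


class TestOracleEquivalence:
    """The vectorized engine must reproduce the literal loop-based
    implementation of every statistic and adjusted p-value."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fct(self, seed):
        pmat = np.random.default_rng(seed).uniform(1e-4, 1, (16, 8))
        ens = NullEnsemble(pmat, B=15)
        res = run_fct(ens)
        phi, p_adj = naive_fct_run(pmat.tolist())
        assert res.statistic == pytest.approx(phi[0], rel=1e-12)
        assert res.p_adjusted == p_adj

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tpm(self, seed):
        pmat = np.random.default_rng(seed).uniform(1e-4, 1, (16, 8))
        ens = NullEnsemble(pmat, B=15)
        res = run_tpm(ens, xi=0.5)
        lw, p_adj = naive_tpm_run(pmat.tolist(), 0.5)
        assert np.log(res.statistic) == pytest.approx(lw[0], rel=1e-10)
        assert res.p_adjusted == p_adj

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_artp(self, seed):
        pmat = np.random.default_rng(seed).uniform(1e-4, 1, (21, 10))
        ens = NullEnsemble(pmat, B=20)
        Ks = (1, 2, 3, 5)
        res = run_artp(ens, Ks=Ks)
        minp, p_adj = naive_artp_run(pmat.tolist(), Ks)
        assert res.statistic == pytest.approx(minp[0], rel=1e-12)
        assert res.p_adjusted == p_adj

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gcp(self, seed):
        pmat = np.random.default_rng(seed).uniform(1e-4, 1, (11, 10))
        ens = NullEnsemble(pmat, B=10)
        res = run_gcp(ens, cutoffs=(0.001, 0.05))
        vals, p_adj = naive_gcp_run(pmat.tolist(), (0.001, 0.05))
        assert res.statistic == pytest.approx(vals[0], rel=1e-12)
        assert res.p_adjusted == p_adj

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("include_observed", [False, True])
    def test_rpcmp_all_layers(self, seed, include_observed):
        pmat = np.random.default_rng(seed).uniform(1e-4, 1, (21, 10))
        ens = NullEnsemble(pmat, B=20)
        scheme = PartitionScheme(DEFAULT_PARTITIONS)
        res, diag = run_rpcmp(
            ens, scheme, cdf_include_observed=include_observed
        )
        all_S, gcp, rp, p_adj = naive_rpcmp_run(
            pmat.tolist(), DEFAULT_PARTITIONS, include_observed
        )
        for l in range(len(DEFAULT_PARTITIONS)):
            np.testing.assert_allclose(
                diag.group_sums[l], np.asarray(all_S[l]), rtol=1e-10, atol=1e-12
            )
        np.testing.assert_allclose(diag.gcp, np.asarray(gcp), rtol=1e-10)
        np.testing.assert_allclose(diag.rpcmp, np.asarray(rp), rtol=1e-10)
        assert res.statistic == pytest.approx(rp[0], rel=1e-10)
        assert res.p_adjusted == p_adj


class TestCountingRules:
    def test_most_extreme_gets_min_p(self, rng):
        # fct/tpm/artp: an observed row smaller than every null entry is the
        # most extreme row under each statistic's own direction
        pmat = rng.uniform(0.3, 1.0, (26, 5))
        pmat[0] = 1e-4
        ens = NullEnsemble(pmat, B=25)
        for method in ("fct", "tpm", "artp"):
            res = run_all(ens, methods=(method,))[method]
            assert res.p_adjusted == pytest.approx(1 / 26), method

    def test_counting_rule_identity_rank_based(self, rng):
        # gcp/rpcmp adjusted p-values follow the documented
        # (1 + #at-least-as-extreme)/(B+1) rule in each statistic's direction
        pmat = np.clip(rng.uniform(size=(26, 40)), 1e-6, 1.0)
        pmat[0, :12] = 5e-4  # push some observed mass into the low groups
        ens = NullEnsemble(pmat, B=25)
        gcp = run_gcp(ens)
        nulls = np.asarray(gcp.null_statistics)
        assert gcp.p_adjusted == pytest.approx(
            (1 + np.count_nonzero(nulls <= gcp.statistic)) / 26
        )
        rp, _ = run_rpcmp(ens)
        nulls = np.asarray(rp.null_statistics)
        assert rp.p_adjusted == pytest.approx(
            (1 + np.count_nonzero(nulls >= rp.statistic)) / 26
        )

    def test_duplicated_observed_row_ties(self, rng):
        pmat = rng.uniform(1e-3, 1.0, (26, 5))
        pmat[0] = pmat[3]  # observed duplicates a permutation row
        ens = NullEnsemble(pmat, B=25)
        for res in run_all(ens).values():
            assert res.p_adjusted >= 2 / 26

    def test_p_adjusted_bounds(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (26, 7))
        ens = NullEnsemble(pmat, B=25)
        for res in run_all(ens).values():
            assert 1 / 26 <= res.p_adjusted <= 1.0

    def test_degenerate_ensemble_warns_and_returns_one(self):
        pmat = np.tile(np.linspace(0.2, 0.8, 5), (11, 1))
        ens = NullEnsemble(pmat, B=10)
        with pytest.warns(UserWarning, match="degenerate"):
            assert run_fct(ens).p_adjusted == 1.0

    def test_null_row_order_invariance(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (31, 6))
        shuffled = pmat.copy()
        shuffled[1:] = shuffled[1:][rng.permutation(30)]
        for run in (run_fct, run_tpm, lambda e: run_rpcmp(e)[0]):
            a = run(NullEnsemble(pmat, B=30))
            b = run(NullEnsemble(shuffled, B=30))
            assert a.p_adjusted == b.p_adjusted
            assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_min_B_floor(self, rng):
        ens = NullEnsemble(rng.uniform(0.1, 1, (11, 4)), B=10)
        with pytest.raises(ValueError, match="floor"):
            run_rpcmp(ens)


class TestStructuralReductions:
    def test_single_group_gcp_ranks_like_fisher(self, rng):
        # one interval covering (0,1]: GCP is a monotone transform of Phi
        pmat = rng.uniform(1e-4, 1.0, (41, 9))
        ens = NullEnsemble(pmat, B=40)
        gcp = run_gcp(ens, cutoffs=(0.9999999,))
        phi = -2 * np.log(pmat).sum(axis=1)
        np.testing.assert_array_equal(
            _rankings(-np.asarray(gcp.null_statistics)), _rankings(phi[1:])
        )
        # the rank-based GCP can tie the observed value with one null row
        # whose count coincides, adding at most one extra "extreme" count
        diff = gcp.p_adjusted - run_fct(ens).p_adjusted
        assert 0.0 <= diff <= 1 / 41 + 1e-12

    def test_artp_k1_is_minp_test(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (31, 8))
        ens = NullEnsemble(pmat, B=30)
        res = run_artp(ens, Ks=(1,))
        # statistic reduces to the empirical p of the smallest p-value
        mins = pmat.min(axis=1)
        s0 = np.count_nonzero(mins[1:] <= mins[0]) / 31
        assert res.statistic == pytest.approx(s0)

    def test_artp_full_K_ranks_like_fisher(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (31, 8))
        ens = NullEnsemble(pmat, B=30)
        res = run_artp(ens, Ks=(8,))
        phi = -2 * np.log(pmat).sum(axis=1)
        # product of all p-values is monotone in Phi, so rejection matches FCT
        assert res.p_adjusted == run_fct(ens).p_adjusted

    def test_single_partition_rpcmp_ranks_opposite_gcp(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (41, 9))
        ens = NullEnsemble(pmat, B=40)
        res, diag = run_rpcmp(ens, PartitionScheme(((0.001, 0.05),)))
        gcp = run_gcp(ens, cutoffs=(0.001, 0.05))
        # 1 - G(GCP) is a non-increasing transform of GCP
        order = np.argsort(diag.gcp[:, 0])
        assert np.all(np.diff(diag.rpcmp[order]) <= 1e-12)
        assert res.p_adjusted == gcp.p_adjusted


class TestRunAll:
    def test_shared_ensemble_and_table(self, small_dataset):
        X, ph = small_dataset
        ens = permuted_pvalues(X, ph, B=60, seed=9)
        results = run_all(ens)
        table = results_table(results, set_id="demo", seed=9)
        assert set(table["method"]) == {"fct", "tpm", "artp", "gcp", "rpcmp"}
        assert table.shape[0] == 5
        assert ((table["p_adjusted"] >= 1 / 61) & (table["p_adjusted"] <= 1)).all()

    def test_unknown_method_rejected(self, toy_ensemble):
        with pytest.raises(ValueError, match="unknown method"):
            run_all(toy_ensemble, methods=("fct", "nope"))

    def test_diagnostics_frames_shapes(self, rng):
        pmat = rng.uniform(1e-4, 1.0, (26, 12))
        _, diag = run_rpcmp(NullEnsemble(pmat, B=25), PartitionScheme(DEFAULT_PARTITIONS))
        frames = diag.frames()
        assert frames["rpcmp"].shape[0] == 26
        assert frames["gcp"]["partition"].nunique() == 5
        n_groups = sum(len(c) + 1 for c in DEFAULT_PARTITIONS)
        assert frames["group_sums"].shape[0] == 26 * n_groups


class TestNullUniformity:
    def test_adjusted_p_uniform_under_null(self, rng):
        # global null: each method's adjusted p is approximately uniform
        reps = 300
        counts = {m: [] for m in ("fct", "tpm", "artp", "gcp", "rpcmp")}
        for r in range(reps):
            pmat = rng.uniform(size=(41, 12))
            ens = NullEnsemble(np.clip(pmat, 1e-12, 1.0), B=40)
            for m, res in run_all(ens).items():
                counts[m].append(res.p_adjusted)
        for m, ps in counts.items():
            rate = np.mean(np.asarray(ps) < 0.25)
            se = np.sqrt(0.25 * 0.75 / reps)
            assert abs(rate - 0.25) < 4 * se, (m, rate)
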