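import numpy as np
import pandas as pd
import pytest

import diatomcal as dc
from diatomcal.data_model import DataError
from diatomcal.synthetic import ION_BLOCK

from conftest import random_community


def brute_force_rda(Y, X, Z=None):
    """Independent RDA oracle: explicit projection matrices + dense eigh."""
    n = Y.shape[0]
    one = np.ones((n, 1))

    def proj(M):
        return M @ np.linalg.pinv(M.T @ M) @ M.T

    Yc = Y - Y.mean(axis=0)
    if Z is not None:
        Pz = proj(np.hstack([one, Z]))
        Yc = Yc - Pz @ Yc
        X = X - Pz @ X
    Xc = X - X.mean(axis=0)
    fitted = proj(Xc) @ Yc
    resid = Yc - fitted
    lam_c = np.sort(np.linalg.eigvalsh(fitted.T @ fitted))[::-1] / (n - 1)
    lam_u = np.sort(np.linalg.eigvalsh(resid.T @ resid))[::-1] / (n - 1)
    return np.clip(lam_c, 0, None), np.clip(lam_u, 0, None)


def _wrap(Y, env_cols, sites=None):
    n = Y.shape[0]
    sites = sites or [f"s{i}" for i in range(n)]
    sp = dc.AbundanceMatrix(
        pd.DataFrame(Y, index=sites, columns=[f"t{j}" for j in range(Y.shape[1])]),
        "hellinger",
    )
    ev = dc.EnvTable(pd.DataFrame(env_cols, index=sites))
    return sp, ev


class TestCorrelationGroups:
    def test_duplicated_variable_forms_one_group(self, rng):
        x = rng.normal(size=20)
        env = dc.EnvTable(pd.DataFrame({"x": x, "y": x.copy(), "z": rng.normal(size=20)}))
        groups = dc.correlation_groups(env)
        assert ["x", "y"] in [sorted(g) for g in groups.groups]

    def test_independent_columns_stay_singletons(self):
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            env = dc.EnvTable(pd.DataFrame(r.normal(size=(35, 5)), columns=list("abcde")))
            g = dc.correlation_groups(env)
            hits += all(len(grp) == 1 for grp in g.groups)
        assert hits >= 190

    def test_recovers_generated_ion_block(self):
        env, _ = dc.simulate_env(dc.SimConfig(seed=4, env_block_r=0.9))
        groups = dc.correlation_groups(env)
        big = max(groups.groups, key=len)
        assert set(ION_BLOCK) <= set(big)

    def test_constant_column_excluded(self, rng):
        env = dc.EnvTable(pd.DataFrame({"a": rng.normal(size=10), "c": np.ones(10)}))
        groups = dc.correlation_groups(env)
        assert groups.excluded == ["c"]


class TestGradientLength:
    @staticmethod
    def _gaussian_community(span, tol, n=30, m=40, seed=0):
        r = np.random.default_rng(seed)
        x = np.linspace(0, span, n)
        opt = np.linspace(-0.5 * tol, span + 0.5 * tol, m)
        mu = np.exp(-((x[:, None] - opt[None, :]) ** 2) / (2 * tol**2))
        p = mu / mu.sum(axis=1, keepdims=True)
        Y = np.vstack([r.multinomial(500, p[i]) for i in range(n)])
        Y = Y[:, Y.sum(axis=0) > 0]
        rel = Y / Y.sum(axis=1, keepdims=True)
        return dc.hellinger(
            dc.AbundanceMatrix(pd.DataFrame(rel, columns=[f"t{j}" for j in range(Y.shape[1])]), "none")
        )

    def test_no_turnover_gives_zero_length(self):
        row = np.array([[0.5, 0.3, 0.2]])
        sp = dc.AbundanceMatrix(pd.DataFrame(np.repeat(row, 6, axis=0), columns=list("abc")), "none")
        length, rec = dc.dca_gradient_length(sp)
        assert length == 0.0 and rec == "RDA"

    def test_short_gradient_recommends_linear_method(self):
        length, rec = dc.dca_gradient_length(self._gaussian_community(span=0.5, tol=1.0))
        assert length < 2 and rec == "RDA"

    def test_full_turnover_exceeds_two_sd(self):
        length, rec = dc.dca_gradient_length(self._gaussian_community(span=4.0, tol=1.0))
        assert length > 2 and rec == "CCA"


class TestRdaFit:
    def test_orthogonal_constraint_explains_nothing(self, rng):
        Y = rng.uniform(size=(10, 4))
        Yc = Y - Y.mean(axis=0)
        v = rng.normal(size=10)
        basis = np.hstack([np.ones((10, 1)), Yc])
        v = v - basis @ np.linalg.lstsq(basis, v, rcond=None)[0]
        sp, ev = _wrap(Y, {"v": v})
        res = dc.rda_fit(sp, ev, ["v"])
        assert res.constrained_variance < 1e-10

    def test_saturated_constraints_leave_no_residual(self, rng):
        n = 6
        Y = rng.uniform(size=(n, 4))
        env = {f"v{j}": rng.normal(size=n) for j in range(n - 1)}
        sp, ev = _wrap(Y, env)
        res = dc.rda_fit(sp, ev, list(env))
        assert res.residual_variance < 1e-10

    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, m, q = 8, 5, 2
            Y = r.uniform(size=(n, m))
            X = r.normal(size=(n, q))
            Z = r.normal(size=(n, 1))
            sp, ev = _wrap(Y, {"a": X[:, 0], "b": X[:, 1], "z": Z[:, 0]})
            res = dc.rda_fit(sp, ev, ["a", "b"], ["z"])
            lam_c, lam_u = brute_force_rda(Y, X, Z)
            np.testing.assert_allclose(res.constrained_eigenvalues, lam_c[:2], atol=1e-8)
            np.testing.assert_allclose(
                res.unconstrained_eigenvalues, lam_u[: len(res.unconstrained_eigenvalues)], atol=1e-8
            )

    def test_total_variance_conserved(self, rng):
        Y = rng.uniform(size=(9, 5))
        sp, ev = _wrap(Y, {"a": rng.normal(size=9), "z": rng.normal(size=9)})
        res = dc.rda_fit(sp, ev, ["a"], ["z"])
        assert res.constrained_variance + res.residual_variance == pytest.approx(
            res.total_variance, abs=1e-8
        )

    def test_collinear_constraints_fatal(self, rng):
        x = rng.normal(size=8)
        sp, ev = _wrap(rng.uniform(size=(8, 3)), {"a": x, "b": 2 * x})
        with pytest.raises(DataError, match="collinear"):
            dc.rda_fit(sp, ev, ["a", "b"])


class TestPermutationTest:
    def test_p_floor_for_overwhelming_signal(self, rng):
        sp, x = random_community(rng, n=25, m=10)
        hel = dc.hellinger(sp)
        # constraint tied directly to the assemblage's own site scores
        score = hel.values.to_numpy() @ np.arange(10, dtype=float)
        ev = dc.EnvTable(pd.DataFrame({"v": score}, index=hel.sites))
        for seed in (0, 1, 2):
            _, p = dc.permutation_test(hel, ev, ["v"], n_perm=99, seed=seed)
            assert p == pytest.approx(0.01)

    def test_p_never_below_floor(self, rng):
        sp, x = random_community(rng)
        ev = dc.EnvTable(pd.DataFrame({"v": rng.normal(size=len(sp.sites))}, index=sp.sites))
        _, p = dc.permutation_test(sp, ev, ["v"], n_perm=19, seed=0)
        assert 1 / 20 <= p <= 1.0


class TestForwardSelect:
    def test_single_significant_candidate_selected(self, rng):
        sp, x = random_community(rng, n=30, m=12)
        hel = dc.hellinger(sp)
        ev = dc.EnvTable(pd.DataFrame({"grad": x}, index=sp.sites))
        rep = dc.forward_select(hel, ev, ["grad"], alpha=0.05, n_perm=99, seed=0)
        assert rep.selected == ["grad"]

    def test_alpha_one_selects_alpha_zero_rejects(self, rng):
        sp, x = random_community(rng, n=15, m=6)
        ev = dc.EnvTable(pd.DataFrame({"v": rng.normal(size=15)}, index=sp.sites))
        assert dc.forward_select(sp, ev, ["v"], alpha=1.0, n_perm=19, seed=0).selected == ["v"]
        assert dc.forward_select(sp, ev, ["v"], alpha=0.0, n_perm=19, seed=0).selected == []

    def test_pure_noise_candidates_mostly_rejected(self):
        empty = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            Y = r.dirichlet(np.ones(15) * 0.5, size=30)
            sp = dc.AbundanceMatrix(
                pd.DataFrame(np.sqrt(Y), index=[f"s{i}" for i in range(30)],
                             columns=[f"t{j}" for j in range(15)]), "hellinger")
            ev = dc.EnvTable(pd.DataFrame(r.normal(size=(30, 4)), index=sp.sites, columns=list("abcd")))
            rep = dc.forward_select(sp, ev, list("abcd"), alpha=0.01, n_perm=199, seed=seed)
            empty += len(rep.selected) == 0
        assert empty >= 18

    def test_redundant_pair_yields_single_selection(self):
        picked = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            sp, x = random_community(r, n=30, m=12)
            hel = dc.hellinger(sp)
            ev = dc.EnvTable(
                pd.DataFrame({"a": x, "b": x + 0.1 * r.normal(size=30)}, index=sp.sites)
            )
            rep = dc.forward_select(hel, ev, ["a", "b"], alpha=0.05, n_perm=99, seed=seed)
            picked.append(len(rep.selected))
        assert all(k == 1 for k in picked)


class TestIndependenceAndPartition:
    def test_duplicate_variables_are_dependent(self, rng):
        sp, x = random_community(rng, n=20, m=8)
        ev = dc.EnvTable(pd.DataFrame({"a": x, "b": x.copy()}, index=sp.sites))
        out = dc.independence_test(sp, ev, "a", "b", alpha=0.05, n_perm=49, seed=0)
        assert out["verdict"] == "dependent"
        assert out["retain"] == "a"  # equal marginals tie-break lexicographically

    def test_orthogonal_effects_are_independent(self):
        r = np.random.default_rng(1)
        n = 40
        a = np.repeat([0.0, 1.0], n // 2)
        b = np.tile([0.0, 1.0], n // 2)  # orthogonal to a by construction
        mu = np.stack([1 + 3 * a, 1 + 3 * b, np.ones(n), np.ones(n)], axis=1)
        Y = mu + 0.1 * r.normal(size=mu.shape)
        sp, ev = None, None
        sp = dc.AbundanceMatrix(
            pd.DataFrame(np.abs(Y), index=[f"s{i}" for i in range(n)], columns=list("wxyz")),
            "hellinger",
        )
        ev = dc.EnvTable(pd.DataFrame({"a": a, "b": b}, index=sp.sites))
        out = dc.independence_test(sp, ev, "a", "b", alpha=0.01, n_perm=199, seed=0)
        assert out["verdict"] == "independent"

    def test_single_variable_partition_reduces_to_rda(self, rng):
        sp, x = random_community(rng, n=15, m=6)
        ev = dc.EnvTable(pd.DataFrame({"v": x}, index=sp.sites))
        part = dc.variance_partition(sp, ev, ["v"], n_perm=19, seed=0)
        res = dc.rda_fit(sp, ev, ["v"])
        assert part["variance_pct"].iloc[0] == pytest.approx(
            100 * res.constrained_variance / res.grand_total_variance, abs=1e-8
        )

    def test_orthogonal_constraints_partition_additively(self, rng):
        n = 16
        Y = rng.uniform(size=(n, 5))
        a = np.repeat([0.0, 1.0], n // 2)
        b = np.tile([0.0, 1.0], n // 2)
        sp, ev = _wrap(Y, {"a": a, "b": b})
        part = dc.variance_partition(sp, ev, ["a", "b"], n_perm=19, seed=0)
        assert part["variance_pct"].sum() == pytest.approx(
            part.attrs["joint_constrained_pct"], abs=1e-8
        )

    def test_shared_variance_has_no_unique_share(self, rng):
        sp, x = random_community(rng, n=14, m=6)
        ev = dc.EnvTable(pd.DataFrame({"a": x, "b": x.copy()}, index=sp.sites))
        part = dc.variance_partition(sp, ev, ["a", "b"], n_perm=19, seed=0)
        # each variable's unique share vanishes; the joint share does not
        assert np.all(part["variance_pct"].to_numpy() < 1e-6)
        assert part.attrs["joint_constrained_pct"] > 1.0


class TestLambdaRatio:
    def test_orthogonal_constraint_gives_zero_ratio(self, rng):
        Y = rng.uniform(size=(10, 4))
        Yc = Y - Y.mean(axis=0)
        v = rng.normal(size=10)
        basis = np.hstack([np.ones((10, 1)), Yc])
        v = v - basis @ np.linalg.lstsq(basis, v, rcond=None)[0]
        sp, ev = _wrap(Y, {"v": v})
        ratio, usable = dc.lambda_ratio(sp, ev, "v")
        assert ratio == pytest.approx(0.0, abs=1e-8)
        assert not usable

    def test_strong_gradient_clears_criterion(self, rng):
        sp, x = random_community(rng, n=30, m=12)
        hel = dc.hellinger(sp)
        ev = dc.EnvTable(pd.DataFrame({"grad": x}, index=sp.sites))
        ratio, usable = dc.lambda_ratio(hel, ev, "grad")
        assert usable and ratio > 0.5
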