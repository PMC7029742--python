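import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakescape.ordination import (
    OrdinationError,
    cca,
    permutation_anova,
    rda_adjusted_r2,
    varpart3,
)


def eigen_oracle(Y, X):
    """Canonical eigenvalues from the weighted cross-product matrices.

    Independent of the SVD route: builds S_qx (S_xx)^-1 S_xq explicitly
    and solves the symmetric eigenproblem.
    """
    Y = np.asarray(Y, dtype=float)
    P = Y / Y.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xc = Xc / np.sqrt(r @ (Xc ** 2))
    Xw = Xc * np.sqrt(r)[:, None]
    Sxx = Xw.T @ Xw
    Sxq = Xw.T @ Q
    M = Sxq.T @ np.linalg.inv(Sxx) @ Sxq
    ev = np.linalg.eigvalsh(M)[::-1]
    return ev[ev > 1e-12]


class TestCca:
    def test_ca_inertia_equals_chi2_over_n(self):
        Y = np.array([[10.0, 0.0], [0.0, 10.0]])
        res = cca(Y)
        chi2 = stats.chi2_contingency(Y, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / Y.sum(), abs=1e-12)
        assert res.total_inertia == pytest.approx(1.0)

    def test_ca_inertia_chi2_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            Y = rng.integers(1, 40, size=(6, 9)).astype(float)
            res = cca(Y)
            chi2 = stats.chi2_contingency(Y, correction=False)[0]
            assert res.total_inertia == pytest.approx(chi2 / Y.sum(), rel=1e-10)

    def test_eigenvalues_match_generalized_eigen_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            Y = rng.integers(1, 50, size=(8, 12)).astype(float)
            X = rng.normal(size=(8, 2))
            res = cca(Y, X)
            oracle = eigen_oracle(Y, X)
            np.testing.assert_allclose(res.eigenvalues, oracle[:len(res.eigenvalues)],
                                       atol=1e-8)

    def test_saturated_constraints_capture_all_inertia(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(1, 30, size=(5, 8)).astype(float)
        X = np.eye(5)[:, :4]  # site indicators, full rank after centering
        res = cca(Y, X)
        assert res.constrained_inertia == pytest.approx(res.total_inertia,
                                                        abs=1e-10)

    def test_constraint_nesting_monotone(self):
        rng = np.random.default_rng(2)
        Y = rng.integers(1, 30, size=(10, 15)).astype(float)
        X = rng.normal(size=(10, 3))
        inertias = [cca(Y, X[:, :q]).constrained_inertia for q in (1, 2, 3)]
        assert inertias[0] <= inertias[1] + 1e-12 <= inertias[2] + 2e-12

    def test_eigenvalues_bounded_by_one_and_nonincreasing(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(1, 30, size=(12, 20)).astype(float)
        X = rng.normal(size=(12, 4))
        ev = cca(Y, X).eigenvalues
        assert (ev <= 1 + 1e-10).all()
        assert (np.diff(ev) <= 1e-12).all()

    def test_inertia_decomposition_additive(self):
        rng = np.random.default_rng(4)
        Y = rng.integers(1, 30, size=(10, 12)).astype(float)
        X = rng.normal(size=(10, 2))
        res = cca(Y, X)
        assert res.constrained_inertia + res.residual_inertia == pytest.approx(
            res.total_inertia, abs=1e-8)

    def test_collinear_constraints_rejected(self):
        rng = np.random.default_rng(5)
        Y = rng.integers(1, 30, size=(8, 10)).astype(float)
        x = rng.normal(size=8)
        with pytest.raises(OrdinationError, match="rank"):
            cca(Y, np.column_stack([x, 2 * x]))

    def test_zero_sum_row_rejected(self):
        Y = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(OrdinationError, match="row"):
            cca(Y)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestVeganCrossCheck:
    """Independent cross-check of CCA and varpart against R's vegan."""

    def test_cca_matches_vegan(self, tmp_path):
        rng = np.random.default_rng(42)
        Y = rng.integers(1, 50, size=(8, 12)).astype(float)
        X = rng.normal(size=(8, 2))
        np.savetxt(tmp_path / "Y.txt", Y)
        np.savetxt(tmp_path / "X.txt", X)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.table('{tmp_path}/Y.txt'))
            X <- as.data.frame(as.matrix(read.table('{tmp_path}/X.txt')))
            m <- cca(Y ~ V1 + V2, data=X)
            cat(m$CCA$eig, m$tot.chi, m$CCA$tot.chi, sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        res = cca(Y, X)
        np.testing.assert_allclose(res.eigenvalues, vals[:2], rtol=1e-6)
        assert res.total_inertia == pytest.approx(vals[2], rel=1e-6)
        assert res.constrained_inertia == pytest.approx(vals[3], rel=1e-6)

    def test_adjusted_r2_matches_vegan(self, tmp_path):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(20, 10))
        X = rng.normal(size=(20, 3))
        np.savetxt(tmp_path / "Y.txt", Y)
        np.savetxt(tmp_path / "X.txt", X)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.table('{tmp_path}/Y.txt'))
            X <- as.matrix(read.table('{tmp_path}/X.txt'))
            cat(RsquareAdj(rda(Y, X))$adj.r.squared, '\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        assert rda_adjusted_r2(Y, X) == pytest.approx(float(out.stdout), rel=1e-6)


class TestAdjustedR2:
    def test_no_predictors_is_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(10, 4))
        assert rda_adjusted_r2(Y, np.empty((10, 0))) == 0.0

    def test_perfect_fit_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        Y = X @ rng.normal(size=(2, 5)) + 3.0
        assert rda_adjusted_r2(Y, X) == pytest.approx(1.0, abs=1e-10)

    def test_matches_ols_trace_oracle(self):
        rng = np.random.default_rng(2)
        n, q = 20, 3
        X = rng.normal(size=(n, q))
        Y = rng.normal(size=(n, 6))
        Yc = Y - Y.mean(axis=0)
        D = np.column_stack([np.ones(n), X])
        H = D @ np.linalg.solve(D.T @ D, D.T)
        r2 = np.trace((H @ Yc).T @ (H @ Yc)) / np.trace(Yc.T @ Yc)
        expected = 1 - (1 - r2) * (n - 1) / (n - q - 1)
        assert rda_adjusted_r2(Y, X) == pytest.approx(expected, abs=1e-10)

    def test_too_many_constraints_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(OrdinationError):
            rda_adjusted_r2(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))


class TestVarpart3:
    def test_duplicated_set_has_zero_unique(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 8))
        X1 = rng.normal(size=(20, 2))
        X3 = rng.normal(size=(20, 2))
        vp = varpart3(Y, X1, X1.copy(), X3)
        assert vp.unique["X2"] == pytest.approx(0.0, abs=1e-10)
        assert vp.unique["X1"] == pytest.approx(0.0, abs=1e-10)

    def test_additive_orthogonal_construction_recovered(self):
        # orthonormal design, Y built additively with known variance shares
        rng = np.random.default_rng(1)
        n = 60
        M = np.linalg.qr(rng.normal(size=(n, 3)))[0]
        X1, X2, X3 = M[:, :1], M[:, 1:2], M[:, 2:3]
        Y = 3.0 * X1 + 2.0 * X2 + 1.0 * X3  # shares 9 : 4 : 1
        vp = varpart3(Y, X1, X2, X3)
        total = sum(vp.unique.values())
        # Ezekiel adjustment of the subset models shifts shares slightly
        assert vp.unique["X1"] / total == pytest.approx(9 / 14, abs=0.02)
        assert vp.unique["X3"] / total == pytest.approx(1 / 14, abs=0.02)
        for v in vp.shared_pairwise.values():
            assert v == pytest.approx(0.0, abs=0.02)
        assert vp.residual == pytest.approx(0.0, abs=1e-6)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(25, 6))
        vp = varpart3(Y, rng.normal(size=(25, 2)), rng.normal(size=(25, 2)),
                      rng.normal(size=(25, 2)))
        total = (sum(vp.unique.values()) + sum(vp.shared_pairwise.values())
                 + vp.shared_all + vp.residual)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_explains_little_on_average(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(100):
            Y = rng.normal(size=(46, 5))
            vp = varpart3(Y, rng.normal(size=(46, 2)), rng.normal(size=(46, 2)),
                          rng.normal(size=(46, 2)))
            vals.append(vp.subset_r2[("X1", "X2", "X3")])
        assert abs(np.mean(vals)) < 0.05


class TestPermutationAnova:
    def _planted(self, seed=0, strength=4.0):
        rng = np.random.default_rng(seed)
        n, m = 20, 30
        x1 = rng.normal(size=n)
        X = np.column_stack([x1, rng.normal(size=n)])
        base = rng.uniform(1, 5, size=m)
        # strong response of the first half of OTUs to x1
        loading = np.zeros(m)
        loading[: m // 2] = strength
        lam = np.exp(np.log(base)[None, :] + np.outer(x1, loading))
        Y = rng.poisson(lam) + 1
        return Y, X

    def test_planted_signal_detected_at_floor(self):
        Y, X = self._planted()
        res = permutation_anova(Y, X, term="model", n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        marg = permutation_anova(Y, X, term="margin:X0", n_perm=199, seed=2)
        assert marg.p_value == pytest.approx(1 / 200)

    def test_missing_margin_name_rejected(self):
        Y, X = self._planted()
        with pytest.raises(OrdinationError, match="nope"):
            permutation_anova(Y, X, term="margin:nope", n_perm=99, seed=0)

    def test_pseudo_f_positive_and_p_bounded(self):
        rng = np.random.default_rng(9)
        Y = rng.integers(1, 30, size=(15, 20))
        X = rng.normal(size=(15, 2))
        res = permutation_anova(Y, X, n_perm=99, seed=3)
        assert res.pseudo_f >= 0
        assert 1 / 100 <= res.p_value <= 1.0
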