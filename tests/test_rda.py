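"""Redundancy analysis engine: transform, fit, permutation tests, selection."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from seascape import RDA, forward_select, hellinger, partial_rda, rda, rda_anova


# ---------------------------------------------------------------------------
# Hellinger transformation
# ---------------------------------------------------------------------------


def test_hellinger_single_column_is_all_ones():
    out = hellinger(pd.DataFrame({"a": [0.2, 0.5, 0.01]}))
    assert np.allclose(out.to_numpy(), 1.0)


def test_hellinger_hand_arithmetic():
    out = hellinger(pd.DataFrame([[0.1, 0.3]]))
    assert out.to_numpy()[0] == pytest.approx([0.5, np.sqrt(0.75)], abs=1e-6)


def test_hellinger_rows_have_unit_sum_of_squares():
    rng = np.random.default_rng(0)
    raw = rng.uniform(0, 0.5, size=(6, 30))
    out = hellinger(pd.DataFrame(raw))
    assert np.allclose((out.to_numpy() ** 2).sum(axis=1), 1.0)


def test_hellinger_rejects_negative_and_flags_zero_rows():
    with pytest.raises(ValueError, match="non-negative"):
        hellinger(pd.DataFrame([[0.1, -0.2]]))
    with pytest.warns(UserWarning, match="all-zero"):
        out = hellinger(pd.DataFrame([[0.0, 0.0], [0.1, 0.3]]))
    assert np.all(out.to_numpy()[0] == 0.0)


# ---------------------------------------------------------------------------
# RDA core
# ---------------------------------------------------------------------------


@pytest.fixture()
def four_pop_fixture():
    """Small written-out response and predictors (4 rows is the smallest
    interesting constrained ordination)."""
    Y = pd.DataFrame(
        {
            "l1": [0.50, 0.62, 0.41, 0.33],
            "l2": [0.12, 0.05, 0.22, 0.28],
            "l3": [0.86, 0.78, 0.88, 0.90],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    X = pd.DataFrame(
        {"env": [1.2, 2.1, 0.4, 0.1], "depth": [10.0, 12.0, 30.0, 25.0]},
        index=Y.index,
    )
    return Y, X


def test_self_explanation_gives_r2_one():
    rng = np.random.default_rng(1)
    Y = pd.DataFrame(rng.normal(size=(10, 6)))
    Yc = Y - Y.mean()
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    X = pd.DataFrame(U[:, :6] * s[:6])
    assert rda(Y, X).r2 == pytest.approx(1.0, abs=1e-10)


def test_rda_matches_independent_two_step_oracle(four_pop_fixture):
    """Explicit per-column OLS (statsmodels) then PCA of fitted values."""
    import statsmodels.api as sm
    from sklearn.decomposition import PCA

    Y, X = four_pop_fixture
    res = rda(Y, X)

    Yc = (Y - Y.mean()).to_numpy()
    Xd = sm.add_constant(X.to_numpy())
    fitted = np.column_stack(
        [sm.OLS(Yc[:, j], Xd).fit().fittedvalues for j in range(Yc.shape[1])]
    )
    ss_fit = (fitted**2).sum()
    ss_tot = (Yc**2).sum()
    assert res.r2 == pytest.approx(ss_fit / ss_tot, abs=1e-10)
    n, m = Y.shape[0], X.shape[1]
    assert res.adj_r2 == pytest.approx(1 - (1 - ss_fit / ss_tot) * (n - 1) / (n - m - 1), abs=1e-10)

    pca = PCA(n_components=len(res.eigenvalues)).fit(fitted)
    # eigenvalues of the fit: PCA explained variance * (n - 1) = squared singular values
    assert res.eigenvalues == pytest.approx(pca.explained_variance_ * (n - 1), abs=1e-9)


def test_eigenvalue_sum_over_total_variance_equals_r2(four_pop_fixture):
    Y, X = four_pop_fixture
    res = rda(Y, X)
    ss_tot = ((Y - Y.mean()) ** 2).to_numpy().sum()
    assert res.eigenvalues.sum() / ss_tot == pytest.approx(res.r2, abs=1e-12)


def test_rda_invariant_to_invertible_reparameterisation(four_pop_fixture):
    Y, X = four_pop_fixture
    A = np.array([[2.0, 0.3], [-1.0, 0.8]])  # invertible
    XA = pd.DataFrame(X.to_numpy() @ A, index=X.index, columns=["a", "b"])
    r1, r2_ = rda(Y, X), rda(Y, XA)
    assert r1.r2 == pytest.approx(r2_.r2, abs=1e-12)
    assert r1.eigenvalues == pytest.approx(r2_.eigenvalues, abs=1e-10)


def test_collinear_predictors_dropped_with_warning(four_pop_fixture):
    Y, X = four_pop_fixture
    X2 = X.copy()
    X2["env_twice"] = 2 * X2["env"]
    with pytest.warns(UserWarning, match="aliased"):
        res = rda(Y, X2)
    assert "env_twice" not in res.predictors
    assert res.r2 == pytest.approx(rda(Y, X).r2, abs=1e-12)


def test_rda_against_vegan_oracle(tmp_path, four_pop_fixture):
    """vegan::rda on the same fixture: R2, adjusted R2 and eigenvalues."""
    Y, X = four_pop_fixture
    Y.to_csv(tmp_path / "Y.csv", index=False)
    X.to_csv(tmp_path / "X.csv", index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        Y <- read.csv("Y.csv"); X <- read.csv("X.csv")
        fit <- rda(Y ~ env + depth, data = X)
        r2 <- RsquareAdj(fit)
        cat(sprintf("%.12f %.12f ", r2$r.squared, r2$adj.r.squared))
        cat(sprintf("%.12f ", fit$CCA$eig))
        """
    )
    (tmp_path / "check.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True, check=True
    )
    vals = [float(v) for v in out.stdout.split()]
    res = rda(Y, X)
    n = Y.shape[0]
    assert res.r2 == pytest.approx(vals[0], abs=1e-9)
    assert res.adj_r2 == pytest.approx(vals[1], abs=1e-9)
    # vegan eigenvalues are SS/(n-1)
    assert res.eigenvalues / (n - 1) == pytest.approx(vals[2:], abs=1e-9)


# ---------------------------------------------------------------------------
# Permutation ANOVA
# ---------------------------------------------------------------------------


def test_perfect_association_reaches_permutation_floor():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(12, 2)))
    B = rng.normal(size=(2, 5))
    Y = pd.DataFrame(X.to_numpy() @ B)
    f, p = rda_anova(Y, X, n_perm=199, seed=0)
    assert np.isinf(f) or f > 1e6
    assert p == pytest.approx(1.0 / 200.0)


def test_saturated_model_is_refused():
    rng = np.random.default_rng(3)
    Y = pd.DataFrame(rng.normal(size=(5, 3)))
    X = pd.DataFrame(rng.normal(size=(5, 4)))
    with pytest.raises(ValueError, match="saturated|degrees"):
        rda_anova(Y, X, n_perm=99, seed=0)
    with pytest.raises(ValueError, match="n_perm"):
        rda_anova(Y, X.iloc[:, :1], n_perm=10, seed=0)


def test_null_type_one_error_quick_check():
    """Smoke-scale type-I calibration (the full 200-replicate check lives in
    the acceptance suite)."""
    rng = np.random.default_rng(4)
    rejections = 0
    for _ in range(40):
        Y = rng.normal(size=(10, 8))
        X = rng.normal(size=(10, 2))
        _, p = rda_anova(Y, X, n_perm=99, seed=int(rng.integers(2**31)))
        rejections += p <= 0.05
    assert rejections / 40 <= 0.15


# ---------------------------------------------------------------------------
# Partial RDA
# ---------------------------------------------------------------------------


def test_partial_with_identical_conditioning_explains_nothing(four_pop_fixture):
    Y, X = four_pop_fixture
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = partial_rda(Y, X, X)
    assert res.r2 == pytest.approx(0.0, abs=1e-12)


def test_partial_with_empty_conditioning_reduces_to_rda(four_pop_fixture):
    Y, X = four_pop_fixture
    plain = rda(Y, X)
    part = partial_rda(Y, X, None)
    assert part.r2 == plain.r2
    assert part.adj_r2 == plain.adj_r2
    assert np.array_equal(part.eigenvalues, plain.eigenvalues)
    assert part.site_scores.equals(plain.site_scores)


def test_orthogonal_decomposition_is_exact():
    """Y = A + B with A orthogonal to B: partial_rda(Y, B, A) explains exactly
    SS(B)/SS(Y), and R2 decomposes additively."""
    rng = np.random.default_rng(5)
    A = rng.normal(size=(12, 1))
    B = rng.normal(size=(12, 1))
    A -= A.mean(0)
    B -= B.mean(0)
    B -= A * (A.T @ B) / (A.T @ A)  # orthogonalise
    Y = pd.DataFrame(A + B)
    partB = partial_rda(Y, pd.DataFrame(B), pd.DataFrame(A))
    ss_b = float((B**2).sum())
    ss_y = float(((Y - Y.mean()) ** 2).to_numpy().sum())
    assert partB.r2 == pytest.approx(ss_b / ss_y, abs=1e-10)
    full = rda(Y, pd.DataFrame(np.hstack([A, B])))
    onlyA = rda(Y, pd.DataFrame(A))
    assert full.r2 == pytest.approx(partB.r2 + onlyA.r2, abs=1e-10)


def test_freedman_lane_partial_test_runs():
    rng = np.random.default_rng(6)
    Z = pd.DataFrame(rng.normal(size=(12, 1)), columns=["z"])
    Y = pd.DataFrame(Z.to_numpy() @ rng.normal(size=(1, 4)) + 0.1 * rng.normal(size=(12, 4)))
    X = pd.DataFrame(rng.normal(size=(12, 1)), columns=["x"])
    f, p = rda_anova(Y, X, Z=Z, n_perm=199, seed=1)
    assert p > 0.05  # X is pure noise once Z is accounted for


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------


def test_single_self_candidate_selected_at_floor():
    """A candidate that determines Y outright is taken at the permutation floor."""
    rng = np.random.default_rng(7)
    v = rng.normal(size=10)
    Y = pd.DataFrame({"l1": v, "l2": 2 * v, "l3": -0.5 * v})
    cand = pd.DataFrame({"v1": v})
    trace = forward_select(Y, cand, alpha=0.05, n_perm=199, seed=0, use_adjr2_ceiling=False)
    assert trace.selected == ["v1"]
    assert trace.steps[0].p_value == pytest.approx(1.0 / 200.0)


def test_true_driver_selected_before_noise():
    rng = np.random.default_rng(8)
    n = 30
    v1 = rng.normal(size=(n, 1))
    Y = pd.DataFrame(v1 @ rng.normal(size=(1, 6)) + 0.2 * rng.normal(size=(n, 6)))
    cand = pd.DataFrame(
        np.hstack([v1, rng.normal(size=(n, 5))]),
        columns=["v1"] + [f"noise{k}" for k in range(5)],
    )
    trace = forward_select(Y, cand, alpha=0.05, n_perm=199, seed=1)
    assert trace.selected[0] == "v1"


def test_pure_noise_candidates_rarely_selected():
    """Double stopping keeps the null selection rate near the nominal level."""
    rng = np.random.default_rng(9)
    n_selected = 0
    reps = 25
    for _ in range(reps):
        Y = pd.DataFrame(rng.normal(size=(10, 6)))
        cand = pd.DataFrame(rng.normal(size=(10, 5)), columns=[f"n{k}" for k in range(5)])
        trace = forward_select(Y, cand, alpha=0.05, n_perm=99, seed=int(rng.integers(2**31)))
        n_selected += len(trace.selected) > 0
    assert n_selected / reps <= 0.2


def test_selection_trace_is_monotone_and_bounded():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(12, 3))
    Y = pd.DataFrame(X @ rng.normal(size=(3, 8)) + 0.3 * rng.normal(size=(12, 8)))
    cand = pd.DataFrame(X, columns=["a", "b", "c"])
    trace = forward_select(Y, cand, alpha=0.1, n_perm=199, seed=2)
    adj = [s.adj_r2_after for s in trace.steps]
    assert all(np.diff(adj) >= -1e-9)
    assert trace.stopped_by in {"alpha", "adjR2-ceiling", "exhausted", "saturation-guard"}
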