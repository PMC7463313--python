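"""Redundancy analysis (RDA) and forward selection of predictors.

RDA is a constrained ordination: the response matrix (here Hellinger-
transformed population minor-allele frequencies) is regressed on the
predictor matrix by least squares and the fitted values are decomposed into
principal axes.  R-squared is the fraction of total response variance
captured by the fit; the adjusted R-squared uses the Ezekiel correction.
Significance is assessed by permutation (unrestricted row permutation for
global tests; Freedman-Lane residual permutation when conditioning
covariates are present), and predictors are chosen by greedy forward
selection with a double stopping rule (marginal permutation p-value and the
adjusted R-squared of the full candidate model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import rng_for

RANK_TOL = 1e-9


def hellinger(raw) -> pd.DataFrame:
    """Hellinger transformation: relative row abundance, then square root.

    Rows that sum to zero are left at zero (flagged via a warning); every
    other row's squared entries sum to 1.
    """
    df = pd.DataFrame(raw).astype(float) if not isinstance(raw, pd.DataFrame) else raw.astype(float)
    vals = df.to_numpy()
    if (vals < 0).any():
        raise ValueError("Hellinger transformation requires non-negative entries")
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows left at zero in Hellinger transform")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(vals / sums[:, None])
    out[zero] = 0.0
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if isinstance(X, pd.Series):
        return X.to_numpy(dtype=float)[:, None], [X.name or "x0"]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent subset of centred columns."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=RANK_TOL * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    return np.asarray(keep, dtype=int)


@dataclass
class RDAResult:
    """Summary of one (partial) RDA fit."""

    predictors: list[str]
    conditioning: list[str]
    r2: float
    adj_r2: float
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    locus_scores: pd.DataFrame
    predictor_scores: pd.DataFrame
    pseudo_f: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "conditioning": self.conditioning,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


class RDA(BaseEstimator):
    """Redundancy analysis as an sklearn-style estimator.

    ``fit(X, Y)`` column-centres Y and X, drops aliased (collinear) predictor
    columns with a warning, computes the least-squares fit
    Yhat = X (X'X)^-1 X' Y and its principal axes.  Fitted attributes carry a
    trailing underscore; ``score`` returns R².
    """

    def __init__(self, scale_predictors: bool = False):
        self.scale_predictors = scale_predictors

    def fit(self, X, Y) -> "RDA":
        Ymat, self.response_names_ = _as_matrix(Y)
        Xmat, xnames = _as_matrix(X)
        n = Ymat.shape[0]
        if Xmat.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")

        Yc = Ymat - Ymat.mean(axis=0, keepdims=True)
        Xc = Xmat - Xmat.mean(axis=0, keepdims=True)
        if self.scale_predictors:
            sd = Xc.std(axis=0, ddof=1)
            Xc = np.divide(Xc, sd, out=np.zeros_like(Xc), where=sd > 0)

        keep = _independent_columns(Xc)
        if keep.size < Xc.shape[1]:
            dropped = [xnames[j] for j in range(Xc.shape[1]) if j not in set(keep.tolist())]
            warnings.warn(f"dropping aliased predictor columns: {dropped}")
        Xc = Xc[:, keep]
        self.predictor_names_ = [xnames[j] for j in keep]
        m = Xc.shape[1]
        if m >= n - 1 and m > 0:
            warnings.warn("model is saturated (predictors >= n - 1); R2 will be 1")

        ss_total = float((Yc**2).sum())
        if m == 0:
            Yhat = np.zeros_like(Yc)
        else:
            coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
            Yhat = Xc @ coef
            self.coef_ = coef
        ss_fit = float((Yhat**2).sum())
        self.r2_ = ss_fit / ss_total if ss_total > 0 else float("nan")
        dof = n - m - 1
        self.adj_r2_ = (
            1.0 - (1.0 - self.r2_) * (n - 1) / dof if dof > 0 else float("nan")
        )

        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        rank = int(np.sum(s > RANK_TOL * max(s.max(), 1.0) if s.size else 0))
        U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
        self.eigenvalues_ = s**2  # sums to SS(Yhat)
        self.site_scores_ = U * s
        self.locus_scores_ = Vt.T
        # biplot scores: correlation of predictors with the site scores
        self.predictor_scores_ = np.zeros((m, rank))
        for k in range(rank):
            axis = self.site_scores_[:, k]
            if axis.std() > 0:
                for j in range(m):
                    if Xc[:, j].std() > 0:
                        self.predictor_scores_[j, k] = np.corrcoef(Xc[:, j], axis)[0, 1]

        self.n_samples_ = n
        self.n_predictors_ = m
        self.ss_total_ = ss_total
        self.ss_fit_ = ss_fit
        self.fitted_values_ = Yhat
        self.residuals_ = Yc - Yhat
        self._X_centred = Xc
        self._Y_centred = Yc
        return self

    def score(self, X=None, Y=None) -> float:
        return self.r2_

    def result(self, index=None, conditioning: list[str] | None = None) -> RDAResult:
        rank = self.eigenvalues_.size
        axes = [f"RDA{k + 1}" for k in range(rank)]
        idx = index if index is not None else np.arange(self.n_samples_)
        return RDAResult(
            predictors=self.predictor_names_,
            conditioning=conditioning or [],
            r2=self.r2_,
            adj_r2=self.adj_r2_,
            eigenvalues=self.eigenvalues_,
            site_scores=pd.DataFrame(self.site_scores_, index=idx, columns=axes),
            locus_scores=pd.DataFrame(self.locus_scores_, index=self.response_names_, columns=axes),
            predictor_scores=pd.DataFrame(self.predictor_scores_, index=self.predictor_names_, columns=axes),
        )


def rda(Y, X) -> RDAResult:
    """Fit an RDA of response Y on predictors X."""
    est = RDA().fit(X, Y)
    index = Y.index if isinstance(Y, pd.DataFrame) else None
    return est.result(index=index)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of column-centred M after least squares on column-centred Z."""
    if Z.shape[1] == 0:
        return M
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def partial_rda(Y, X, Z=None) -> RDAResult:
    """RDA of Y on X conditioned on covariates Z (Freedman-Lane residualisation).

    Y and X are residualised on Z; the reported R² is the semi-partial
    fraction: SS explained by X-after-Z over the *total* SS of Y.  With Z
    empty this reduces bit-for-bit to ``rda``.
    """
    if Z is None or (hasattr(Z, "shape") and np.asarray(Z).size == 0):
        return rda(Y, X)
    Ymat, ynames = _as_matrix(Y)
    Xmat, xnames = _as_matrix(X)
    Zmat, znames = _as_matrix(Z)
    n = Ymat.shape[0]
    Yc = Ymat - Ymat.mean(axis=0, keepdims=True)
    Xc = Xmat - Xmat.mean(axis=0, keepdims=True)
    Zc = Zmat - Zmat.mean(axis=0, keepdims=True)
    Zc = Zc[:, _independent_columns(Zc)]

    ss_total = float((Yc**2).sum())
    Yres = _residualize(Yc, Zc)
    Xres = _residualize(Xc, Zc)

    # drop X columns entirely absorbed by Z
    keep = [j for j in range(Xres.shape[1]) if np.abs(Xres[:, j]).max() > 1e-10]
    Xres = Xres[:, keep]
    kept_names = [xnames[j] for j in keep]
    est = RDA().fit(Xres, Yres) if Xres.shape[1] else None

    if est is None or est.n_predictors_ == 0:
        r2 = 0.0
        adj = 0.0
        eig = np.array([])
        idx = Y.index if isinstance(Y, pd.DataFrame) else np.arange(n)
        empty = pd.DataFrame(index=idx)
        return RDAResult(kept_names, znames, r2, adj, eig, empty, pd.DataFrame(index=ynames), pd.DataFrame())

    r2 = est.ss_fit_ / ss_total if ss_total > 0 else float("nan")
    m = est.n_predictors_
    q = Zc.shape[1]
    dof = n - m - q - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else float("nan")
    res = est.result(index=Y.index if isinstance(Y, pd.DataFrame) else None, conditioning=znames)
    res.predictors = kept_names
    res.r2 = r2
    res.adj_r2 = adj
    return res


def _pseudo_f(Yc, Q_x, n, m, q) -> float:
    """Pseudo-F from the orthonormal basis Q_x of the (residualised) predictors."""
    ss_fit = float(((Q_x.T @ Yc) ** 2).sum())
    ss_res = float((Yc**2).sum()) - ss_fit
    dof_res = n - m - q - 1
    if dof_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    if ss_res <= 0:
        return float("inf")
    return (ss_fit / m) / (ss_res / dof_res)


def rda_anova(
    Y,
    X,
    Z=None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Permutation ANOVA of an RDA (pseudo-F and p-value).

    Global test (no Z): rows of Y are permuted freely.  Partial test:
    Freedman-Lane — Y is decomposed on Z into fitted + residual parts and the
    residuals are permuted.  p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = rng_for(seed, "rda-anova")
    Ymat, _ = _as_matrix(Y)
    Xmat, _ = _as_matrix(X)
    n = Ymat.shape[0]
    Yc = Ymat - Ymat.mean(axis=0, keepdims=True)
    Xc = Xmat - Xmat.mean(axis=0, keepdims=True)
    Xc = Xc[:, _independent_columns(Xc)]

    if Z is not None and np.asarray(Z).size > 0:
        Zmat, _ = _as_matrix(Z)
        Zc = Zmat - Zmat.mean(axis=0, keepdims=True)
        Zc = Zc[:, _independent_columns(Zc)]
    else:
        Zc = np.empty((n, 0))
    q = Zc.shape[1]

    Xres = _residualize(Xc, Zc)
    keep = [j for j in range(Xres.shape[1]) if np.abs(Xres[:, j]).max() > 1e-10]
    Xres = Xres[:, keep]
    m = Xres.shape[1]
    if m == 0:
        raise ValueError("no predictor variance left after conditioning")
    Q_x, _ = np.linalg.qr(Xres)

    if q > 0:
        coef, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
        Y_fit_z = Zc @ coef
        Y_res_z = Yc - Y_fit_z
        f_obs = _pseudo_f(Y_res_z, Q_x, n, m, q)
    else:
        Y_res_z = Yc
        Y_fit_z = np.zeros_like(Yc)
        f_obs = _pseudo_f(Yc, Q_x, n, m, q)

    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_perm = Y_fit_z + Y_res_z[perm]
        Y_perm = Y_perm - Y_perm.mean(axis=0, keepdims=True)
        if q > 0:
            Y_perm = _residualize(Y_perm, Zc)
        f_star = _pseudo_f(Y_perm, Q_x, n, m, q)
        if f_star >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(f_obs), float(p)


@dataclass
class SelectionStep:
    variable: str
    adj_r2_after: float
    p_value: float


@dataclass
class SelectionTrace:
    """Record of a forward-selection run."""

    steps: list[SelectionStep] = field(default_factory=list)
    stopped_by: str = "exhausted"
    full_model_adj_r2: float | None = None
    seed: int | None = None

    @property
    def selected(self) -> list[str]:
        return [s.variable for s in self.steps]


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = 0,
    use_adjr2_ceiling: bool = True,
    global_test: bool = True,
) -> SelectionTrace:
    """Greedy forward selection of RDA predictors with double stopping.

    Selection begins only if the global model (all candidates at once) is
    itself significant at ``alpha`` — the guard that keeps the null selection
    rate near the nominal level.  At each step the candidate giving the
    largest adjusted R² whose marginal permutation p-value (conditioned on
    the already-selected set) is <= alpha is added.  Selection stops when no
    candidate passes, when the adjusted R² of the model would exceed that of
    the full candidate model, or when adding another variable would saturate
    the model.  Both the global test and the adjusted-R² ceiling are skipped
    when the full candidate model is saturated (no residual degrees of
    freedom), leaving the per-step permutation test as the only guard.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    rng = rng_for(seed, "forward-select")
    Ymat, _ = _as_matrix(Y)
    n = Ymat.shape[0]

    ceiling = np.inf
    full_feasible = candidates.shape[1] < n - 1
    if use_adjr2_ceiling and full_feasible:
        full = RDA().fit(candidates, Ymat)
        ceiling = full.adj_r2_
    trace = SelectionTrace(full_model_adj_r2=None if np.isinf(ceiling) else ceiling, seed=seed)

    if global_test and full_feasible:
        _, p_global = rda_anova(
            Ymat, candidates, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        if p_global > alpha:
            trace.stopped_by = "global-test"
            return trace

    selected: list[str] = []
    remaining = list(candidates.columns)
    while remaining:
        if len(selected) + 1 >= n - 1:
            trace.stopped_by = "saturation-guard"
            break
        Z = candidates[selected] if selected else None
        best = None
        for var in remaining:
            trial = candidates[selected + [var]]
            est = RDA().fit(trial, Ymat)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                _, p = rda_anova(Ymat, candidates[[var]], Z=Z, n_perm=n_perm, seed=sub_seed)
            except ValueError:
                continue
            if p <= alpha and (best is None or est.adj_r2_ > best[1]):
                best = (var, est.adj_r2_, p)
        if best is None:
            trace.stopped_by = "alpha"
            break
        var, adj, p = best
        if adj > ceiling + 1e-12:
            trace.stopped_by = "adjR2-ceiling"
            break
        trace.steps.append(SelectionStep(variable=var, adj_r2_after=adj, p_value=p))
        selected.append(var)
        remaining.remove(var)
    else:
        trace.stopped_by = "exhausted"
    return trace
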