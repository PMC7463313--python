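"""Outlier-locus detection: a PCA-based scan and an F_ST-based scan.

The PCA scan regresses each locus on the leading principal components of the
individual genotype matrix, scores loci by a robust Mahalanobis distance of
the regression z-scores rescaled by a genomic inflation factor, and converts
to chi-squared p-values with Benjamini-Hochberg q-values.

The F_ST scan is a parametric-bootstrap null: neutral loci are simulated
under the Balding-Nichols model at the observed multilocus theta and sample
sizes, matched to the observed loci by global minor-allele-frequency bin, and
each observed locus is ranked against its matched null per-locus thetas.
Candidate outliers are the loci flagged by *both* scans; the complement is
the neutral panel.

Both scans are sklearn-style estimators: construct with parameters, ``fit``
a GenotypeMatrix, read the fitted ``result_``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import EmpiricalCovariance, MinCovDet
from statsmodels.stats.multitest import multipletests

from .._utils import rng_for
from ..genotypes import MISSING, GenotypeMatrix
from .diversity import wc_variance_components


@dataclass
class OutlierScanResult:
    """Per-locus statistics of one scan."""

    table: pd.DataFrame  # columns: locus, stat, p, q, flagged
    method: str
    alpha: float

    @property
    def flagged_loci(self) -> set[str]:
        return set(self.table.loc[self.table["flagged"], "locus"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _bh_flag(pvals: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(pvals)
    q = np.full_like(pvals, np.nan, dtype=float)
    flagged = np.zeros(pvals.size, dtype=bool)
    if ok.any():
        rej, qv, _, _ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        flagged[ok] = q[ok] <= alpha
    return q, flagged


class PcaOutlierScan(BaseEstimator):
    """PCA-regression outlier scan over individual genotypes.

    Per-locus z-scores from regressing each (centred/scaled, mean-imputed)
    locus on the K leading principal components of the individual matrix are
    combined into a Mahalanobis distance, rescaled by the genomic inflation
    factor (median distance over the chi-squared median), and referred to an
    F(K, n-K-1) distribution — the exact small-sample reference for
    t-distributed scores, which keeps the null tail calibrated where the
    chi-squared approximation is liberal.  The covariance of the z-vectors is
    estimated empirically by default; ``robust=True`` switches to the minimum
    covariance determinant, which resists masking by a large outlier fraction
    but trims heterogeneous-variance loci under weak structure and then
    over-flags (the genomic inflation factor only guards the bulk, not the
    tail).

    Parameters
    ----------
    n_components : number of leading principal components K, chosen by the
        user from the scree (``explained_variance_ratio_`` is exported).
    alpha : q-value threshold for flagging.
    min_maf : loci below this global MAF are excluded from the scan
        (statistic NaN, never flagged).
    robust : use a robust (MCD) covariance for the Mahalanobis step.
    """

    def __init__(
        self,
        n_components: int = 2,
        alpha: float = 0.05,
        min_maf: float = 0.01,
        robust: bool = False,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.min_maf = min_maf
        self.robust = robust

    def fit(self, G: GenotypeMatrix, y=None) -> "PcaOutlierScan":
        K = self.n_components
        n, L = G.n_individuals, G.n_loci
        if not (1 <= K < n):
            raise ValueError("n_components must satisfy 1 <= K < n_individuals")

        called = G.called_mask()
        geno = np.where(called, G.genotypes, 0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = geno.sum(axis=0) / (2.0 * called.sum(axis=0))
        maf = np.minimum(p_hat, 1 - p_hat)
        usable = np.isfinite(maf) & (maf >= self.min_maf)

        sd = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
        X = np.zeros((n, L))
        cols = np.nonzero(usable)[0]
        X[:, cols] = (geno[:, cols] - 2.0 * p_hat[cols]) / sd[cols]
        X[:, cols] = np.where(called[:, cols], X[:, cols], 0.0)  # mean imputation

        U, s, _ = np.linalg.svd(X, full_matrices=False)
        if np.sum(s > 1e-10) < K:
            raise ValueError("n_components exceeds the rank of the genotype matrix")
        self.explained_variance_ratio_ = (s**2 / (s**2).sum())[: min(n, 20)]
        self.singular_values_ = s
        self.scores_ = U[:, :K] * s[:K]

        # per-locus multiple regression on the orthonormal PCs
        Uk = U[:, :K]
        B = Uk.T @ X[:, cols]                      # (K, L_used)
        rss = (X[:, cols] ** 2).sum(axis=0) - (B**2).sum(axis=0)
        dof = n - K - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = np.maximum(rss, 0.0) / dof
            z = B / np.sqrt(sigma2)[None, :]
        z = z.T                                     # (L_used, K)
        z[~np.isfinite(z)] = 0.0

        # Mahalanobis distance of the z-vectors
        if self.robust:
            cov = MinCovDet(random_state=0).fit(z)
        else:
            cov = EmpiricalCovariance().fit(z)
        d2 = cov.mahalanobis(z)

        lam = np.median(d2) / stats.chi2.ppf(0.5, df=K)
        self.inflation_factor_ = float(lam)
        stat = np.full(L, np.nan)
        stat[cols] = d2 / lam
        pvals = stats.f.sf(stat / K, K, n - K - 1)
        q, flagged = _bh_flag(pvals, self.alpha)

        self.result_ = OutlierScanResult(
            table=pd.DataFrame(
                {"locus": G.locus_ids, "stat": stat, "p": pvals, "q": q, "flagged": flagged}
            ),
            method="pca",
            alpha=self.alpha,
        )
        return self


def _per_locus_theta(G: GenotypeMatrix) -> np.ndarray:
    a, b, c = wc_variance_components(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


class FstOutlierScan(BaseEstimator):
    """Parametric-bootstrap F_ST outlier scan.

    ``n_sim`` neutral loci are simulated under Balding-Nichols at the
    observed multilocus theta and the observed per-population sample sizes;
    each observed locus is compared against the null loci falling in the same
    global-MAF bin (width ``maf_bin_width``): p = (1 + #null theta >= observed
    theta) / (1 + #matched).
    """

    def __init__(
        self,
        n_sim: int = 20_000,
        alpha: float = 0.05,
        maf_bin_width: float = 0.05,
        seed: int | None = 0,
    ):
        self.n_sim = n_sim
        self.alpha = alpha
        self.maf_bin_width = maf_bin_width
        self.seed = seed

    def fit(self, G: GenotypeMatrix, y=None) -> "FstOutlierScan":
        rng = rng_for(self.seed, "fst-scan")
        a, b, c = wc_variance_components(G)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta_obs = a / (a + b + c)
        ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        theta_ml = float(a[ok].sum() / (a + b + c)[ok].sum()) if ok.any() else float("nan")
        self.multilocus_theta_ = theta_ml

        L = G.n_loci
        pvals = np.full(L, 1.0)
        if np.isfinite(theta_ml) and theta_ml > 0:
            pops = G.populations
            sizes = [int((G.pop_labels == pop).sum()) for pop in pops]
            null_theta, null_maf = _simulate_null_thetas(theta_ml, sizes, self.n_sim, rng)

            freq = G.global_allele_freq()
            obs_maf = np.minimum(freq, 1.0 - freq)
            nbins = int(np.ceil(0.5 / self.maf_bin_width))
            obs_bin = np.clip((obs_maf / self.maf_bin_width).astype(float), 0, nbins - 1)
            obs_bin = np.where(np.isfinite(obs_maf), np.floor(obs_bin), -1).astype(int)
            null_bin = np.clip(np.floor(null_maf / self.maf_bin_width), 0, nbins - 1).astype(int)

            for bin_id in range(nbins):
                null_t = np.sort(null_theta[null_bin == bin_id])
                sel = (obs_bin == bin_id) & np.isfinite(theta_obs)
                if not sel.any():
                    continue
                if null_t.size == 0:  # fall back to the full null set
                    null_t = np.sort(null_theta)
                n_ge = null_t.size - np.searchsorted(null_t, theta_obs[sel], side="left")
                pvals[sel] = (1.0 + n_ge) / (1.0 + null_t.size)

        q, flagged = _bh_flag(pvals, self.alpha)
        self.result_ = OutlierScanResult(
            table=pd.DataFrame(
                {"locus": G.locus_ids, "stat": theta_obs, "p": pvals, "q": q, "flagged": flagged}
            ),
            method="fst",
            alpha=self.alpha,
        )
        return self


def _simulate_null_thetas(theta: float, sizes: list[int], n_sim: int, rng):
    """Per-locus WC theta and global MAF for Balding-Nichols null loci."""
    r = len(sizes)
    p_anc = rng.uniform(0.02, 0.98, size=n_sim)
    aa = p_anc * (1.0 - theta) / theta
    bb = (1.0 - p_anc) * (1.0 - theta) / theta
    p_pop = rng.beta(aa[None, :], bb[None, :], size=(r, n_sim))

    n = np.asarray(sizes, dtype=float)[:, None] * np.ones((1, n_sim))
    # genotype counts per pop: binomial draws at HWE within populations
    het = np.empty((r, n_sim))
    p_obs = np.empty((r, n_sim))
    for k, nk in enumerate(sizes):
        g = rng.binomial(2, p_pop[k][None, :], size=(nk, n_sim))
        p_obs[k] = g.mean(axis=0) / 2.0
        het[k] = (g == 1).mean(axis=0)

    n_tot = n.sum(axis=0)
    n_bar = n.mean(axis=0)
    n_c = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
    p_bar = (n * p_obs).sum(axis=0) / n_tot
    s2 = (n * (p_obs - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * het).sum(axis=0) / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        t = a / (a + b + c)
    maf = np.minimum(p_bar, 1.0 - p_bar)
    ok = np.isfinite(t) & np.isfinite(maf)
    return t[ok], maf[ok]


def outlier_scan_pca(G: GenotypeMatrix, n_components: int = 2, alpha: float = 0.05) -> OutlierScanResult:
    return PcaOutlierScan(n_components=n_components, alpha=alpha).fit(G).result_


def outlier_scan_fst(
    G: GenotypeMatrix, n_sim: int = 20_000, alpha: float = 0.05, seed: int | None = 0
) -> OutlierScanResult:
    return FstOutlierScan(n_sim=n_sim, alpha=alpha, seed=seed).fit(G).result_


def outlier_intersection(
    a: OutlierScanResult, b: OutlierScanResult
) -> tuple[set[str], set[str]]:
    """Loci flagged by both scans, and the complementary neutral panel."""
    universe_a = list(a.table["locus"])
    universe_b = list(b.table["locus"])
    if set(universe_a) != set(universe_b):
        raise ValueError("scans cover different locus sets")
    outliers = a.flagged_loci & b.flagged_loci
    neutral = set(universe_a) - outliers
    return outliers, neutral


def genotype_accumulation(
    G: GenotypeMatrix, max_loci: int | None = None, reps: int = 50, seed: int | None = None
) -> pd.DataFrame:
    """Genotype accumulation curve: distinguishable multilocus genotypes as a
    function of the number of loci sampled (without replacement), with the
    mean and variance over ``reps`` resamples per locus count."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng_for(seed, "genotype-accumulation")
    L = G.n_loci
    if max_loci is None:
        max_loci = L
    if max_loci > L:
        import warnings

        warnings.warn(f"max_loci capped at the {L} available loci")
        max_loci = L
    rows = []
    geno = G.genotypes
    for n_loci in range(1, max_loci + 1):
        counts = np.empty(reps)
        for r in range(reps):
            cols = rng.choice(L, size=n_loci, replace=False)
            sub = np.ascontiguousarray(geno[:, cols])
            counts[r] = np.unique(sub, axis=0).shape[0]
        rows.append(
            {
                "n_loci": n_loci,
                "mean_genotypes": counts.mean(),
                "var_genotypes": counts.var(ddof=1) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
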