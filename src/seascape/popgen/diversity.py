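"""Diversity indices and Weir-Cockerham F-statistics.

Observed heterozygosity, Nei's unbiased gene diversity, the inbreeding
coefficient F_IS with a percentile bootstrap over loci, the Weir-Cockerham
(1984) theta estimator of F_ST with locus-bootstrap confidence intervals,
and the population-by-locus minor-allele-frequency matrix that feeds the
ordination stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._utils import rng_for
from ..genotypes import MISSING, GenotypeMatrix


def _per_pop_counts(G: GenotypeMatrix):
    """Per (population, locus): called sample size n, allele frequency p of
    the counted allele, and observed heterozygote fraction h."""
    pops = G.populations
    P, L = len(pops), G.n_loci
    n = np.zeros((P, L))
    p = np.full((P, L), np.nan)
    h = np.full((P, L), np.nan)
    for k, pop in enumerate(pops):
        sub = G.genotypes[G.pop_labels == pop]
        called = sub != MISSING
        nk = called.sum(axis=0).astype(float)
        geno = np.where(called, sub, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pk = geno.sum(axis=0) / (2.0 * nk)
            hk = ((sub == 1) & called).sum(axis=0) / nk
        n[k] = nk
        p[k] = np.where(nk > 0, pk, np.nan)
        h[k] = np.where(nk > 0, hk, np.nan)
    return pops, n, p, h


def wc_variance_components(G: GenotypeMatrix, pops: list[str] | None = None):
    """Weir-Cockerham (1984) per-locus variance components (a, b, c).

    ``a`` is the among-population component, ``b`` the among-individuals-
    within-populations component and ``c`` the within-individuals component;
    theta = sum(a) / sum(a + b + c) over loci.  Loci with fewer than one
    called individual in any population, or with n_c <= 0, are returned as
    NaN and excluded from multilocus sums.
    """
    if pops is not None:
        keep = np.isin(G.pop_labels, pops)
        G = G.subset_individuals(keep)
    labels, n, p, h = _per_pop_counts(G)
    r = len(labels)
    if r < 2:
        raise ValueError("need at least 2 populations")

    valid = np.all(n >= 1, axis=0)
    n_bar = n.mean(axis=0)
    n_tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_tot

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    invalid = ~valid | ~np.isfinite(n_c) | (n_c <= 0) | (n_bar <= 1)
    for comp in (a, b, c):
        comp[invalid] = np.nan
    return a, b, c


def _theta_from_components(a, b, c) -> float:
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0 or not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom)


def multilocus_fst(G: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta over all (or the given) populations."""
    a, b, c = wc_variance_components(G, pops)
    return _theta_from_components(a, b, c)


def _bootstrap_theta(a, b, c, n_boot: int, rng) -> np.ndarray:
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, t = a[ok], (a + b + c)[ok]
    L = a.size
    idx = rng.integers(0, L, size=(n_boot, L))
    num = a[idx].sum(axis=1)
    den = t[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


@dataclass
class FstMatrix:
    """Pairwise Weir-Cockerham theta with percentile-bootstrap 95% CIs."""

    populations: list[str]
    theta: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame

    def display(self) -> pd.DataFrame:
        """Point estimates with negative values truncated to 0."""
        return self.theta.clip(lower=0.0)

    def to_csv(self, path) -> None:
        rows = []
        pops = self.populations
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                rows.append(
                    {
                        "pop_a": pops[i],
                        "pop_b": pops[j],
                        "theta": self.theta.iloc[i, j],
                        "ci_low": self.ci_low.iloc[i, j],
                        "ci_high": self.ci_high.iloc[i, j],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def pairwise_fst(
    G: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None
) -> FstMatrix:
    """Pairwise theta for every population pair, CI by bootstrap over loci."""
    pops = G.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rng = rng_for(seed, "fst-bootstrap")
    P = len(pops)
    theta = np.full((P, P), 0.0)
    lo = np.full((P, P), 0.0)
    hi = np.full((P, P), 0.0)
    for i in range(P):
        for j in range(i + 1, P):
            a, b, c = wc_variance_components(G, [pops[i], pops[j]])
            t = _theta_from_components(a, b, c)
            boots = _bootstrap_theta(a, b, c, n_boot, rng)
            ql, qh = np.nanpercentile(boots, [2.5, 97.5])
            theta[i, j] = theta[j, i] = t
            lo[i, j] = lo[j, i] = ql
            hi[i, j] = hi[j, i] = qh
    mk = lambda arr: pd.DataFrame(arr, index=pops, columns=pops)
    return FstMatrix(pops, mk(theta), mk(lo), mk(hi))


def diversity(G: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Per-population diversity table: N, H_O, H_E, F_IS with bootstrap CI.

    H_O is the heterozygote fraction among called genotypes; H_E is Nei's
    unbiased gene diversity 2p(1-p) * 2n/(2n-1); population values are means
    across the loci called in that population.  F_IS = 1 - mean(H_O)/mean(H_E)
    with a 95% percentile bootstrap over loci; a population is flagged
    significant when the CI excludes 0.
    """
    rng = rng_for(seed, "fis-bootstrap")
    pops, n, p, h = _per_pop_counts(G)
    rows = []
    for k, pop in enumerate(pops):
        ok = n[k] > 0
        nk, pk, hk = n[k][ok], p[k][ok], h[k][ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            he = 2.0 * pk * (1.0 - pk) * (2.0 * nk) / (2.0 * nk - 1.0)
        ho_mean = float(hk.mean())
        he_mean = float(he.mean())
        fis = 1.0 - ho_mean / he_mean if he_mean > 0 else float("nan")

        L = hk.size
        idx = rng.integers(0, L, size=(n_boot, L))
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_fis = 1.0 - hk[idx].mean(axis=1) / he[idx].mean(axis=1)
        lo, hi = np.nanpercentile(boot_fis, [2.5, 97.5])
        n_ind = int((G.pop_labels == pop).sum())
        rows.append(
            {
                "population": pop,
                "N": n_ind,
                "H_O": ho_mean,
                "H_E": he_mean,
                "F_IS": fis,
                "F_IS_ci_low": float(lo),
                "F_IS_ci_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def pop_maf_matrix(G: GenotypeMatrix, impute_missing: bool = True) -> pd.DataFrame:
    """Populations x loci matrix of globally-minor-allele frequencies.

    The minor allele is defined over the full sample (so a population's value
    may exceed 0.5 when its local minor allele differs).  Cells for loci
    uncalled in a population are mean-imputed across populations when
    ``impute_missing`` (required downstream by the ordination).
    """
    pops, n, p, _ = _per_pop_counts(G)
    freq = G.global_allele_freq()
    flip = freq > 0.5
    maf = np.where(flip[None, :], 1.0 - p, p)
    df = pd.DataFrame(maf, index=pops, columns=G.locus_ids)
    if impute_missing:
        df = df.fillna(df.mean(axis=0))
    return df
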