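"""RADseq-style SNP filtering cascade.

Rules are applied in a fixed order — locus missingness, degenerate-F_IS
exclusion, minor-allele frequency, linkage-disequilibrium pruning, and
Hardy-Weinberg departures replicated across populations — with the count
removed at each stage recorded in a report.  The cascade is idempotent:
re-running it on its own output removes nothing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np

from ..genotypes import MISSING, GenotypeMatrix


@dataclass
class FilterParams:
    max_locus_missing: float = 0.25
    maf_min: float = 0.01
    ld_r2_max: float = 0.7
    hwe_alpha: float = 0.01
    hwe_min_pops: int | None = None  # default: ceil(4/7 * n_pops)
    max_indiv_missing: float | None = None  # individual-level screen, off by default

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "maf_min", "ld_r2_max", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-stage locus (and individual) removal counts, in application order."""

    stages: list[dict] = field(default_factory=list)
    individuals_removed: int = 0
    loci_in: int = 0
    loci_out: int = 0

    def record(self, rule: str, n_in: int, n_removed: int, **extra) -> None:
        self.stages.append({"rule": rule, "loci_in": n_in, "removed": n_removed, "retained": n_in - n_removed, **extra})

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def genotypic_r2(locus_a: np.ndarray, locus_b: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1/2 genotype vectors over
    co-called individuals.  NaN (treated as not linked) when either locus has
    zero variance among the co-called individuals."""
    a = np.asarray(locus_a, dtype=float)
    b = np.asarray(locus_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@lru_cache(maxsize=100_000)
def _hwe_exact_cached(n_het: int, n_rare_hom: int, n_common_hom: int) -> float:
    """Exact conditional HWE test by full enumeration of heterozygote counts
    given the allele counts, two-sided via probability ordering."""
    n = n_het + n_rare_hom + n_common_hom
    n_rare = n_het + 2 * n_rare_hom  # copies of the rarer allele
    if n == 0:
        raise ValueError("no genotypes")
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic

    # log P(n_het | n, n_rare) up to a common constant:
    # P ∝ 2^het * n! / (het! * rare_hom! * common_hom!) ... with allele-count terms constant
    def logprob(het: int) -> float:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        return (
            het * math.log(2.0)
            - math.lgamma(het + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (n_het - n_rare % 2) // 2
    p_obs = probs[obs]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value for one locus's genotype counts
    (major-allele homozygotes, heterozygotes, minor-allele homozygotes)."""
    total = n_hom_major + n_het + n_hom_minor
    if total <= 0:
        raise ValueError("total genotype count must be > 0")
    # orient so the 'rare' homozygote really is the rarer allele's
    minor_copies = n_het + 2 * n_hom_minor
    if minor_copies <= total:  # minor allele is the rarer one
        return _hwe_exact_cached(n_het, n_hom_minor, n_hom_major)
    return _hwe_exact_cached(n_het, n_hom_major, n_hom_minor)


def _pairwise_r2_matrix(geno: np.ndarray) -> np.ndarray:
    """All-pairs genotypic r² with pairwise-complete observations, vectorised
    through matrix products.  Pairs where either locus is invariant among the
    co-called individuals get NaN."""
    X = geno.astype(float)
    M = (geno != MISSING).astype(float)
    X = np.where(geno == MISSING, 0.0, X)

    n = M.T @ M                      # co-called counts per pair
    sx = X.T @ M                     # sum of x over co-called, per pair
    sy = sx.T
    sxy = X.T @ X
    sxx = (X * X).T @ M
    syy = sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        r2 = cov**2 / (var_x * var_y)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def _locus_fis_global(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus F_IS = 1 - H_O/H_E over the whole sample (plain 2p(1-p) H_E);
    NaN where monomorphic."""
    called_mask = G.called_mask()
    called = called_mask.sum(axis=0).astype(float)
    geno = np.where(called_mask, G.genotypes, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = geno.sum(axis=0) / (2.0 * called)
        h_obs = ((G.genotypes == 1) & called_mask).sum(axis=0) / called
        h_exp = 2.0 * p * (1.0 - p)
        fis = 1.0 - h_obs / h_exp
    fis[h_exp == 0] = np.nan
    return fis


def filter_pipeline(G: GenotypeMatrix, params: FilterParams | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filtering cascade and report per-stage removals.

    Order: (0, optional) individuals with too much missing data; (1) loci
    missing in more than ``max_locus_missing`` of individuals; (2) loci whose
    overall F_IS is 1, -1 or undefined; (3) loci with global minor-allele
    frequency below ``maf_min``; (4) LD pruning — of each pair with genotypic
    r² above ``ld_r2_max``, the locus with more missing data is dropped (ties
    drop the lexicographically later id); (5) loci out of Hardy-Weinberg
    equilibrium at ``hwe_alpha`` in at least ``hwe_min_pops`` populations
    (default: ceil(4/7 x number of populations)).
    """
    params = params or FilterParams()
    report = FilterReport(loci_in=G.n_loci)

    if params.max_indiv_missing is not None:
        miss = (~G.called_mask()).mean(axis=1)
        keep = miss <= params.max_indiv_missing
        report.individuals_removed = int((~keep).sum())
        if report.individuals_removed:
            G = G.subset_individuals(keep)

    # 1 — locus missingness
    miss = (~G.called_mask()).mean(axis=0)
    keep = miss <= params.max_locus_missing
    report.record("missingness", G.n_loci, int((~keep).sum()), threshold=params.max_locus_missing)
    G = G.subset_loci(keep)

    # 2 — degenerate overall F_IS
    fis = _locus_fis_global(G)
    bad = np.isnan(fis) | (np.abs(np.abs(fis) - 1.0) < 1e-9)
    report.record("fis_exclusion", G.n_loci, int(bad.sum()))
    G = G.subset_loci(~bad)

    # 3 — global MAF
    freq = G.global_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= params.maf_min
    report.record("maf", G.n_loci, int((~keep).sum()), threshold=params.maf_min)
    G = G.subset_loci(keep)

    # 4 — LD pruning
    r2 = _pairwise_r2_matrix(G.genotypes)
    miss_count = (~G.called_mask()).sum(axis=0)
    drop = np.zeros(G.n_loci, dtype=bool)
    ii, jj = np.nonzero(np.triu(r2 > params.ld_r2_max, k=1))
    for i, j in zip(ii, jj):
        if miss_count[i] > miss_count[j]:
            loser = i
        elif miss_count[j] > miss_count[i]:
            loser = j
        else:
            loser = i if G.locus_ids[i] > G.locus_ids[j] else j
        drop[loser] = True
    report.record("ld", G.n_loci, int(drop.sum()), r2_threshold=params.ld_r2_max)
    G = G.subset_loci(~drop)

    # 5 — HWE departures replicated across populations
    pops = G.populations
    min_pops = params.hwe_min_pops or math.ceil(4.0 / 7.0 * len(pops))
    n_fail = np.zeros(G.n_loci, dtype=int)
    for pop in pops:
        sub = G.genotypes[G.pop_labels == pop]
        for j in range(G.n_loci):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            if hwe_test(*counts) <= params.hwe_alpha:
                n_fail[j] += 1
    keep = n_fail < min_pops
    report.record("hwe", G.n_loci, int((~keep).sum()), alpha=params.hwe_alpha, min_pops=min_pops)
    G = G.subset_loci(keep)

    report.loci_out = G.n_loci
    return G, report
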