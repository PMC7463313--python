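"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from seascape import FlowGridSpec, SiteTable, UniformResidual, gen_flow
from seascape.genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written as plain loops, separate from the
# vectorised library code they check)
# ---------------------------------------------------------------------------


def brute_force_theta(G: GenotypeMatrix) -> float:
    """Loop-wise Weir-Cockerham (1984) multilocus theta, transcribed directly
    from the published variance-component formulas."""
    pops = G.populations
    num = den = 0.0
    for j in range(G.n_loci):
        ns, ps, hs = [], [], []
        for pop in pops:
            col = G.genotypes[G.pop_labels == pop, j]
            col = col[col != MISSING]
            if len(col) == 0:
                break
            ns.append(len(col))
            ps.append(col.sum() / (2.0 * len(col)))
            hs.append(float(np.mean(col == 1)))
        else:
            r = len(pops)
            ns_a = np.array(ns, dtype=float)
            ps_a = np.array(ps)
            hs_a = np.array(hs)
            n_bar = ns_a.mean()
            n_tot = ns_a.sum()
            n_c = (n_tot - (ns_a**2).sum() / n_tot) / (r - 1)
            if n_c <= 0 or n_bar <= 1:
                continue
            p_bar = (ns_a * ps_a).sum() / n_tot
            s2 = (ns_a * (ps_a - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (ns_a * hs_a).sum() / n_tot
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2.0
            num += a
            den += a + b + c
    return num / den if den != 0 else float("nan")


def enumeration_hwe_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value by direct enumeration of the conditional genotype
    distribution given allele counts, using exact rational-free arithmetic via
    log-factorials; independent of the library's recurrence/caching."""
    import math

    n = n_hom_major + n_het + n_hom_minor
    n_minor = n_het + 2 * n_hom_minor
    n_major = 2 * n - n_minor
    if min(n_minor, n_major) == 0:
        return 1.0
    rare = min(n_minor, n_major)

    def log_p(het: int) -> float:
        rare_hom = (rare - het) // 2
        common_hom = n - het - rare_hom
        # P(het | allele counts) = n! 2^het / (het! rare_hom! common_hom!) * rare! common! / (2n)!
        return (
            math.lgamma(n + 1)
            + het * math.log(2.0)
            - math.lgamma(het + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    probs = np.exp([log_p(h) for h in hets])
    obs_het = n_het
    p_obs = probs[hets.index(obs_het)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture()
def one_site() -> SiteTable:
    return SiteTable.from_records([{"site_id": "A", "lon": -5.5, "lat": 53.0}])


@pytest.fixture()
def small_grid_spec() -> FlowGridSpec:
    return FlowGridSpec(
        lon_min=-6.5, lon_max=-4.5, lat_min=52.2, lat_max=53.8,
        n_lon=20, n_lat=20, duration_days=3.0, time_step_h=1.0,
    )


@pytest.fixture()
def uniform_east_flow(small_grid_spec):
    """0.1 m/s eastward everywhere, no tide."""
    return gen_flow(small_grid_spec, tidal_amplitude_ms=0.0, residual=UniformResidual(0.1, 0.0))


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    """Two populations of five, four hand-written loci."""
    geno = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 0],
            [0, 2, 1, 1],
            [2, 0, 1, 0],
            [1, 1, 0, 0],
            [2, 2, 0, 1],
            [1, 2, 1, 0],
            [2, 1, 0, 0],
            [2, 2, 1, 1],
            [1, 2, 0, 0],
        ],
        dtype=np.int8,
    )
    pops = np.array(["P1"] * 5 + ["P2"] * 5, dtype=object)
    return GenotypeMatrix(geno, pops, [f"loc{j}" for j in range(4)])
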