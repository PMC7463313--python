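"""SNP genotype matrices, environmental tables, and their generators.

Genotypes are stored as minor-allele counts (0/1/2, -1 = missing) for
individuals x loci, with a population label per individual.  The neutral
generator draws population allele frequencies from the Balding-Nichols model
(Beta-distributed around an ancestral frequency with differentiation
parameter F), which has a closed-form F_ST expectation and therefore supports
exact recovery tests.  A small set of loci can instead follow an
environmental gradient on the logit scale, emulating loci under spatially
varying selection; an optional weak spatially structured component can be
added to the neutral loci to emulate isolation by distance / current-driven
gene flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_for
from .sites import SiteTable

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci minor-allele counts with population labels."""

    genotypes: np.ndarray      # int8, values {0, 1, 2, MISSING}
    pop_labels: np.ndarray     # object, one per individual
    locus_ids: list[str]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, L = self.genotypes.shape
        if self.pop_labels.size != n:
            raise ValueError("one population label per individual required")
        if len(self.locus_ids) != L:
            raise ValueError("one locus id per column required")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, missing}")
        counts = pd.Series(self.pop_labels).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"populations with fewer than 2 individuals: {small}")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i:04d}" for i in range(n)]
        elif len(self.individual_ids) != n:
            raise ValueError("one individual id per row required")

    # -- shapes and views ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_equal(self.genotypes, MISSING)

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            idx = keep
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            pop_labels=self.pop_labels,
            locus_ids=[self.locus_ids[i] for i in idx],
            individual_ids=self.individual_ids,
        )

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.nonzero(keep)[0]
        else:
            idx = keep
        return GenotypeMatrix(
            genotypes=self.genotypes[idx],
            pop_labels=self.pop_labels[idx],
            locus_ids=list(self.locus_ids),
            individual_ids=[self.individual_ids[i] for i in idx],
        )

    def global_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per locus, over called genotypes."""
        m = self.masked()
        return (m.sum(axis=0) / (2.0 * m.count(axis=0))).filled(np.nan)

    # -- I/O -------------------------------------------------------------------
    def to_tsv(self, genotype_path, popmap_path=None) -> None:
        vals = self.genotypes.astype(object)
        vals[self.genotypes == MISSING] = pd.NA
        df = pd.DataFrame(vals, index=self.individual_ids, columns=self.locus_ids)
        df.to_csv(genotype_path, sep="\t", index_label="individual", na_rep="NA")
        if popmap_path is not None:
            pd.DataFrame({"individual": self.individual_ids, "population": self.pop_labels}).to_csv(
                popmap_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, genotype_path, popmap_path) -> "GenotypeMatrix":
        df = pd.read_csv(genotype_path, sep="\t", index_col="individual", na_values=["NA"])
        popmap = pd.read_csv(popmap_path, sep="\t").set_index("individual")
        pops = popmap.loc[df.index, "population"].to_numpy(dtype=object)
        geno = df.fillna(MISSING).to_numpy(dtype=np.int8)
        return cls(geno, pops, list(df.columns), individual_ids=list(df.index))

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Write a minimal VCF (GT only, one biallelic record per locus)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.individual_ids) + "\n")
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, lid in enumerate(self.locus_ids):
                gts = "\t".join(gt_map[int(g)] for g in self.genotypes[:, j])
                fh.write(f"{chrom}\t{j + 1}\t{lid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path, popmap_path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        locus_ids: list[str] = []
        rows: list[np.ndarray] = []
        for k, rec in enumerate(vcf):
            locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            g = rec.gt_types.astype(np.int8)
            g = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING)
            rows.append(g)
        popmap = pd.read_csv(popmap_path, sep="\t").set_index("individual")
        pops = popmap.loc[individuals, "population"].to_numpy(dtype=object)
        return cls(np.column_stack(rows), pops, locus_ids, individual_ids=individuals)


@dataclass
class EnvTable:
    """Per-site environmental variables (one row per site)."""

    table: pd.DataFrame  # index = site_id

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.table.to_numpy(dtype=float))):
            raise ValueError("environmental table must be finite")

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def standardized(self, var: str) -> np.ndarray:
        x = self.table[var].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="site_id")

    @classmethod
    def read_csv(cls, path) -> "EnvTable":
        return cls(pd.read_csv(path, index_col="site_id"))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

MONTHS = ("apr", "may", "jun", "jul", "aug", "sep")
# seasonal baselines (deg C) for a temperate shelf sea: monthly mean SST,
# offset of monthly-minimum SST below the mean, and mean surface-bottom
# temperature difference (stratification peaks mid-summer)
_SST_MEAN_BASE = {"apr": 9.5, "may": 11.0, "jun": 13.0, "jul": 15.0, "aug": 15.5, "sep": 14.5}
_SST_MIN_OFFSET = 1.5
_SBTD_MEAN_BASE = {"apr": 0.1, "may": 0.5, "jun": 1.2, "jul": 2.0, "aug": 1.8, "sep": 1.0}


def gen_env_table(
    sites: SiteTable,
    gradient_axis: str = "lat",
    slope_per_degree: float = 1.0,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> EnvTable:
    """Synthesise monthly SST (mean, min) and SBTD (mean) per site.

    Every variable is a linear function of site position along
    ``gradient_axis`` ('lat' or 'lon') plus i.i.d. Gaussian noise; the
    default slope spans a few degrees C across a typical sampling domain.
    """
    if len(sites) == 0:
        raise ValueError("site table is empty")
    if gradient_axis not in ("lat", "lon"):
        raise ValueError("gradient_axis must be 'lat' or 'lon'")
    rng = rng_for(seed, "env-table")
    pos = sites.lat if gradient_axis == "lat" else sites.lon
    s = pos - pos.mean()

    cols = {}
    for month in MONTHS:
        base_mean = _SST_MEAN_BASE[month]
        cols[f"sst_mean_{month}"] = base_mean + slope_per_degree * s + rng.normal(0, noise_sd, len(sites))
        cols[f"sst_min_{month}"] = (
            base_mean - _SST_MIN_OFFSET + slope_per_degree * s + rng.normal(0, noise_sd, len(sites))
        )
        cols[f"sbtd_mean_{month}"] = (
            _SBTD_MEAN_BASE[month] + 0.3 * slope_per_degree * s + rng.normal(0, 0.3 * noise_sd, len(sites))
        )
    return EnvTable(pd.DataFrame(cols, index=pd.Index(sites.site_ids, name="site_id")))


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_genotypes(
    n_pops: int = 7,
    n_per_pop: int = 20,
    n_loci: int = 2000,
    target_fst: float = 0.02,
    n_outlier_loci: int = 0,
    env: EnvTable | None = None,
    env_var: str | None = None,
    outlier_effect: float = 0.0,
    missing_rate: float = 0.0,
    spatial_score: np.ndarray | None = None,
    spatial_effect: float = 0.0,
    pop_ids: list[str] | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a SNP panel with weak neutral structure and optional outliers.

    Neutral loci: ancestral frequency p ~ U(0.05, 0.95); population
    frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``target_fst``
    (Balding-Nichols; F -> 0 collapses to identical frequencies).  The last
    ``n_outlier_loci`` loci instead follow
    logit(p_pop) = logit(p) + outlier_effect * z_env, where z_env is the
    standardized environmental variable per population.  If ``spatial_score``
    is given (one value per population), neutral-locus logits receive an
    additional spatial_effect * z_score * b_l shift with b_l ~ N(0, 1) per
    locus, producing spatially autocorrelated neutral structure; the default
    (0) is the pure Balding-Nichols model.  Genotypes ~ Binomial(2, p_pop),
    re-polarised so values count the globally minor allele; entries are set
    missing i.i.d. at ``missing_rate``.
    """
    if not (0.0 <= target_fst < 1.0):
        raise ValueError("target_fst must be in [0, 1)")
    if n_outlier_loci > n_loci:
        raise ValueError("n_outlier_loci must be <= n_loci")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if n_outlier_loci > 0 and outlier_effect != 0.0 and (env is None or env_var is None):
        raise ValueError("outlier loci with nonzero effect require env and env_var")

    rng = rng_for(seed, "genotypes")
    if pop_ids is None:
        pop_ids = (
            list(env.site_ids)[:n_pops] if env is not None and len(env.site_ids) >= n_pops
            else [f"pop{i + 1}" for i in range(n_pops)]
        )
    if len(pop_ids) != n_pops:
        raise ValueError("pop_ids length must equal n_pops")

    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    F = target_fst
    if F > 0:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_pop = rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))
    else:
        p_pop = np.tile(p_anc, (n_pops, 1))

    if spatial_score is not None and spatial_effect != 0.0:
        z = np.asarray(spatial_score, dtype=float)
        if z.size != n_pops:
            raise ValueError("spatial_score needs one value per population")
        z = (z - z.mean()) / (z.std(ddof=0) or 1.0)
        b_l = rng.normal(0.0, 1.0, size=n_loci)
        shift = spatial_effect * np.outer(z, b_l)
        p_pop = _expit(_logit(np.clip(p_pop, 1e-6, 1 - 1e-6)) + shift)

    is_outlier = np.zeros(n_loci, dtype=bool)
    if n_outlier_loci > 0:
        is_outlier[-n_outlier_loci:] = True
        if outlier_effect != 0.0:
            z_env = env.standardized(env_var)[:n_pops]
            shift = outlier_effect * z_env[:, None]
            p_pop[:, is_outlier] = _expit(_logit(p_anc[None, is_outlier]) + shift)

    pops = np.repeat(np.asarray(pop_ids, dtype=object), n_per_pop)
    geno = np.empty((n_pops * n_per_pop, n_loci), dtype=np.int8)
    for k in range(n_pops):
        geno[k * n_per_pop : (k + 1) * n_per_pop] = rng.binomial(
            2, p_pop[k][None, :], size=(n_per_pop, n_loci)
        )

    # re-polarise to the globally minor allele
    freq = geno.mean(axis=0) / 2.0
    flip = freq > 0.5
    geno[:, flip] = 2 - geno[:, flip]

    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING

    locus_prefix = np.where(is_outlier, "outl", "snp")
    locus_ids = [f"{locus_prefix[j]}_{j:05d}" for j in range(n_loci)]
    return GenotypeMatrix(geno, pops, locus_ids)
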