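# seascape

A seascape-genomics toolkit for marine species with pelagic larvae. It couples
a Lagrangian larval-dispersal simulator with population-genomic analysis and
spatial eigenfunction regression, so that the question *"is the genetic
structure of these populations explained by geography, by current-driven
larval transport, or by the environment?"* can be answered — and, because
every input can be synthesised with known ground truth, the whole chain can be
validated end to end.

## Who it is for

Population geneticists and biophysical modellers working on benthic or
sessile marine species (bivalves, gastropods, many fish) whose adults do not
move but whose larvae drift on ocean currents for weeks. For such species,
connectivity between beds or estuaries is set by hydrodynamics during a short
pelagic larval duration (PLD), and management units must be inferred jointly
from genomic markers and transport modelling.

## What it computes

**Larval transport.** Particles are released in daily cohorts (default
750/day at 12:00 over 16 days — 12,000 per site, spanning a spring–neap
cycle), advected through a gridded velocity field (RK4, bilinear in space,
linear in time), and settle at the first trajectory sample aged 30–40 days
that passes within 10 km of a settlement site. Settlement counts become a
connectivity matrix `C[i,j] = P(settle at j | released at i)` with the number
*released* as denominator, plus self-recruitment summaries and dispersal
density maps.

**Population genomics.** A RADseq-style SNP filter cascade (missingness >
25 %, degenerate F_IS, MAF < 0.01, LD pruning at r² > 0.7, HWE departures
replicated across populations); observed/expected heterozygosity and F_IS
with locus bootstraps; Weir–Cockerham (1984) θ,

&nbsp;&nbsp;&nbsp;&nbsp;θ = Σ_l a_l / Σ_l (a_l + b_l + c_l),

with percentile bootstrap CIs over loci; and two outlier scans — a
PCA-regression scan (Mahalanobis distance of per-locus z-scores, genomic
inflation factor, Benjamini–Hochberg q-values) and a parametric-bootstrap
F_ST scan against a Balding–Nichols null matched by minor-allele-frequency
bin. Candidate adaptive loci are those flagged by *both* scans.

**Spatial eigenfunctions.** Geographic structure enters as distance-based
Moran's eigenvector maps (dbMEM, the classical PCNM construction: distances
truncated at the longest minimum-spanning-tree edge, Gower-centred,
eigen-decomposed); directional transport enters as asymmetric eigenvector
maps (AEM) built from the sites-by-edges matrix of the directed connectivity
graph.

**Environmental association.** Population minor-allele frequencies are
Hellinger-transformed and regressed on the candidate predictors (dbMEMs,
AEMs, sea-surface temperature and stratification variables) by redundancy
analysis (RDA): R² = SS(Ŷ)/SS(Y) with the Ezekiel adjustment, permutation
ANOVA (Freedman–Lane under conditioning), and forward selection with a
global pre-test and a double stopping rule.

**Synthetic generators.** Tidal + residual flow fields; Balding–Nichols
genotypes (population allele frequencies Beta-distributed around an ancestral
frequency with differentiation F) with optional environment-driven outlier
loci and a spatially autocorrelated neutral component; per-site monthly
SST/SBTD tables.

## Worked example

The bundled synthetic study places seven sites ~57 km apart along a coast, in
a strong oscillatory tide (0.4 m/s M2) over a weak 0.02 m/s eastward residual
drift — so each site's larvae reach the next site downstream during the
30–40-day settlement window:

```python
import seascape as ss
from seascape.study import physical_stage, genetic_replicate

bases = physical_stage()                       # PTM -> connectivity -> dbMEM/AEM
print(bases.connectivity.to_dataframe().round(2))
rep = genetic_replicate(bases, seed=11)        # genotypes -> scans -> RDA selection
print(f"Multilocus F_ST: {ss.popgen.multilocus_fst(rep.genotypes):.4f}")
print("Outliers (both scans):", len(rep.outlier_loci))
print("Outlier panel selected:", rep.outlier_trace.selected)
print("Neutral panel selected:", rep.neutral_trace.selected)
```

prints

```
     S1   S2   S3   S4   S5   S6   S7
S1  0.0  1.0  0.0  0.0  0.0  0.0  0.0
S2  0.0  0.0  1.0  0.0  0.0  0.0  0.0
S3  0.0  0.0  0.0  1.0  0.0  0.0  0.0
S4  0.0  0.0  0.0  0.0  1.0  0.0  0.0
S5  0.0  0.0  0.0  0.0  0.0  1.0  0.0
S6  0.0  0.0  0.0  0.0  0.0  0.0  1.0
S7  0.0  0.0  0.0  0.0  0.0  0.0  0.0
Multilocus F_ST: 0.0384
Outliers (both scans): 15
Outlier panel selected: ['sst_min_apr']
Neutral panel selected: ['AEM1']
```

The connectivity matrix is the designed downstream chain; the weak tidal-only
net transport means nothing moves upstream. Forward selection recovers the
planted drivers: the 15 candidate adaptive loci follow April minimum SST
(adjR² = 0.88, permutation p = 0.005), while the spatially autocorrelated
neutral background is explained by the first asymmetric eigenvector of the
transport network (AEM1) rather than by any temperature variable.

A YAML-configured end-to-end run (`seascape run --config config.yaml`) writes
connectivity CSVs, filter reports, scan tables, eigenfunction bases and RDA
results with provenance headers and a checksummed manifest; see
`seascape.pipeline.PipelineConfig` for the schema.

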