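# Methods

This note documents the models, numerical choices and limitations behind the
package, stage by stage.

## Flow fields and the synthetic circulation

Velocity fields are 2-D (depth-averaged) `u, v` on a regular lon/lat/time
grid. The generator composes a rectilinear tidal oscillation
`A·sin(2πt/T + φ)` along a fixed compass axis with a time-invariant residual
component: a uniform drift, a Gaussian-ring gyre, or a Gaussian zonal front
jet. Defaults (tide 0.5 m/s at the 12.42 h M2 period; residuals < 0.1 m/s)
reproduce the regime of tidally energetic shelf seas, where tides move larvae
tens of kilometres but cancel over a cycle and net transport is set by weak,
persistent density-driven currents. The optional random phase is the only
stochastic element, so fields are reproducible by construction.

What this stand-in does **not** emulate: 3-D shear and stratification
dynamics, wind-driven variability, and realistic coastlines. Tests that pass
on these fields validate the *machinery* (integration, interpolation,
settlement accounting, eigenfunction construction), not any particular sea.

## Particle tracking

- **Release**: cohorts of 750 particles per site per day at 12:00 over the
  first 16 days of a month (12,000 per site), spanning a spring–neap cycle.
- **Integration**: RK4 by default (`dt = 360 s`); forward Euler retained for
  cross-checks. Positions update in degrees through local metres-per-degree
  factors (111,194 m/° latitude; ×cos(lat) for longitude) — exact enough at
  regional scale and projection-free.
- **Interpolation**: bilinear in lon/lat, linear in time; exact at grid
  nodes and sample times. Positions surrounded entirely by land cells get
  zero velocity and a land flag.
- **Land policy**: `slide` (zero the offending displacement component;
  preserves along-coast transport) by default; `halt` and `reflect`
  selectable. Particles that leave the grid are frozen at the exit point,
  flagged, and counted as unsettled.
- **Settlement**: trajectory samples (hourly) with particle age inside the
  30–40-day competency window are scanned in order; the first sample within
  10 km (great-circle) of any site settles the particle there —
  first-contact-and-stop. Several sites in range at one sample: nearest
  wins, exact ties break lexicographically on site id. Hourly sampling
  cannot miss a crossing because the 10 km radius far exceeds hourly
  displacement at realistic speeds (≤ 0.5 m/s → ≤ 1.8 km/h).
- **Diffusion**: an optional seeded random-walk term exists but is off by
  default; the transport model is deterministic.

Crediting only the first site contacted (rather than every site passed) is a
deliberate reading of an ambiguous rule; both are countable from the same
trajectories, and the counting function is separate from the integrator so
the alternative is a small change.

## Connectivity

`C[i,j]` = settled-at-j / released-from-i, so each row sum plus the
unsettled fraction is exactly 1 on integer counts. Monthly matrices are
first-class; the seasonal network is their element-wise mean, and the "±" on
self-recruitment is the sample SD of the diagonal across months. Dispersal
maps are per-source position histograms normalised by contributing samples,
with out-of-grid mass reported separately. Map/matrix similarity is the
squared Pearson correlation of flattened entries, undefined (an error) when
either input has zero variance. Larval output is not weighted by population
abundance — the matrices are per-released-particle probabilities.

## Genotype and environment generators

Neutral loci follow the Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.95), population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F the target differentiation (0.02 by default, the weak-structure regime of
fine-scale marine studies); F → 0 degenerates cleanly to identical
frequencies. The closed-form F_ST expectation is what makes exact recovery
tests possible. Outlier loci instead take
logit(p_pop) = logit(p) + β·z_env with z_env the standardized environmental
variable per population — a clinal-selection caricature with tunable effect
β (2.0 in the bundled study, which yields per-locus θ an order of magnitude
above the neutral background, matching the separation real scans rely on).

An optional third layer adds spatially autocorrelated neutral structure:
logit shifts `γ·z_site·b_l` with b_l ~ N(0,1) per locus and z_site a
standardized site score (e.g. position along the transport axis). Pure
Balding–Nichols frequencies are i.i.d. across populations and therefore
carry no geography for an ordination to find; the spatial layer (γ = 0.10 in
the bundled study, default 0 = off) emulates isolation by distance and
current-mediated gene flow so that end-to-end variable recovery is a
meaningful test. It raises realised multilocus F_ST above the Balding–Nichols
target (the spatial variance adds to the drift variance), which mirrors how
overall differentiation exceeds the "neutral i.i.d." component in real data.

Genotypes are Binomial(2, p_pop), re-polarised so values count the globally
minor allele; missingness is i.i.d. (the real mechanism is unknown — do not
expect missingness-driven artefacts to be represented). Environment tables
are linear functions of site position along a chosen axis plus Gaussian
noise, with seasonal baselines (April–September SST means 9.5–15.5 °C,
surface–bottom temperature difference peaking in July) typical of a
temperate shelf sea; per-site values are order-of-magnitude realistic, not
calibrated to any particular region.

## SNP filtering

Rules run in a fixed order — locus missingness > 0.25; overall F_IS ∈ {1,
−1, undefined} (monomorphic loci fall here, since their F_IS is undefined);
global MAF < 0.01; LD pruning; HWE — because order changes results; the
report records per-stage removals. LD pruning computes all-pairs genotypic
r² on pairwise-complete observations and, for each pair above 0.7, drops the
locus with more missing data (ties drop the lexicographically later id);
this is idempotent, since each offending pair loses one member. The HWE rule
removes loci out of equilibrium at p ≤ 0.01 in at least ⌈4/7·n_pops⌉
populations (the 4-of-7 design generalised); the test is the exact
conditional test (full enumeration of heterozygote counts given allele
counts, two-sided by probability ordering), chosen over χ² because per-site
samples are small (tens of individuals).

## Diversity and F_ST

H_O is the called-heterozygote fraction; H_E is Nei's unbiased gene
diversity 2p(1−p)·2n/(2n−1); population values are means over the loci
called in that population, and F_IS = 1 − mean(H_O)/mean(H_E) (ratio of
averages, as in standard hierarchical-F packages) with a 95 % percentile
bootstrap over loci; "significant" means the CI excludes 0. Pairwise and
multilocus F_ST is Weir–Cockerham (1984) θ — ratio of summed variance
components over loci — with percentile bootstrap CIs (1,000 resamples over
loci by default). Loci with no called individuals in a population, or with
non-positive n_c, are excluded from the sums. Negative point estimates are
kept internally and truncated to zero only for display.

The population × locus MAF matrix uses the *globally* minor allele, so a
population whose local minor allele differs can show a frequency above 0.5.
Cells for loci uncalled in a population are mean-imputed across populations
(the ordination requires a complete matrix).

## Outlier scans

**PCA scan.** Genotypes are centred by 2p̂ and scaled by √(2p̂(1−p̂)),
missing entries mean-imputed, loci below a MAF floor (0.01) excluded. Each
locus is regressed on the K leading principal components (K is a user
choice; the scree is exported); the z-score vectors are combined into a
Mahalanobis distance, rescaled by the genomic inflation factor
λ = median(d²)/χ²_K(0.5), and referred to F(K, n−K−1); Benjamini–Hochberg
q-values flag loci at q ≤ 0.05. Two numerical choices matter and were made
after explicit calibration experiments (the suite re-runs them):

- the covariance of the z-vectors is estimated *empirically* by default.
  A minimum-covariance-determinant estimate (available via `robust=True`)
  trims the heterogeneous-variance tail of the z-cloud under weak structure
  and then over-flags: the inflation factor only anchors the bulk of the
  distribution, not the tail.
- the reference distribution is F(K, n−K−1), the exact small-sample law for
  Hotelling-type statistics built from t-distributed scores; χ²_K is
  anti-conservative in the far tail at n in the low hundreds, which is
  where Benjamini–Hochberg operates.

**F_ST scan.** A parametric bootstrap: `n_sim` (20,000) neutral loci are
simulated under Balding–Nichols at the observed multilocus θ and observed
per-population sample sizes, binned by global MAF (width 0.05), and each
observed locus is ranked against its bin: p = (1 + #null θ ≥ θ_obs)/(1 +
#matched), then BH. The per-bin permutation floor bounds the smallest
achievable p; detecting a *single* outlier among L loci needs
n_sim ≳ 10·L/α in the relevant bin. When θ̂ ≤ 0 every p is 1. This is a
deliberately simple, fully documented null — its claim is calibration on
synthetic data, not equivalence to any MCMC-based scan.

Candidate adaptive loci are the **intersection** of the two scans' flags;
the complement is the neutral panel. Intersecting deliberately trades power
for a lower false-discovery rate.

## Spatial eigenfunctions

Sites project to local Cartesian metres (y = R·Δlat; x = R·cos(lat_site)·Δlon,
eastings along each site's own parallel — pairwise distances stay within 1 %
of great-circle over a few-degree domain). dbMEM follows the classical PCNM
recipe: Euclidean distances, truncation at the longest minimum-spanning-tree
edge, distances beyond it replaced by 4t, Gower double-centring of −D²/2,
eigen-decomposition, eigenvectors with eigenvalue > 1e−8 of the maximum
retained and scaled by √eigenvalue. Modern Moran's-I-positive selection
variants are intentionally not used. On a regular transect the leading
eigenfunctions are sinusoids (the first a full period, not a monotone
gradient — a property of the 4t fill), verified exactly against an
independent R implementation.

AEM builds the sites × edges matrix E (E[i,e] = 1 iff edge e lies on a
directed path from a virtual upstream origin to site i), weights columns by
edge probability, centres, and takes the SVD; AEMs are left singular vectors
(centred, unit-norm), eigenvalues the squared singular values. The origin
feeds every in-degree-0 node with unit weight. Origin-feed edges are kept as
columns of E by default; `include_origin_edges=False` drops them, removing
contrasts that reflect only the arbitrary attachment (relevant when several
disconnected sites hang off the origin). Raw connectivity probabilities are
used as weights (no resistance transform); the edge threshold is
configurable, default 0 (any positive probability is a link). Eigenvector
signs are fixed by making the largest-magnitude loading positive, for
reproducibility across linear-algebra backends.

## Redundancy analysis

Responses are Hellinger-transformed (row relative abundance, then square
root; all-zero rows are flagged and left at zero) — the transformation alone,
with no additional detrending. RDA column-centres Y and X, drops aliased
predictor columns with a warning (greedy rank test, tolerance 1e−9), fits
Ŷ = X(XᵀX)⁻¹XᵀY, and decomposes Ŷ by SVD; R² = SS(Ŷ)/SS(Y),
adjR² = 1 − (1−R²)(n−1)/(n−m−1). Partial RDA residualises Y and X on the
conditioning set and reports the semi-partial R² (against the *total* SS of
Y), so orthogonal decompositions are exactly additive; an empty conditioning
set reduces bit-for-bit to plain RDA.

Permutation ANOVA uses pseudo-F = (SS(Ŷ)/m)/(SS(res)/(n−m−q−1)), free row
permutation for global tests and Freedman–Lane residual permutation under
conditioning, p = (exceedances + 1)/(n_perm + 1), always seeded. Saturated
models (m + q ≥ n − 1) are refused with an error — with only a handful of
populations this guard binds quickly and is why variable subsets must be
tested in small groups.

Forward selection is greedy with three guards: (1) a global significance
pre-test of the full candidate model at α — the step that keeps the null
selection rate near nominal; (2) the marginal permutation test of each
candidate given the selected set, at α; (3) the adjusted-R² ceiling of the
full candidate model. When the full model is saturated (more candidates than
populations minus two, as in the bundled seven-site study) guards (1) and
(3) are infeasible and are skipped; the per-step test remains.

## The bundled study and problem sizes

The packaged synthetic study chains seven sites ~57 km apart under a 0.02 m/s
residual drift so that the 30–40-day window lands each cohort on the next
site downstream, giving a six-edge directed connectivity chain whose first
AEM is a gradient along the transport axis. Genetic replicates use 7 × 20
individuals × 600 loci (15 outlier loci, β = 2.0, spatial layer γ = 0.10,
2 % missingness). The tracking stage runs 25 particles/day × 4 days per site
at dt = 900 s: with a deterministic flow the realised chain is identical at
the full 750 × 16 schedule, and the smaller cohorts keep a full
25-replicate recovery experiment inside a routine test run. Calibration
suites use 50 null replicates (scans), 200 (permutation type-I), and 20
seeds at 7 × 20 × 2,000 loci (Balding–Nichols recovery).

## Known limitations

- Transport is single-generation; multi-generation (stepping-stone) gene
  flow, which reshapes real spatial structure, is outside the model.
- 2-D depth-averaged advection; no vertical behaviour, mortality or growth.
- The F_ST-scan null conditions on the global multilocus θ; strong
  hierarchical structure among populations would miscalibrate it.
- The equirectangular projection and the per-step metres-per-degree update
  degrade beyond a few degrees of latitude span.
- The environment generator produces linear gradients plus noise; real
  covariance among monthly temperature variables (strong collinearity,
  shared seasonality) is only partly represented, so variable-identity
  recovery on real data will be harder than on synthetic tables.
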