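# Methods

## Biostratigraphic origin estimation

The preservation model treats the distinct fossil-bearing horizons of a
family as a homogeneous Poisson sample over the lineage's true
stratigraphic range. Conditional on the horizon count `N_h`, the horizon
ages are order statistics of a uniform distribution, which makes the gap
between the true origin and the oldest horizon, measured in units of the
observed range `R`, pivotal. That pivot yields the classical
range-extension confidence limit

    CI_alpha = y + f * R * ((1 - alpha)^(-1/(N_h - 1)) - 1)

and the unbiased ML origin estimate `y + (y - z)/(N_h - 1)`. Both need
`N_h >= 2` and `R > 0`; families failing that are carried through tables
with a status flag instead of numbers. The test suite validates the closed
forms against a Monte-Carlo oracle: on simulated uniform records the
one-tailed 95% limit is exceeded by the true origin 5% of the time
(±1.5% binomial error over 2,000 records with 3–20 horizons), and the mean
point estimate over 10,000 records (10 horizons each) sits within 2% of
the true range extension of the true origin. These sizes run in seconds
and give roughly two-sigma sensitivity, which we consider adequate for a
correctness (as opposed to power) check.

Conventions: ages are Ma and increase into the past; distinct ages define
horizons (ties collapse — horizons count strata, not specimens);
interval-dated occurrences use the interval midpoint by default with an
`interval_policy="oldest"` alternative, since occurrence compendia rarely
state their convention; the `articulated_only` switch restricts records to
articulated/associated material for more conservative first appearances.

The `CI_0.5,10%` sensitivity variant is implemented as a multiplicative
factor `f = 10` on the range extension: if preservation before the first
appearance ran at 10% of the within-range rate, expected gaps there are
stretched tenfold. This is the simplest model consistent with "an order of
magnitude higher during the observed range", and it makes the variant
exactly linear in `f` (tested).

## Truncated-Cauchy soft-bound calibrations

A minimum bound `L(t_min, p, c)` with left tail probability
`pL = 0.025` has, above `t_min`, a Cauchy density with location
`t_min(1+p)` and scale `c*t_min`, truncated at `t_min` and renormalized to
mass `1 - pL`; below `t_min` the density is the standard thin power tail
`pL * theta/t_min * (t/t_min)^(theta-1)` with `theta` chosen for
continuity at `t_min`. Quantile and CDF are exact (scipy Cauchy ppf/cdf
plus the closed-form tail), and agree to 1e-8 round-trip.

**Solving the scale from a bound pair.** Published calibration tables give
`(t_min, t_max, p)` and the solved `c`; exactly which quantile the "97.5%
soft maximum" denotes is not algebraically fixed by that phrasing, so
`solve_scale_c` implements three conventions for the renormalized upper
component's mass `r` above `t_max`:

- `matched` (default): `r = pL/(1 - 2*pL) = 0.025/0.95`,
- `prior`: `r = pL/(1 - pL)` (t_max is the 97.5% quantile of the full
  calibration prior),
- `component`: `r = pL` (97.5% quantile of the upper component alone).

The default was determined by calibrating against the bundled reference
set of five percomorph calibrations: re-solving under `matched` reproduces
four of the five published scales to within 0.2% (printed rounding), while
`prior` lands ~2.3% and `component` ~4.5% away. The three differ by only a
few percent, but the data are unambiguous about which one generated the
published numbers.

**A published inconsistency.** The reference scale for the
Gadus/Polymixia calibration (bounds 93.9 → 125.0 Ma) is `0.00180` as
published, but no convention comes near it: the bounds imply `c ≈ 0.0180`
under the same convention that reproduces the other four rows, and the
published value would put only ~0.24% (not 2.5%) of the prior mass above
125 Ma. We conclude the published value dropped a decimal place; the
package reports the solved value and flags the discrepancy wherever that
calibration is printed.

Root finding is bisection (Brent) on `log10(c)` in `[-8, 3]`; the
component tail is strictly increasing in `c`, so the objective is monotone
and the bracket safe. Emitted calibration text uses MCMCTREE's 100-My time
unit by default and appends a control-file stub (burn-in 10,000, sampling
every 50 cycles, 10,000 samples) recording the dating settings this
package prepares inputs for; the MCMC itself is out of scope.

## Timescale concordance

Molecular ages are paired with fossil-based ML origin estimates at the
*stem* node (parent of the family's MRCA; for a single sampled tip, the
tip's parent), because the fossil estimates pertain to total groups and
the stem node is the total-group origin in a sampled phylogeny. A `crown`
switch exists for sensitivity. Only estimable families enter the RSS;
signed residuals (molecular − paleontological) are exposed alongside so
directional bias is visible. Scheme differences over a node-age table are
the mean and SD of per-node absolute differences in posterior means; the
SD is the sample SD (`ddof=1`) by default with the population SD behind a
flag, since published "±SD" values rarely state the divisor.

## Supermatrix coding

Concatenation orders protein genes, then rRNA, then tRNA, padding missing
taxa with gaps and logging every pad; ND6 is excluded by default for its
heterogeneous base composition. RY-coding applies only at third codon
positions: A/G/R → A, C/T/Y → C, gaps and `?` preserved, and every IUPAC
symbol that mixes the purine and pyrimidine classes (W, S, K, M, B, D, H,
V, N, X) → N; the map is idempotent and exhaustively tested against the
IUPAC ambiguity table. Translation uses Biopython's vertebrate
mitochondrial code (ATA = Met, TGA = Trp; AGA/AGG are stops); all-gap
codons become `-`, partially gapped or ambiguous codons `X`, and internal
stops translate to `*` with a positioned warning.

Output columns are regrouped into contiguous partition blocks (pos1, pos2,
pos3, rRNA, tRNA — or aa, rRNA, tRNA), giving the documented 5/5/4/3
partition counts; a per-column provenance map retains each column's source
gene and phase. Internal coordinates are 0-based half-open; emitted
partition files are 1-based inclusive (`DNA, pos1 = 1-140`), the
convention of partitioned-ML input files. tRNA genes form a single
partition (the published partition counts imply one, not a stem/loop
split).

## Ancestral depth reconstruction

Species depths are means of the reported minimum and maximum; species
missing either bound are excluded, not imputed. The reconstruction is the
re-rooting contrasts procedure: the ML estimate at an internal node equals
the Felsenstein pruning (contrast) state at the root of the tree re-rooted
at that node. It is implemented as Gaussian message passing on the
unrooted tree — each neighbour contributes a subtree message `(m, v)` and
the nodal estimate is their precision-weighted mean — which makes
root-position invariance structural rather than numerical. The estimates
coincide with the joint GLS reconstruction (tested against an explicit
Laplacian solve to 1e-8 on randomized trees, and against a
covariance-matrix GLS for the root).

The Brownian rate is profiled out of the state estimates; reported nodal
variances use the contrasts-estimated rate (mean squared standardized
contrast). Zero-length cherries are handled by the limit rule (exact
constraints; conflicting exact constraints average, with a log note).
Branch profiles interpolate linearly in elapsed time between the endpoint
estimates — the behaviour of the standard contrast-based visualization —
with endpoints matching the node estimates exactly; we treat the linear
rule as an interpretation of the cited interpolation equation rather than
a verified reimplementation of any particular tool's code path. The
epipelagic/mesopelagic boundary is fixed at 200 m (the euphotic-zone
limit).

## Synthetic data and what it does not show

Generators are seeded and bit-reproducible. Fossil horizons come from a
(piecewise) Poisson process — uniform preservation by default, with a
two-rate variant whose boundary defaults to the simulated first
appearance; the defaults (rates 0.1–0.5 horizons/My, 15-family census
2/3/10) mirror the structure of the empirical record. Chronograms are
coalescent-style ultrametric trees with strictly positive branches; traits
evolve by exact BM increments; paired timescales use Gaussian noise
(default SD 5 My) and a constant inter-scheme bias (default 16 My, the
scale of the reported within-radiation scheme offset); codon alignments
are i.i.d. codons with stop-codon rejection (note this shifts
third-position base frequencies slightly: 28 of the 60 accepted
equal-frequency codons end in a purine).

Because the packaged tables are synthetic, passing tests demonstrate the
*estimators and codings* are correct, not that any empirical number is
reproduced: empirical RSS values, posterior node ages, tree likelihoods,
bootstrap supports and the empirical ~470 m ancestral depth all depend on
external sequence/occurrence/depth data and MCMC or ML tree inference,
which this package only prepares inputs for. The synthetic generators also
idealize reality: no alignment ambiguity, no among-lineage rate variation,
no preservation heterogeneity beyond the two-rate model, and no
phylogenetic error in the chronogram.

## Numerical choices

- Quantile/CDF tolerances: 1e-10 round-trip in unit tests; solver xtol
  1e-13 on `log10(c)`.
- Duplicate occurrences (same family, locality, age) collapse with a
  warning; sequence dedup keeps the longest ungapped sequence per
  (species, gene), first occurrence on ties, logged.
- `ci_table` emits non-estimable families with status flags; per-family
  failures never abort the table.
- Pipeline manifests are written atomically (temp file + rename); config
  hashes are SHA-256 over the canonicalized config.
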