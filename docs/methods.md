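# Methods

## The estimator

The binding enthalpy is computed as a four-box balance of mean potential
energies, ΔH = ⟨E⟩_complex + ⟨E⟩_solvent − ⟨E⟩_receptor − ⟨E⟩_ligand,
implemented as (⟨E⟩_complex + ⟨E⟩_solvent) − (⟨E⟩_receptor + ⟨E⟩_ligand)
so that exchanging the bound and unbound sides flips the sign bitwise
exactly. The method assumes (i) the four simulations sample equilibrium
ensembles of the same force field at the same temperature and pressure,
(ii) atom counts balance between the two sides so self-energies cancel
(validated when counts are supplied; a warning is logged otherwise), and
(iii) the pressure–volume work is negligible — the `pv_correction()` hook
makes that assumption explicit and returns zero.

Each ensemble mean is the **unweighted mean of per-trajectory time
averages**: every independent trajectory contributes equally regardless of
length, because independent starts probe different basins of the potential
energy surface and length-weighting would double-count whichever basin
happened to run longer. A pooled-snapshot weighting is available
(`weighting="snapshot"`) but non-default; the two coincide for equal
lengths.

## Uncertainty: pairwise reblocking

Energy snapshots are autocorrelated, so the naive SEM s/√n is biased low
by a factor of roughly √n_corr. Pairwise reblocking halves the series
repeatedly (averaging adjacent non-overlapping pairs, discarding a
trailing odd element, so level k has exactly ⌊n/2ᵏ⌋ blocks); once the
block size exceeds the correlation length the block means are independent
and sem = √(s²/m) (unbiased m−1 variance over m blocks) is unbiased. The
estimate at a level with m blocks itself carries a relative uncertainty of
1/√(2(m−1)), reported as `sem_of_sem`.

Two selection rules read a single number off the curve:

- **max** (default, conservative): the largest SEM over the *reliable*
  levels. An unrestricted maximum is dominated by the last levels, where a
  handful of blocks make the estimate pure noise; the rule therefore
  considers only levels whose SEM is determined to 10 % or better
  (m ≥ 50 blocks, `min_blocks`), falling back to all levels with ≥ 2
  blocks for very short series. The 10 % reliability cut is the package's
  operationalisation of "read the plateau, not the noise"; it is exposed
  as a parameter.
- **heuristic**: the optimal-block-size convention — estimate the
  correlation length at each level from the statistical inefficiency,
  n_corr = (sem_B/sem_0)², and take the smallest block size with
  B³ ≥ 2·n·n_corr², falling back to **max** with a warning when no level
  qualifies (only possible for pathologically short or correlated input).

For an ensemble, the default (`mode="pooled"`) concatenates trajectories
in trajectory-id order and reblocks the pooled series; block boundaries
spanning independent trajectories can only lower the apparent correlation,
keeping the max-rule estimate conservative. `mode="per_trajectory"`
reblocks each trajectory separately and combines the K SEMs as
√(Σ sem_t²)/K, the SEM of an unweighted mean of independent means — useful
when trajectories differ grossly in length. Degenerate inputs: a constant
series yields SEM 0 at every level (not an error); fewer than 4 points is
an error.

Per-system SEMs combine in quadrature because the four simulations are
independent and ΔH is an additive combination of their means.

## Decomposition

Valence / Coulomb / Lennard-Jones components apply the same balance to
per-term-group traces. The GROMACS-dialect default grouping is Val ←
{Bond, Angle, Proper Dih., Improper Dih., U-B, Ryckaert-Bell.}, Coul ←
{Coulomb (SR), Coul. recip., Coulomb-14}, LJ ← {LJ (SR), LJ-14, Disp.
corr.}; restraint terms are excluded with a warning. When the component
traces sum to the total trace per snapshot, the component enthalpies sum
to the total ΔH exactly (to 1e-6 kcal/mol in the additivity test, the
slack being pure floating-point accumulation).

## Diagnostics

**Convergence.** The profile recomputes ΔH with every trajectory truncated
to its first ⌈f·N⌉ snapshots on an even grid of fractions f. Truncating
proportionally (rather than concatenating trajectories) keeps both
within-trajectory drift and between-trajectory disagreement visible. The
drift statistic — |mean of the profile over the trailing 20 % of the grid
minus the full-data value| — is this package's operationalisation of an
"uneven profile"; the default tolerance of 0.5 kcal/mol is one quarter of
the customary 2 kcal/mol accuracy band for computed-vs-ITC comparisons.
Both are parameters.

**Heterogeneity.** Metastable substates bias ΔH exactly through the
per-trajectory means, so the detector clusters those means directly:
single linkage on the real line (sort, cut every adjacent gap above the
threshold). The default threshold is 3× the pooled per-trajectory SEM
(root-mean-square of within-trajectory reblocked SEMs) — a gap that
individual-trajectory noise cannot plausibly produce. An ensemble is
flagged only when ≥ 2 groups each hold ≥ 2 trajectories, so an isolated
straggler is not evidence of a second state. A structural clustering
obtained elsewhere can be supplied verbatim via `groups=`; per-group ΔH is
computed by the conditional estimator when the full quadruple is given.

**Conditional ΔH** restricts any subset of roles to named trajectories and
re-runs the full estimator, down to a single trajectory per role (the SEM
then comes from within-trajectory blocking alone). Recombining a
partition's group estimates with equal-trajectory weights reproduces the
full estimate exactly, because the ensemble mean is a flat average of
per-trajectory means.

## Synthetic data

The generator models each trajectory as an exactly discretised
Ornstein–Uhlenbeck process: E₀ ~ N(μ, σ²), E_{i+1} = μ + φ(E_i − μ) + ε_i
with φ = exp(−dt/τ) and ε_i ~ N(0, σ²(1−φ²)), so every snapshot has the
stationary marginal and the lag-1 autocorrelation is φ by construction.
Streams are split per (role, trajectory) by seed-sequence spawn keys, so
adding a trajectory never perturbs earlier ones and a fixed seed is
bit-reproducible.

Default study conditions: K = 20/10/20/10 trajectories for
complex/solvent/receptor/ligand, N = 10⁵ snapshots per trajectory at
dt = 0.1 ps, σ = 30 kcal/mol, τ = 1 ps, role means of order −10⁴ to −10⁵
kcal/mol arranged so the ground-truth ΔH is −8 kcal/mol. These magnitudes
put the final combined SEM at roughly 0.1–0.3 kcal/mol — the uncertainty
scale of a production calculation — while keeping a 50-seed validation run
around a minute on one CPU; they are the package's chosen validation
conditions, stated in `default_study_spec` and overridable.

Metastable substates are emulated by per-role state offsets with mixture
weights: each trajectory is pinned to one state for its whole length.
Trajectories are allocated to states deterministically (largest-remainder
rounding, contiguous blocks, labels recorded) rather than sampled, so the
per-state subsets are exactly sized and reproducible — the quantity of
interest is conditional on the realised assignment, and deterministic
allocation removes a nuisance source of variance without changing what is
being tested. Ground truths (mixture-weighted ΔH, per-state conditional
ΔH) are recomputable from the spec alone.

What the generator does *not* emulate: non-Gaussian energy fluctuations,
slow within-trajectory state switching (states are frozen per trajectory),
long-range correlations beyond a single exponential time, and any coupling
between the four boxes. Passing tests therefore demonstrate the
statistical machinery — not that a particular force field or sampling
protocol yields accurate enthalpies for real complexes.

## Benchmark

The bundled tables transcribe the experimental ITC enthalpies (with
printed uncertainties and citations) and the Val/Coul/LJ components for
the 11-complex nonredundant protein–peptide set. R² is defined as the
squared Pearson correlation of calculated vs experimental values;
`definition="identity"` switches to the coefficient of determination about
the equivalence line, which additionally penalises systematic offset.
Experimental uncertainties are carried through but do not weight RMSE or
R². Correlations from fewer than 2 (R²) or 3 (component r) pairs, or from
a constant column, are reported as absent rather than zero. The main-text
experimental table prints no temperature column, so `ITCRecord.temperature`
is stored as missing rather than invented.

## Numerical choices and edge cases

- kJ→kcal conversion is a single division by exactly 4.184; no
  intermediate rounding.
- Time stamps must be strictly increasing and uniform to a relative 1e-6;
  traces shorter than 2 points, or containing non-finite values, are
  rejected at construction.
- Blocking preserves the grand mean exactly for power-of-two lengths; with
  odd leftovers discarded the level means differ by O(1/n) (documented on
  `BlockingCurve`).
- Unequal trajectory lengths are accepted with a warning (the estimator
  averages per-trajectory means, so lengths need not match).
- XVG files default to kJ/mol (the GROMACS convention) unless the y-axis
  label says otherwise or the caller overrides; delimited tables default
  to kcal/mol.
- An optional read-time stride is exposed but defaults to none: the
  estimator consumes every recorded snapshot.

## Limitations

- The package analyses energy time series; it does not run MD, parse
  trajectories or topologies, or compute energies from coordinates.
- Binary energy formats (EDR) are not read; export XVG or tabular text
  first. This keeps the readers dependency-free and bit-auditable.
- Heterogeneity detection sees only what is visible in mean energies; two
  conformational states with equal mean energy are indistinguishable here
  even though a structural clustering would separate them (supply such a
  clustering via `groups=` to analyse it).
- The conservative max rule overestimates the SEM slightly by
  construction; the heuristic rule is provided for users who prefer an
  unbiased plateau read.
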