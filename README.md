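# calorimd

Absolute protein–peptide binding enthalpies from molecular-dynamics
potential-energy time series, by the direct (multibox) method — with
reblocking error analysis, conformational-sampling diagnostics, an
enthalpy decomposition, and a benchmark against experimental isothermal
titration calorimetry (ITC).

## The problem

ITC measures the heat of a binding event, ΔH, directly. Predicting the
same number from simulation is hard because it is a *small difference of
enormous averages*: the mean potential energy of a solvated protein box is
tens of thousands of kcal/mol, and the binding enthalpy is a few kcal/mol.
The direct method estimates it as a balance of four independent
simulations,

    ΔH = ⟨E⟩_complex + ⟨E⟩_solvent − ⟨E⟩_receptor − ⟨E⟩_ligand ,

where the bound state is the protein–peptide complex in water plus a
matching pure-water box and the unbound state is the apo receptor in water
plus the free peptide in water. Atom counts must balance exactly between
the two sides so that force-field self-energies cancel; the
pressure–volume contribution is negligible at ambient conditions.

Each ⟨E⟩ is the unweighted mean of the per-trajectory time averages over K
independent trajectories (K = 20 for complex and receptor, 10 for solvent
and ligand by default). Because energy snapshots are strongly
autocorrelated, per-system uncertainties σᵢ come from Flyvbjerg–Petersen
pairwise reblocking — adjacent values are averaged into ever-larger blocks
until block means are independent — and the SEM of ΔH follows by
quadrature:

    σ(ΔH) = sqrt(σ²_complex + σ²_solvent + σ²_receptor + σ²_ligand) .

The dominant failure mode is not statistical noise but *metastability*:
trajectories trapped in long-lived conformational substates (a terminal
tail locked in one arrangement, a transient helix) bias the ensemble mean.
The diagnostics module exposes this from the energies alone, via the
cumulative-ΔH convergence profile and single-linkage clustering of
per-trajectory mean energies, and a conditional estimator recomputes ΔH on
a chosen subset of trajectories (e.g. only those in the substate
consistent with the bound structure).

ΔH also decomposes into physical components — valence (bond/angle/
dihedral), Coulomb, and Lennard-Jones — by applying the same four-box
balance to each energy-term group separately.

## What's in the box

| module        | contents |
|---------------|----------|
| `energy_io`   | GROMACS XVG / CSV / TSV readers, kJ→kcal normalisation, trajectory ensembles, atom-balance validation |
| `blocking`    | pairwise reblocking, conservative max rule and optimal-block-size heuristic |
| `calorimetry` | ensemble means, ΔH with quadrature SEM, Val/Coul/LJ decomposition |
| `diagnostics` | convergence profiles, heterogeneity detection, conditional ΔH |
| `benchmark`   | bundled 11-complex experimental ITC table + component table, RMSE/R²/Pearson metrics |
| `synth`       | Ornstein–Uhlenbeck trajectory generator with metastable states and known ground-truth ΔH |
| `cli`         | `calorimd` command: simulate, compute-dh, reblock, converge, heterogeneity, benchmark, run |

## Worked example

```python
import calorimd as cmd

# a synthetic study at the default conditions: 20/10/20/10 trajectories,
# 1e5 snapshots each, fluctuations of 30 kcal/mol decorrelating over 1 ps,
# ground-truth dH = -8 kcal/mol
spec = cmd.default_study_spec(seed=42)
syn = cmd.gen_quadruple(spec)

est = cmd.delta_h(syn.quadruple)
print(est)                          # -7.84 +/- 0.24 kcal/mol

prof = cmd.convergence_profile(syn.quadruple, n_points=20)
print(prof.drift, prof.converged)   # 0.016 True

rep = cmd.trajectory_heterogeneity(syn.quadruple.complex)
print(len(rep.groups), rep.flagged) # 1 False
```

The estimate lands within one SEM of the construction truth (−8.0); the
convergence drift of 0.016 kcal/mol over the trailing 20 % of the data is
far below the 0.5 kcal/mol gate, and the complex trajectories form a
single energy cluster — no sampling pathology.

Benchmarking the bundled component sums against the experimental table:

```python
records, components = cmd.load_fixtures()
calc = {r.pdb_id: r.val + r.coul + r.lj for r in components.itertuples()}
report = cmd.compare(calc, records, components=components)
print(report.rmse, report.n_within_limit, report.pearson_by_component["coul"])
# 1.59  8  0.52
```

i.e. RMSE 1.59 kcal/mol over the 11 complexes, 8 of 11 inside the
customary 2 kcal/mol accuracy band, and a moderate Pearson correlation of
0.52 between the Coulomb component and the experimental enthalpy.

The same workflow is available from the shell:

```sh
calorimd simulate --config study.yaml --out data/
calorimd compute-dh --complex data/complex --solvent data/solvent \
                    --receptor data/receptor --ligand data/ligand
calorimd benchmark --calc calc.csv
```

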