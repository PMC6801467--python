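# Methods

This note documents the model, the approximations, the defaults, and the
design decisions behind `movetype`, in the order the pipeline uses them.

## 1. The movable-type approximation

The quantity of interest is ΔG_binding = −RT log(Z_PL/Z_L), the log-ratio
of bound-state (protein–ligand complex) and free-state (solvated ligand)
partition functions. Computing either Z exactly requires integrating the
Boltzmann factor over all configurational degrees of freedom; the
movable-type approach replaces that with two nested approximations:

1. **Independence across atoms.** Within a small displacement range, the
   work done on atom *A* by each neighbor *i* is treated as independent,
   so the molecular partition function factorizes into per-atom partition
   functions: log Z_M = Σ_A log Z_A − E_config/RT. Each Z_A is computed
   with every other atom frozen at the input configuration.
2. **Separability across axes.** Each atom's displacement-energy landscape
   is built per Cartesian axis from the reversible work of projected pair
   forces (a left-Riemann line integral with step Δr, the inclination
   cos θ recomputed at every step), and the 3-D grid energy is the sum
   E_Ax + E_Ay + E_Az. The joint landscape is never re-evaluated.

Both approximations are validated against brute-force oracles in
`movetype.benchmark.brute_force_log_partition`:

* `mode="grid"` enumerates the joint product of the engine's per-atom
  state grids. When movable atoms interact only with fixed atoms, the
  cross-atom factorization is exact algebra and the two routes agree to
  floating point (asserted at 1e-6).
* `mode="rescore"` re-evaluates the true pair potential at every jointly
  displaced configuration — no independence, no separability. Against this
  oracle the factorized engine carries the axis-separability and
  finite-step errors; on mild landscapes the disagreement stays within a
  few percent of RT (asserted at 5%). A 1e-6 match against this mode is
  unattainable in principle: the left-Riemann integral alone contributes
  an O(Δr) energy error (≈10⁻³–10⁻² kcal/mol at the default Δr), which is
  why the two oracle modes exist separately.

### Sampling parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `distance_range` | total displacement span per axis (Å) | 1.0 | standard small-movement window of the method |
| `step` (Δr) | work-integration step (Å) | 0.005 | converged to ≪0.01 kcal/mol against direct energy differences |
| `displacement_unit` (Δτ) | partition-grid spacing (Å) | 0.05 | tiles the range with a manageable state count |
| `n_states_per_axis` (n) | states at ±kΔτ, k ≤ n | 10 | 2n·Δτ covers the 1 Å range exactly |
| `angle_range_deg` | angular sampling window | 30 | provenance only — see below |

The angular window is carried in the config (and echoed into report
provenance) but the integrator recomputes the exact force projection at
every step as the atom moves, which supersedes any tabulated angle grid;
a ±15° discretization would only coarsen what is here computed exactly.
State weights are uniform (no angular Jacobian): the states are Cartesian
grid displacements, not polar samples.

### Conventions with consequences

* **Z is a state average, not a state sum.** The normalization is
  logsumexp(−E/RT) − log(n_states). A zero-potential grid then has
  log Z = 0, and any grid-size constant cancels between bound and free
  states, making ΔG invariant to grid resolution (asserted in tests).
  Any consistent constant would cancel in the ratio; the average is the
  convention that also makes single numbers interpretable.
* **Log-domain everywhere.** Realistic ensembles have |E| up to hundreds
  of kcal/mol; exp(−E/RT) overflows double precision near −500 kcal/mol.
  All partition values are carried as natural-log quantities and ensembles
  combine via `scipy.special.logsumexp`.
* **Clashes are states, not crashes.** A displacement that drives a pair
  under 0.1 Å gets +∞ energy (zero Boltzmann weight); a configuration
  whose atoms already overlap gets log Z = −∞ and a `clashed` flag, so
  Monte Carlo ensembles tolerate bad members. Only an *entirely* clashed
  grid raises.
* **Natural log in ΔG.** The worked-example arithmetic (pure subtraction
  of ensemble energies) cannot discriminate log bases; natural log is used
  consistently, with RT·ln 10 = 1.3642 kcal/mol wherever pIC50 enters.

## 2. The default pair potential

The engine is potential-agnostic: `PotentialModel` exposes pair-energy and
pair-force rules, a torsion term, and a solvation rule, all swappable. The
shipped default is deliberately plain, honest molecular mechanics:

* Lennard-Jones 12-6 with geometric-mean ε and arithmetic-mean r_min
  combination; per-element parameters in `elements.py`.
* Coulomb with coulomb constant 332.0636 kcal·Å/(mol·e²) and a
  distance-dependent dielectric ε(r) = 4r (a constant dielectric is a
  config switch), a common implicit-screening choice for docking-scale
  models.
* CHARMM-form switching to zero over the last 1 Å before the 9 Å cutoff,
  applied to energy and differentiated analytically for the force, so
  force ≡ −dE/dr holds to 1e-4 kcal/mol/Å everywhere (property-tested).
* 1-2 and 1-3 intramolecular pairs excluded; 1-4 pairs scaled by 0.5
  (configurable), the common molecular-mechanics convention.
* Torsion: one 3-fold cosine term, ½·k·(1+cos 3φ), per rotatable bond
  (k = 1 kcal/mol default). With the 1-4 Lennard-Jones term this gives a
  butane-like chain its anti plus two gauche minima.
* Solvation: per-atom accessible-surface-area term Σ σ_el·A_i with a
  deterministic 64-point Shrake–Rupley areas routine (probe 1.4 Å) and
  generic atomic solvation parameters (hydrophobic C/S pay for burial,
  polar N/O gain exposure). The 64-point quadrature is intentionally
  coarse — adequate for ensemble energetics, visibly jagged under 1°
  torsion scans, which is why sampler-oracle tests switch it off.

Custom pair rules supplied through `pair_energy_rule` are used verbatim
inside the cutoff (no switching); if no force rule accompanies them the
force falls back to a central difference. The test suite uses harmonic and
zero-potential rules this way.

Missing ligand partial charges are assigned with RDKit's Gasteiger scheme
(iterative partial equalization of orbital electronegativity); protein
atoms read from PDB default to zero charge. This is an explicit stand-in:
no claim is made that it matches any published charge model, and the
potential-config file (`--potential`) can override the element tables.

## 3. Ensembles

**Free state.** Metropolis Monte Carlo over rotatable-bond torsions
(uniform proposals, kT = 0.593 kcal/mol), each accepted sample locally
minimized in torsion space (Nelder–Mead, ≤50 iterations; bond lengths and
angles rigid), scored with the full configuration energy, deduplicated
greedily best-energy-first at 0.3 Å superposed heavy-atom RMSD. Rotatable
bonds are acyclic heavy-heavy single bonds with a further heavy neighbor
on each side, so terminal methyls do not count.

**Bound state.** Anchor points on a 1 Å grid over the binding-site sphere;
at each anchor the top conformers are tried in randomized rigid
orientations, clash-filtered (minimum ligand–protein distance 1.2 Å), and
the best orientation per anchor is refined by a 6-dof rigid-body Powell
minimization of the cross interaction energy. The protein is fixed
throughout — a rigid-receptor protocol; a side-chain flexibility flag is
deliberately not offered because nothing downstream depends on it and an
untested knob is worse than none. Poses deduplicate at 1.0 Å
receptor-frame ligand RMSD (no superposition: poses live in the receptor
frame; free conformers, which have no frame, superpose first).

Both samplers are pure functions of their seed (bit-identical repeat runs,
asserted). They are documented stand-ins at the contract level — ranked,
distinct, clash-free configuration sets — and the partition engine
downstream is sampler-agnostic; any external conformer generator or
docking program can feed it.

The free protein's partition function never appears: with a rigid receptor
it is the same constant in every calculation and cancels in all
comparisons, matching the final-formula convention ΔG = −RT log(Z_PL/Z_L).

## 4. What the toy systems emulate — and what they do not

The registered toy families (`pair`, `chain-N`, `host-guest-ring`) provide
geometries where every claim is checkable by enumeration: an attractive
pocket whose global minimum an exhaustive grid can certify, chains whose
torsion landscape a 1° scan can map, two-atom systems whose joint
partition function fits in memory. Passing on them demonstrates the
*machinery* — integrals, factorization, log-sum-exp laws, determinism —
not chemical accuracy. Real protein–ligand systems add polarization,
explicit water, protonation equilibria, receptor strain and charge models
the default potential does not attempt; absolute ΔG values from the
default potential should be read as method output, not predictions
competitive with a fitted force field. The bundled caspase tables carry
the published calculated values precisely so the statistics layer can be
validated independently of any potential.

## 5. Affinity conversions and statistics

pIC50 → ΔG uses ΔG ≈ RT ln IC50 = −RT·ln 10·pIC50 with IC50 in molar,
valid when the substrate concentration is small; relative affinities
ΔΔG = −RT ln(IC50₁/IC50₂) cancel the concentration-dependent terms and are
antisymmetric by construction.

Benchmark statistics: RMSE with divisor n (this choice reproduces the
annotated fixture statistics exactly; divisor n−1 does not), squared
Pearson correlation, and Kendall τ-b (equal to plain τ-a on the tie-free
bundled tables, where τ = 10/28 for the small-molecule set is an exact
rational). The fixture headers record which annotated correlation values
recompute from the two-decimal printed precision and which deviate beyond
rounding; the deviating ones are shipped as annotations, not asserted
targets. Fixtures are SHA-256-checked on load.

## 6. Interface analysis

Close contacts: heavy-atom pairs within 3 Å by default (hydrogens by
flag). Hydrogen bonds: donor–acceptor ≤ 3.5 Å and donor-H···acceptor
≥ 120°, standard structural-biology geometry; when a structure carries no
explicit hydrogens at all, protein-side donation falls back to the
distance criterion alone (documented fallback, applied only when the
ligand atom has no hydrogen to settle the angle). Aromatic rings are
reported as aromatic-proximal contacts (ring centroid ≤ 4.5 Å) and never
scored energetically — no parameters for C-H/π terms are pretended.
`compare_interfaces` reports residues and hydrogen bonds gained/lost plus
the cross contact-energy difference, and the decomposition
cross + intra + torsion + solvation = total is asserted exactly.

## 7. Known limitations

* Axis separability is uncontrolled for strongly anisotropic local
  landscapes; the rescore oracle bounds it only on the mild toys tested.
* The left-Riemann integral has first-order step error; Δr = 0.005 Å
  keeps it below 0.01 kcal/mol on the tested profiles but it does not
  vanish.
* The solvation term is area-proportional only — no polar screening
  beyond the distance-dependent dielectric, no self-energy.
* The samplers make no completeness claim; missed low-energy conformers
  bias Z_L upward (and missed poses bias Z_PL upward) with no internal
  diagnostic beyond ensemble-size reporting.
* Protonation states, tautomers and missing atoms must be resolved
  upstream; inputs are taken as complete.

## 8. Problem sizes used in the shipped checks

Tests and the acceptance script run on two-atom joint enumerations
(n = 2 states per axis, 125–15 625 joint states), 20-seed docking repeats
on the 8-atom ring host, and the bundled 8/8/15-row affinity tables. These
sizes make every oracle exhaustive and the whole suite runs in well under
a minute; nothing in the method is specific to them, and the full-range
default configuration (21³ states per atom) is exercised wherever no joint
enumeration is required.
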