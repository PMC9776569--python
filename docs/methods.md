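# Methods

## Scope and architecture

`constph` implements the computational core of a discrete (stochastic
titration) constant-pH MD scheme: the per-cycle sequence *solve continuum
electrostatics → sample protonation states by Monte Carlo → update charges →
relax → advance the conformation*. The conformational stage is an interface
(`ConformationProvider`); the shipped providers (static, ensemble-cycling,
Gaussian-jitter) are desk-scale stand-ins that let the entire titration
machinery be exercised and validated without an MD engine. The cycle
interval and the solvent-relaxation hook are expressed in provider steps;
in a production MD coupling they correspond to τ = 20 ps segments and a
0.2 ps frozen-solute solvent relaxation.

## Electrostatics

The linear Poisson–Boltzmann equation is discretized with the standard
7-point stencil on cubic grids (potential in kT/e, lengths in nm, charges
in e). Defaults follow common CpHMD practice: ε_in = 2, ε_out = 80,
temperature 310 K, 81 nodes per side, two-step focusing from 0.1 nm to
0.025 nm spacing with the fine grid centered on the titratable group, and a
convergence threshold of 0.01 kT/e. Ionic strength defaults to 0.1 mol/L
(1:1 salt, linearized Debye–Hückel term on ion-accessible nodes); the
analytic oracles in the tests also run at 0 M where closed forms are exact.

Numerical choices:

- **Charge assignment** is trilinear, conserving total charge to 1e-12 e.
- **Dielectric sampling.** Edge dielectrics are midpoint-sampled by default
  (classic DelPhi-style behaviour). This makes solvation energies a
  staircase function of how the sphere boundary falls against the grid, and
  the error along the refinement ladder 0.1 → 0.05 → 0.025 nm is *not*
  monotone (measured 1.98% / 4.57% / 1.44% for the q = +1, a = 0.2 nm Born
  sphere). The `dielectric_smoothing="harmonic"` option instead
  harmonically averages ε over the exact fraction of each edge inside the
  solute, which converges smoothly (3.03% / 0.54% / 0.05% on the same
  ladder) and is what the refinement property test uses. The default stays
  midpoint because it is the behaviour the production settings were
  calibrated against.
- **SOR stopping.** With optimal over-relaxation (ω ≈ 1.92 at 81 nodes) the
  raw "max node update < tol" rule stops roughly 13× early in true error,
  so the solver additionally requires the projected remaining error
  (update × ρ/(1−ρ), ρ = observed contraction rate) to fall below the
  threshold. The reported residual still satisfies the documented
  `residual ≤ convergence_tol` contract.
- **Boundary conditions.** Coarse-grid faces carry the Debye-screened
  Coulomb sum of the placed charges; fine-grid faces are trilinearly
  interpolated from the coarse solution. Charges outside the fine grid
  contribute through those boundary values (their interactions are
  evaluated on the coarse potential).
- **Grid anisotropy.** The 7-point lattice Green's function deviates from
  1/(4πεr) by up to ≈ +4% on-axis at r = 3h (and ≈ −2% on the diagonal);
  oracle tests therefore compare the direction-averaged potential at each
  radius.
- **Coarse box.** Edge = max(solute extent + 2 nm, 81 × 0.1 nm); the
  spacing is inflated with a warning when a solute would not fit.

## Charging energies and the coupling matrix

For each site state the LPBE is solved with only that state's charges
placed, twice: in the full protein and in the isolated model compound
(the site's model-compound atoms, optionally plus configured cap atoms),
on the *identical* fine grid centered on the model compound. Grid
self-energies then cancel in the protein-minus-model difference, giving

    pKint(i,s) = pKmod(i,s) − ΔΔG(i,s) / (kT ln 10).

The sign convention is anchored by the identity test: a model compound
that *is* the whole protein yields pKint = pKmod exactly (both contexts
follow the same code path).

The site–site coupling uses differences against the reference states,
W((i,a),(j,b)) = Σ_c Δφ_{i,a}(r_c) Δq_{j,b}(c) / ln 10, symmetrized by
averaging with its transpose. This form makes W vanish whenever either
member is in its reference state, which is required for consistency with
the background term of pKint (other sites enter that term at reference
charges) and gives the reference microstate energy exactly zero.

The microstate energy generalizes the usual two-term form with a
`(1 − x)(pKmod − pKint)` contribution so that deprotonated non-reference
tautomers carry their electrostatic shift; it reduces to the textbook
expression when, as in all shipped fixtures, the deprotonated reference is
the only deprotonated state.

## Monte Carlo

One cycle attempts, in randomized order, one single-site move per site
(uniformly random alternative state) and one joint move per *coupled pair*
— pairs whose largest |W| over state combinations exceeds 2 pK — with
Metropolis acceptance min(1, 10^(−ΔE)). Pair proposals draw a random state
for each member independently; this is simpler than schemes that exclude
the current combination but has the same stationary distribution. Because
the per-cycle move order is a uniformly random permutation (a set closed
under reversal), the cycle-level kernel is reversible, which the detailed
balance test exploits. The default run length is 10⁵ cycles; occupancies
for an 8-site system then match exact enumeration to ≲ 0.002 absolute.
Sampling uses `numpy.random.Generator(PCG64)` with explicit seeds recorded
in results; runs are bit-reproducible.

Degenerate caution: at pH exactly equal to a site's pKint every
single-site move has ΔE = 0 and is always accepted, so the *final* state
of a run alternates deterministically with cycle parity even though the
occupancies are correct. The stochastic-titration loop is insensitive to
this (it consumes occupancies and per-cycle samples at many pH values),
but exact-degeneracy fixtures should avoid even cycle counts when testing
final-state statistics.

## Radii from Lennard-Jones parameters

The atomic radius is the distance where the combined 12-6 atom–water pair
potential crosses +2 RT on the repulsive wall (closed form via the
quadratic in (σ/r)⁶), using the full LJ pair (attractive plus repulsive —
the alternative reading, repulsive-only, is not used). How that contact
distance maps to a per-atom radius is genuinely open; the default
subtracts the probe's own half contact distance r*(probe,probe)/2, which
makes the water oxygen's radius self-consistent and keeps radii
approximately pairwise additive, and `subtract_probe=False` exposes the
whole-distance convention. Lorentz–Berthelot combination is the default
(geometric available). Atoms with ε = 0 (all-atom hydrogens) receive a
fixed 0.05 nm radius. Temperature default 310 K.

## Calibration

pKmod values are calibrated against experimental pentapeptide
pK<sub>a</sub> data by shift-and-correct: titrate with the trial pKmod,
fit the Hill curve, add (pK_exp − pK_sim). One pass removes a constant
bias exactly; the loop iterates (tolerance 0.05 pK, max 5 rounds) because
MC noise leaves a residual, and a single-pass mode reproduces the plain
one-shot protocol. The pH grid is 7 points at guess ± {0, 0.5, 1.0, 1.5}.
With per-round noise of σ = 0.05 pK the post-bias shifts are differences
of two noise draws (σ√2 ≈ 0.07), so at tolerance 0.1 an occasional seed
needs a fourth verification round — the stub-engine test freezes exactly
that simulated behaviour.

## Titration analysis

Curves aggregate replicate occupancy series after discarding a burn-in
fraction (default 0.2, mirroring the use of the 10–50 ns segment of 50 ns
runs); fixed-width sliding windows yield per-window curves for
time-resolved pK<sub>a</sub> estimates. Hill fits run on the mean curve
(replicate-mean fitting was chosen over pooled-point fitting; the jackknife
then refits leave-one-replicate-out means), with initial guess pKa = pH of
the half-point, n = 1, n bounded in (0, 5]. Fits are flagged unconverged
with fewer than three interior points, on optimizer failure, or when the
fitted pKa falls outside [pH_min − 2, pH_max + 2] — the analogue of
"extrapolated beyond the simulated range" exclusions. Jackknife error is
sqrt((m−1)/m Σ(pKa₍₋ₖ₎ − mean)²) over converged combinations, undefined
when all fail.

Total charge curves sum z_p·f + z_d·(1−f) over sites plus a fixed
background; the isoelectric point is the root of the linearly interpolated
curve (smallest root with a warning if several). Contact fractions count
frames with minimum side-chain distance ≤ 0.4 nm. The benchmark computes
RMSE/MAE/ME (predicted − experimental; positive = overestimation) and the
maximum deviation, globally and per residue type, excludes tyrosines (and
unconverged fits) by default, and evaluates the null model — every residue
predicted at its residue-type reference pK<sub>a</sub> — on the same
residue set from user-supplied tables.

## Counterions

The neutralizing ion count per pH is the integer (sign opposite the
replicate-averaged solute charge) minimizing the residual, n =
max(0, ⌈|Q| − 0.5⌉), with the half-integer tie broken toward fewer ions
(minimal perturbation). A simulation is flagged for restart when its
running mean charge drifts strictly more than 1 e from the original
estimate (compared with a 1e-9 epsilon so an exact 1.0 e drift computed in
floating point does not trigger); counts are then recomputed from the
running mean.

## What the synthetic systems do and do not show

Fixtures are Born spheres, two-site rods, bead pentapeptides, and random
n-site energy tables with attached analytic or enumerable truth. They
validate the electrostatics, the sampler, and the analysis chain
end-to-end, but they have no conformational flexibility, no explicit
solvent, no real force-field charge distributions, and site counts far
below a protein's. Passing tests therefore demonstrate correctness of the
method's machinery, not the accuracy of pK<sub>a</sub> predictions for
real proteins — that depends on the MD engine, force field, and sampling
time supplied in production use. Problem sizes in the test suite (33–81
node grids, 10⁵ MC cycles, 8-site enumerations) were chosen as the
smallest systems whose oracles are still sharp.

## Known limitations

- Nonlinear PB, molecular (SES) surfaces, and periodic electrostatics are
  out of scope; the dielectric boundary is the union of atomic spheres
  (optionally probe-inflated).
- The union-of-spheres fraction used by harmonic smoothing takes the
  maximum over atoms on shared edges, exact for isolated spheres and a
  close bound for overlapping ones.
- The model compound is the site's model-compound atom set; whether
  backbone cap atoms belong in its dielectric is configurable
  (`model_extra_atoms`) rather than fixed.
- Tautomer support is structural (per-state charge sets, per-state pKmod);
  the shipped fixtures exercise two-state sites.
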