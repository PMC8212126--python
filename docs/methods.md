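# Methods

This note documents the models implemented in `saxstool`, the assumptions
they make, the tunable parameters and their defaults, and what the synthetic
test world does and does not establish.

## 1. The Bayesian SAXS restraint

### Likelihood and priors

Intensities are assumed Gaussian around the scaled forward model with
errors σ·s(qᵢ): the experimental uncertainties s(q) are taken at face value
up to one global error-scale σ. With a Jeffreys prior p(σ) ∝ 1/σ and flat
priors on γ, c1, c2 inside their admissible boxes, the negative log posterior
in the nuisance parameters is

    f(γ, σ) = (M / 2σ²)·χ²(γ) + M·log σ,
    χ²(γ)  = (1/M) Σᵢ ((Iᵢ − γ·mᵢ) / sᵢ)².

Both stationary conditions are closed-form:

* γ̂ = Σ Iᵢmᵢ/sᵢ² / Σ mᵢ²/sᵢ² (weighted least squares). A non-positive γ̂
  indicates pathological data and raises a warning; the value is floored at
  the smallest positive float when used downstream.
* σ̂ = √χ²(γ̂). An exact fit (χ² = 0) is floored at σ_min = 1e-6 with a
  warning.

Other prior choices are conceivable; the Jeffreys/flat combination is the
one under which both σ̂² = χ² and the marginal log-χ² score hold exactly,
and it is stated here as an explicit modelling assumption.

### Automatic weight and marginal score

The curvature of f in the residuals gives the data weight w = M/2σ², which at
the MAP equals M/2χ². During refinement the weight therefore *increases* as
the fit improves — an annealing schedule that requires no user input. χ² is
computed on the linear intensity scale with the experimental error bars;
the logarithm enters only through the score. Integrating σ out of the
posterior yields the equivalent parameter-free score (M/2)·log χ², a strictly
monotone transform of χ²; the two orderings agree, which the tests verify
numerically.

Only a single dataset is supported: each dataset needs its own σ, and
multi-dataset inference is out of scope.

### c1/c2 grid search

c1 ∈ [0.95, 1.05] and c2 ∈ [−2, 4] are optimized by three rounds of an 11×11
grid: the full box; an 11×11 grid spanning a 2×2 block of the previous cells
centered on the best pair; and a final grid with half that extent again
(final spacings 0.001 and 0.06). Before every cell evaluation γ and σ are
reset to their MAP values, so cells are compared by M/2·(1 + log χ²). Ties
keep the first cell in c1-major order; refinement grids are clipped to the
admissible box. The coarse-to-fine scheme assumes the round-1 argmin lands
within one cell of the basin of the optimum; this requires the excluded-volume
and hydration responses to be distinguishable (see §7).

## 2. Forward model

The theoretical profile is a Debye double sum over heavy atoms,
I(q) = Σᵢⱼ fᵢfⱼ sinc(q dᵢⱼ), with per-atom amplitudes

    fᵢ(q) = f_vac,ᵢ(q) − f_dummy,ᵢ(q)·g(q, c1) + c2·wᵢ·f_water(q).

* Vacuum factors: 4-Gaussian international-tables coefficients; implicit
  hydrogens of standard protein atoms are folded into their heavy atom
  (electrons and displaced volume) via a per-atom-name lookup.
* Dummy (displaced-solvent) factors: Gaussian spheres of the element's
  displaced volume (H 5.15, C 16.44, N 2.49, O 9.13, S 19.86, P 5.73 Å³) at
  bulk density 0.334 e/Å³.
* g(q, c1) = c1³·exp(−(4π/3)^{3/2} q² r_m² (c1²−1)/4π) with r_m the mean
  dummy radius of the molecule — the standard radius-rescaling form of the
  excluded-volume correction.
* Hydration: one water form factor per atom scaled by c2 and the atom's
  fractional solvent accessibility (Shrake–Rupley, 64 golden-spiral points,
  probe 1.8 Å).

This is a formula-level reimplementation in the FoXS spirit; bit
compatibility with existing programs is explicitly not a goal. sinc(0) = 1 is
handled exactly; the implementation is verified against an O(N²) double-loop
oracle at 1e-10 relative and against closed forms for 1 and 2 scatterers.
A `ProfileEvaluator` caches the pairwise sinc kernel so that c1/c2 scans at
fixed coordinates cost one bilinear form per cell.

Coarse mode: `coarse_grain` collapses each residue to one `BEAD` pseudo-atom
(flat 10 e⁻ form factor, 15 Å³ displaced volume, 2.5 Å radius). The bead
parameters were fixed once so that bead contrast stays positive over the whole
c1 range while c1/c2 retain leverage. Profiles computed from beads carry a
`coarse` flag.

## 3. Monte Carlo samplers

Energy = w·χ²(γ) + E_ev at temperature 1, Metropolis acceptance, where w is
the Bayesian weight (refreshed with γ, σ after every step block) or a fixed
value, and E_ev = k·Σ(rᵢ+rⱼ−dᵢⱼ)² over overlapping pairs (k = 1 score-unit/Å²
by default, Bondi radii, pairs within one rigid body and 1-2/1-3 chain
neighbors excluded).

* Rigid docking: each step = `moves_per_step` combined rotation+translation
  proposals of the mobile body (Gaussian angle and displacement), then a
  nuisance update; c1/c2 re-optimization is scheduled via
  `optimize_c1c2_every` (every step in full docking runs, off in the toy
  tests where beads make it nearly inert).
* Dihedral refinement: each move perturbs one randomly chosen rotatable
  dihedral by a Gaussian (defaults 5e-2 rad for termini, 5e-3 rad for the
  linker) and rigidly rotates everything downstream, so covalent geometry is
  conserved exactly. The toy bead world uses 0.05 rad for the linker as well:
  the small production value is matched to all-atom runs 10–100× longer than
  desk scale. Hydration weights are frozen between c1/c2 refreshes.
* Fixed-weight runs use the identical samplers with w constant and no σ
  update — the comparison arm for the automatic weight.
* `randomize_start` draws uniform orientations (normalized 4-D Gaussians) and
  positions on an enlarged bounding sphere, rejecting clashes (error after
  10⁴ rejections). Stalls (no acceptance in 100 consecutive steps) log a
  warning only.

Nuisance parameters are set to their MAP values deterministically, not
sampled. Seeded runs are bit-reproducible.

## 4. Linker construction

Stages: (i) straight-line Cα path pushed out of obstacle exclusion spheres
(grow-and-repel; the minimizer does the real work); (ii) Cα minimization
under consecutive-distance harmonics (target D = 3.86 Å, k = 10/Ų) plus
one-sided quadratic exclusion — linker Cα diameter D, obstacle atoms diameter
2D — with 1,000 steepest-descent then 1,000 conjugate-gradient steps;
(iii) all-atom placement: backbone (+Cβ, Gly excepted) atoms seeded uniformly
in a D-sphere around each Cα and minimized first under the bonded network
(250 SD + 1,000 CG), then again with volume exclusion on.

The bonded terms are harmonic *distance* restraints: bonds at ideal topology
values, 1-3 distances standing in for angles, and Cα(i)–Cα(i+1) = 3.86 Å
standing in for the trans ω — a deliberate approximation of a full bonded
parameter set with uniform force constants (k = 100). Obstacle atoms within
4.5 Å of an anchor are treated as its covalent/sequence neighbors and do not
repel the chain. Built models pass a quality gate (Cα spacing D ± 0.1 Å
including the anchor bonds, peptide C–N < 1.5 Å, residual clash ≤ 0.01);
failures are rejected and rebuilt with a fresh seed. Termini grow residue by
residue with ideal geometry (NeRF), trans ω and uniform φ/ψ, resampling on
clash (error after 10³ resamples per residue).

Rotamer libraries, analytic loop closure and hydrogens are out of scope.

## 5. SOM pose clustering

Descriptors are 7-D: mobile-body COM in the fixed body's frame plus the unit
quaternion of the mobile body's rotation relative to its template. The
training metric adds the COM Euclidean distance and the quaternion geodesic
scaled by 2·d_max/π, where d_max — the diagonal of the training COMs'
bounding box — is computed once and frozen. |q·q′| handles the double cover;
the arccos is snapped to 0 when |dot| ≥ 1−1e-12 because it is ill-conditioned
at 1 and identity must cost exactly zero.

Training is classic online SOM: BMU by the mixed metric, Gaussian
neighborhood on the grid, linear interpolation for COMs and sign-aligned
slerp (renormalized) for quaternions. The schedule — 10 epochs, learning rate
0.5 → 0.01 linear, neighborhood radius max(shape)/2 → 1 exponential — is a
standard choice; no canonical schedule exists for this task. All schedule
parameters are configurable. Structures are rebuilt from neurons by placing
the mobile template at the neuron COM/quaternion (clash reported as a flag,
not an error). Cluster groups are produced by connected-component labeling of
non-empty neurons under a user-supplied distance threshold; the original
grouping of map regions was a manual/visual step, so no canonical threshold
exists.

## 6. GA ensemble selection

The ensemble χ² compares the experimental profile with
scale·Σₖ wₖ·Iₖ(q). Weights and scale are fitted jointly inside the fitness
evaluation by NNLS on unnormalized nonnegative coefficients (scale = Σv,
w = v/Σv); `fit_scale=False` gives the literal unscaled form. Exact duplicate
members make the split degenerate and are resolved uniformly with a warning.

The GA evolves fixed-size member sets: tournament selection (size 2),
uniform crossover at rate 0.8 with duplicate repair, one member replacement
per offspring in expectation (a per-gene-rate mode exists), elitism of one,
fitness caching per member set. Production defaults are 1,000 generations ×
population 1,000 × 5 repeats; tests run 200 × 200 × 3.

**Identifiability.** A pool of smooth scattering curves is strongly
degenerate: combinations of near-duplicate conformers fit a mixture as well
as the generating members. Only *aggregate* weights per conformational state
are identifiable, and that is what the recovery tests assert (weights summed
per state via `group_composition`), mirroring how ensemble compositions are
reported per cluster group. Member-level identity should not be expected
from this method on real data either.

## 7. Synthetic world

`fixtures` generates: two bead domains of distinct sizes (16 and 10 beads,
radii 9/6.5 Å, COMs exactly at the stated separation, default 30 Å) with
facing anchor beads and an optional bead linker; noisy profiles with
s(q) = a·I(q) + b, defaults a = 0.01 and b = 1e-4·I(0), chosen so that χ² ≈ 1
and σ̂ ≈ 1 are the recovery targets; dense atomistic globules (150 atoms,
C/N/O/S) with genuinely buried atoms — needed because a loose surface-only
cloud leaves the c1 and c2 responses nearly collinear and the grid search
unconstrained; and profile pools with planted mixtures and recorded ground
truth. Everything is seeded and byte-reproducible.

What the toy world does **not** establish: absolute intensity scales of real
proteins, detector artifacts (smearing, buffer mismatch), the information
content of all-atom scattering at wide angles, force-field realism of the
linker, or member-level ensemble identifiability. Green tests certify the
algebra, the geometry, the samplers' statistical behavior and the workflow
plumbing — not agreement with any particular experimental dataset.

## 8. Numerical choices

* σ floor 1e-6; quaternion-dot snap at 1−1e-12; sinc(0)=1 explicit.
* Grid-search ties: first cell in c1-major order.
* Excluded-volume k = 1, vdW radii per element, BEAD radius 2.5 Å.
* Debye sums chunk over q to bound memory at ~160 MB double precision.
* Steepest descent uses multiplicative step adaptation (×1.2 on success,
  ×0.5 on failure); conjugate gradient is scipy's with analytic gradients.
* All RNGs are numpy `default_rng` seeded from user-facing seeds; derived
  seeds stay below 2³¹.
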