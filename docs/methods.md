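# Methods

## The model

A medium-chain fatty acid is represented as a linear chain of
coarse-grained beads, each standing for roughly four heavy atoms. The
head bead is `P4` (neutral carboxylic acid, charge 0) or `Qa`
(carboxylate, charge −1); tail beads are apolar `C1`. Chain geometry:

| chain | beads | bond length |
|-------|-------|-------------|
| C14   | 4     | 0.47 nm     |
| C12   | 4     | 0.37 nm     |
| C10   | 3     | 0.47 nm     |
| C8    | 3     | 0.37 nm     |

C12 and C8 reuse the C14/C10 bead counts with a shortened bead spacing,
since a two-carbon difference is below the resolution of a four-to-one
mapping. Chains are freely jointed — bonds only, no angle potential: no
angle terms are part of the published bead model for these chains, and at
3–4 beads the conformational effect of an angle term is minor compared
with the interaction-parameter uncertainty. Bead mass is 72 amu, the
standard mass of a 4-heavy-atom bead.

## Composition arithmetic

`molecules_for_concentration` uses the direct mole count
`round(c[mol/L] · V[L] · N_A)` with rounding half away from zero; in the
reference 22×22×44 nm box 1 mM ↦ 12.82 → 13 molecules, 50 mM ↦ 641.
Salt instead uses the per-mM convention `count(1 mM) × I[mM]` by default
(140 mM ↦ 13 × 140 = 1820 pairs), because integer "ions per mM" times
ionic strength is how such compositions are conventionally quoted; the
direct count (1795 for the same box) is available via
`salt_convention="direct"`, and both conventions are exposed for the
fatty acids as well. Protonation splits round half to even — a pure
tie-break (13 molecules at fraction 0.5 → 6 deprotonated). Counterions
equal deprotonated heads, so compositions are charge neutral by
construction. Temperature is carried as metadata (default 37 °C; 50 °C
supported for the C12 condition) and only affects the engine.

## Aggregate detection

Molecules i and j are directly linked when the minimum over bead pairs of
the minimum-image distance is strictly below the cutoff (default 0.6 nm,
the contact distance at this bead resolution); aggregates are connected
components (single linkage). Strict `<` fixes the measure-zero boundary
case reproducibly. Only fatty-acid beads participate; ions and solvent
are implicit and never cluster. The production path uses a periodic
kd-tree with post-filtering to the strict rule and is required — and
tested — to equal an all-pairs union-find oracle exactly. A cutoff at or
above half the smallest box edge is rejected (minimum image undefined).

The aggregate size distribution is molecule-weighted by default
(`probabilities[s]` = fraction of molecules in size-s aggregates,
averaged over frames); aggregate weighting is a switch. The free-size
cutoff is the size at the minimum strictly between the first two local
maxima of the distribution (ties to the smaller size); with no second
peak the default of 5 is returned with a flag. A molecule is free when
its aggregate size is ≤ the cutoff; the strict-`<` boundary alternative
is a switch. Free fractions are averaged over 20 evenly spaced snapshots
from the final 10% of a trajectory (both configurable) — the late-window
generalisation of sampling a fixed interval at the end of a long run —
and reported with the across-snapshot standard deviation.

## CMC estimation

**Free-fraction route.** `f(C) = a·C^b` is fitted by unweighted nonlinear
least squares (initialised from the log-log regression; R² computed on
untransformed fractions; per-point standard deviations are reported but
unused). The CMC solves `a·C^b = 1/2` — half free, half aggregated —
requiring `b < 0`; estimates outside the fitted range are flagged
extrapolated. The plain power form has no offset; fractions above 1 at
low concentration are prevented at the data level (fractions are
physical, in (0, 1]).

**Surface-tension route.** Tension versus log10(concentration in molar)
is split at every contiguous position leaving ≥ 2 points per side; each
side gets a least-squares line and the split with minimal total SSE wins,
ties going to the split with more points in the low-concentration
segment. The CMC is 10^(intersection). Exactly piecewise-linear data
yields zero SSE and the exact break point; near-parallel fitted lines
raise a no-intersection error.

**Comparisons.** Percent decreases between conditions round to integers
and experimental/simulated fold ratios to one decimal, matching how such
tables are conventionally reported. A published reference CMC table for
the four chains under the standard protonation/ionic-strength conditions
ships with the package (`REFERENCE_CMC_MM`); the column assignment for
the C12/C14 mixed-protonation vs neutral conditions is taken to be the
one consistent with the published percent decreases, the source table
being ambiguous there.

## The reduced engine

The engine is an implicit-solvent Langevin stand-in for explicit-solvent
CG-MD, built so every analysis stage can be exercised at desk scale:

- **Interactions.** Harmonic bonds `½k(r−r₀)²` (k = 1250 kJ/mol/nm²);
  truncated-and-shifted 12-6 LJ between beads of different molecules
  (σ = 0.47 nm, cutoff 1.2 nm) with a symmetric well-depth table —
  tail-tail 4.2 kJ/mol carries the implicit hydrophobic attraction,
  head-involving pairs are 1.5–2.2 kJ/mol; Debye-screened Coulomb
  `f·q₁q₂·exp(−r/λ_D)/(ε_r·r)` between charged heads (ε_r = 15, λ_D from
  ionic strength and temperature by the Debye–Hückel expression, ≈0.36 nm
  at 140 mM). These well depths are configuration, not claims of
  parameterisation accuracy. Intramolecular nonbonded pairs are excluded.
- **Integrator.** BAOAB Langevin splitting, timestep 0.02 ps, friction
  1/ps, 310 K; with friction 0 the scheme reduces to velocity Verlet
  (energy drift over 10⁴ steps measures < 0.1% of the initial kinetic
  energy). An optional timestep ramp mirrors staged equilibration;
  default runs use a short steepest-descent minimisation instead.
- **Neighbouring.** A cell list (≥ 3 cells per dimension, else all-pairs
  fallback) with minimum-image distances; the two force paths agree to
  floating-point accumulation order.
- **Determinism.** One integer seed drives placement, initial velocities
  and thermal noise through a seed sequence; identical inputs give
  identical trajectories.
- **Failure mode.** Non-finite coordinates abort with the step number.

**What the engine does and does not emulate.** Solvent, counterions and
salt are implicit: there is no pressure coupling, no explicit water, no
hydrodynamics, and the hydrophobic driving force is a pair potential
rather than an emergent solvent effect. Consequently absolute aggregation
thresholds (apparent CMCs of order 30–100 mM for the default parameters)
do not — and are not expected to — match explicit-solvent CG-MD or
experiment. What the engine does reproduce, and what passing tests
demonstrate, are directional effects: free fraction decreasing with
concentration, a repulsive-only control staying ≥ 90% free, and the
4-bead chain showing a lower apparent CMC than the 3-bead chain.
Micelle-to-bilayer morphology changes, Krafft behaviour and
protonation-equilibrium (pKa) effects are out of scope.

## Study conditions

The standard reduced study (`micellekit.study`) runs 30, 60, 90 and
120 mM in a 15 nm cube (61–244 three-bead molecules, up to ~980 beads for
the 4-bead chain), fully deprotonated with 140 mM implicit salt, three
replicate seeds per concentration, 50,000 steps (1 ns) per run with
frames every 250 steps (201 frames; the final-10% window then holds
exactly the 20 analysis snapshots). The run length was chosen so the
free fraction has stabilised over the analysis window at the highest
concentration; the concentration range brackets the reduced model's 50%
point so the power-law fit interpolates rather than extrapolates. The
labeled-configuration generator builds aggregates by chained attachment
(each molecule placed within 0.4–0.85× cutoff of an already placed bead,
guaranteeing a connected contact graph) and separates groups by more than
cutoff + margin including periodic self-images, so clustering must
recover the construction exactly.

## Numerical choices and degenerate inputs

- Rounding: half away from zero for mole counts, half to even for
  protonation ties; reporting rounds percent decreases to integers and
  folds to one decimal.
- Boundary-equal contact distances are non-contacts (strict `<`).
- Two-line split ties prefer the larger low-concentration segment;
  distribution-valley ties prefer the smaller size.
- Empty/degenerate inputs raise typed validation errors
  (`InvalidInputError` family) distinct from run-time numerical failures
  (`NumericalError` family); the CLI maps these to exit codes 2 and 3.
- Steepest descent only ever accepts downhill moves, so minimised energy
  is never above the input energy; step length underflow terminates.

## Known limitations

- The engine's interaction table is hand-set, not derived from any
  parameterisation pipeline; only orderings and trends are meaningful.
- Single-linkage clustering joins transiently touching micelles; no
  persistence criterion is applied before counting.
- The power-law CMC form is empirical; it cannot represent a plateau at
  f = 1, so points far below the aggregation onset flatten the fit.
- Constant-volume only; no barostat, no explicit-ion electrostatics
  beyond Debye screening, orthorhombic boxes only.
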