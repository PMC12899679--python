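# Methods

## Model

The potential treats electrostatics with localized, polarizable bond
dipoles.  Each C–O, O–H and C–H bond carries one point dipole; C–C bonds
carry none, which keeps the electrostatic term count low.  A dipole has a
permanent magnitude μ₀ (Debye, per bond-type key) and an induced increment

δμ = c (q − q₀) d / 0.20819434

in Debye, with d the instantaneous bond length (Å), q the partial charge
(e) of the bond's polarization-carrying atom, q₀ an atom-type reference
charge (e) and c a global correction factor.  The division converts e·Å to
Debye.  The polarization-carrying atom is the positive terminal of the
bond: the hydrogen for O–H/C–H, the carbon for C–O.  This choice follows
from the fact that reference charges are naturally tabulated for the
hydroxyl/aliphatic hydrogens; it is configurable in principle through the
q₀ table.  Which bond classes respond at all is a parameter-file flag
(`induced_enabled`): the shipped default polarizes O–H and C–H bonds and
keeps C–O bonds permanent-only, reflecting that the C–O induced response
is intentionally excluded in this parameterization lineage.  There is no
self-consistency loop — induced dipoles are a single-pass function of the
supplied charges, which is what makes the model cheap and makes the
many-body decomposition below exactly attributable to the charge provider.

Two sites i, j interact as

E = k_dd μᵢμⱼ/r³ (2 cosα cosα′ + sinα sinα′ cosβ),   μ = μ₀ + δμ

with α the angle of axis i to the center line directed i→j, α′ of axis j
to the line j→i, and β the dihedral between the axis planes.  With these
conventions head-to-tail alignment (α=0, α′=π) gives −2k_ddμᵢμⱼ/r³,
i.e. attraction, and the form is algebraically identical to the classical
dipole interaction tensor — both are verified in the tests against a
two-point-charge Coulomb oracle (relative agreement ≲1e−4 at d/r = 0.01)
and an independent tensor evaluation.  k_dd = 332.0637 × 0.20819434² ≈
14.3933 kcal·mol⁻¹·Å³·D⁻² is stored in the parameter file so energies are
bit-reproducible.

The axis sign convention points each dipole from the negative to the
positive end (O→C, O→H, C→H), overridable per bond key (`axis_sign`),
and the site sits at the bond midpoint (`site_fraction` = 0.5); neither
convention is forced by the functional form, so both are explicit
parameters whose effect is observable through the dipole fit.

### Exclusions and scaling

Intramolecular dipole pairs interact only when the shortest covalent path
containing both bonds spans ≥3 bonds; the metric is 2 + (graph distance
between the bonds' nearest endpoints), so exactly the pairs sharing an
atom are excluded.  Surviving pairs are unscaled.  Van der Waals 12-6
terms start at 1–4 atom pairs with a 0.5 factor, 1–5 and longer are
unscaled; parameters are per-type (ε, Rmin) combined by Lorentz–Berthelot
(geometric-mean radius rule selectable).  No distance cutoffs are applied
by default — target systems are clusters of tens of molecules.

### Hydrogen-bond orbital correction

Each detected intermolecular hydrogen bond of the four parameterized
classes (OW-HW···OW, OH-HO···OW, OW-HW···OH, OW-HW···OS) contributes

E = D [e^{−2a(R−R₀)} − 2e^{−a(R−R₀)}]^p cos(α−α₀) cos(β₁−β₀) cos(β₂−β₀)

with R the donor-O–acceptor-O distance, p odd (default 5) so the ideal
geometry yields exactly −D.  Detection uses R ≤ 3.5 Å and D–H···A ≥ 120°.
α is the D–H···A angle; β₁/β₂ are the angles between the acceptor→H axis
and the acceptor's two covalent bonds — a provisional convention chosen
because it is well defined for all three acceptor types (water, hydroxyl,
ring ether) and reduces to lone-pair directionality for tetrahedral
oxygens.  Each cosine factor is clamped to 0 beyond a 90° deviation so a
*bonding* correction can never change sign at grossly non-ideal geometry;
the term stays continuous because the cosine itself vanishes there.
Intramolecular sugar–sugar contacts are never assigned an orbital term.

## Interaction energies and the many-body decomposition

All supermolecular quantities are evaluated at the fixed cluster geometry:

IE_tot = E(cluster) − Σ E(monomer k),  ΔE₂(i,j) = E(dimer) − E(i) − E(j),
IE_mb = IE_tot − Σ ΔE₂.

Monomers are not relaxed, so bonded terms cancel identically (the
implementation still computes them; the cancellation is asserted in tests
rather than assumed).  The charge provider is invoked once per evaluated
(sub)system.  Because dipole pair energies are pairwise in the site
magnitudes, IE_mb is *exactly* zero whenever the provider is
environment-independent — this is both a test oracle and the design
rationale: any nonzero IE_mb is attributable to whole-system versus
subsystem charge differences.  A corollary worth recording: with a
provider that adds a fixed Δq only when ≥2 molecules are present, the
cluster and every dimer see identical charges, all intermolecular terms
cancel in the expansion, and IE_mb reduces to Σ_k [E_k(reference) −
E_k(shifted)] over monomers.  For water that sum is exactly zero (a water
has no surviving intramolecular dipole pair); only molecules with
intramolecular pairs (polyols, sugars) produce a nonzero IE_mb under such
a threshold provider.  The test suite asserts both branches against the
hand expansion.

## Parameter fitting

*Electrostatics.*  At fixed geometries and charges the modeled Cartesian
molecular dipole Σ(μ₀+δμ)·axis is linear in every μ₀ and in c, so the fit
of {μ₀ per bond key, c} to reference dipole vectors is solved exactly by
linear least squares (`DipoleFitModel.fit()` → results object with
estimates, per-component and magnitude RMSEs, `summary()`).  This replaces
manual adjustment with the exact minimizer of the same objective.  Rank
deficiency (a bond key absent from all observations) raises with the
unidentifiable keys named.

*Torsions and van der Waals.*  Selected Fourier amplitudes and per-type
(ε, Rmin) are refined by bounded coordinate descent on the RMSE of
relative conformational energies over an ensemble, all conformers equally
weighted, each parameter confined to a ±10% multiplicative box around its
initial value (the refinement is meant to stay close to its
transferred-parameter starting point).  The step fraction halves when a
sweep yields no improvement; the objective trace is non-increasing by
construction.

*Reference charges.*  q₀ per atom type is the arithmetic mean of the
provider charges over all atoms of that type across the supplied systems.
The shipped q₀(HO) is 0.2142 e.

## Error metrics

RMSE(0) compares relative energies with both series anchored at the
*reference* method's global-minimum conformer, so all models share one
anchor.  RMSE(each) and MAE(each) are the RMS and the maximum of
(ΔE_model − ΔE_ref) over all unordered conformer pairs — shift-invariant
without privileging any anchor; MAE here is a *maximum*, not a mean,
absolute error.  MRE averages |model−ref|/|ref| over nonzero references;
R² is 1 − SS_res/SS_tot about the reference mean.

## Optimization

Forces are central finite differences of the total energy (default step
1e−4 Å); analytic gradients of the induced and orbital terms are not
implemented.  The default minimizer is steepest descent with a
backtracking line search — accepted steps never increase the energy —
converging on |ΔE| < 1e−6 kcal·mol⁻¹ over 3 consecutive steps or RMS
gradient < 0.01 kcal·mol⁻¹·Å⁻¹; an L-BFGS-B option runs on the same
numerical gradient.  Geometry-independent charge providers are evaluated
once per gradient, not per displacement.  Structural comparison uses
Kabsch least-squares superposition with a proper rotation enforced and,
by default, heavy atoms only.

## Synthetic data

The fixture generators produce every structure the tests need:

- **Water clusters** — rigid experimental monomers (O–H 0.9572 Å, H–O–H
  104.52°) packed by seeded rejection sampling at ~40 Å³/molecule with a
  minimum O–O distance of 2.5 Å.  They emulate cluster *packing* and
  determinism, not hydrogen-bond network optimality: a random 20-water
  cluster is typically net repulsive under the placeholder parameters,
  which is expected for unrelaxed random orientations.
- **Polyol chains and alkanes** — idealized tetrahedral zigzag geometries
  exercising typing, pair-list scaling and intramolecular polarization.
- **Pyranose template** — a 24-atom C₆H₁₂O₆ ideal chair (ring torsions
  ±60°, axial/equatorial substituents per anomer) with the full 7 C–O /
  5 O–H / 7 C–H polar-bond census (19 dipole sites) and exactly one
  anomeric H2 hydrogen.  It is a topology/typing fixture, not a literature
  conformer.
- **Dipole rigs** — two free-standing sites realizing an exact requested
  (r, α, α′, β), used to probe the coupling formula directly.
- **Environment-shift provider** — the minimal non-additive charge
  provider discussed above.

Consequently, passing tests demonstrate internal consistency, analytic
limits, oracle agreement and parameter identifiability; they do not
demonstrate agreement with quantum-chemical benchmarks, which requires
externally fitted parameter tables, benchmark geometries and a
semiempirical charge engine supplied as inputs.

## Numerical choices and degenerate inputs

- Angles are degrees in files, radians internally; all indices 1-based in
  files, 0-based in memory.
- The azimuth β is set to 0 when either axis is parallel to the center
  line (the sinα sinα′ factor vanishes there anyway).
- Coincident dipole centers, zero-length bonds and zero vdW distances
  raise typed errors; untabulated torsion types contribute zero (sparse
  Fourier tables), optionally with a warning.
- The Morse-bracket exponent p must be odd; p = 1 recovers a plain Morse
  well.
- The placeholder parameter set is a self-consistent working set with
  GLYCAM06-scale bonded constants, plausible bond moments (O–H ≈ 1.5 D,
  C–O ≈ 0.9 D, C–H ≈ 0.3 D) and textbook hydrogen-bond scales; its
  provenance is flagged in the file's `meta` block.

## Problem sizes

The test suite and the acceptance script run on clusters of ≤20 waters,
≤30-atom brute-force oracles, 1000-rig oracle sweeps and 6-conformer
refinement ensembles — sizes chosen so every check is exhaustive or
near-exhaustive at interactive runtimes.

## Known limitations

- No periodic boundary conditions, Ewald summation or distance cutoffs;
  the implementation targets finite clusters.
- No analytic gradients; optimization cost scales as 6N energy
  evaluations per step.
- The hydrogen-bond angular convention (β₁/β₂) is provisional, as noted.
- The shipped parameters are placeholders: quantities computed with them
  are internally meaningful (identities, decompositions, recoveries) but
  are not predictions of benchmark-grade energetics.
- The external-engine charge adapter shells out per evaluation; for
  many-body decompositions of large clusters this is the dominant cost.
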