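# pbdp — polarizable bond-dipole potential for carbohydrates and water

`pbdp` implements a molecular-mechanics potential for carbohydrates and
carbohydrate–water clusters in which electrostatics is carried by
**polarizable bond dipoles** rather than atomic point charges.  Every polar
bond — C–O, O–H and C–H (C–C bonds are deliberately excluded) — carries a
point dipole at its midpoint with a permanent magnitude μ₀ and a
geometry/environment-responsive induced increment

    δμ = c (q − q₀) d

where *d* is the instantaneous bond length (Å), *q* the partial charge (e)
of the bond's polarization-carrying atom from a pluggable charge provider,
*q₀* a fixed atom-type reference charge and *c* a dimensionless correction
factor.  No self-consistent polarization cycle is performed.

The total energy is

    E = Σ_b K_b (b − b₀)²  +  Σ_θ K_θ (θ − θ₀)²  +  Σ_φ Σ_n V_n [1 + cos(nφ − γ_n)]
      + Σ_es k_dd (μᵢ₀+δμᵢ)(μⱼ₀+δμⱼ)/r³ · (2cosα cosα′ + sinα sinα′ cosβ)
      + Σ_vdW (A_ij/R¹² − B_ij/R⁶)
      + Σ_HB D [e^{−2a(R−R₀)} − 2e^{−a(R−R₀)}]^p · cos(α−α₀)cos(β₁−β₀)cos(β₂−β₀)

with (r, α, α′, β) the mutual orientation of a dipole pair, 12-6 van der
Waals terms under Lorentz–Berthelot combination with 0.5-scaled 1–4 pairs,
and a Morse-type orbital-overlap correction per intermolecular hydrogen
bond of the four parameterized classes (OW-HW···OW, OH-HO···OW, OW-HW···OH,
OW-HW···OS).  Dipole–dipole interactions act between intermolecular site
pairs and intramolecular pairs separated by ≥3 covalent bonds.

The package is aimed at force-field developers and method benchmarkers: it
provides the energy model, supermolecular interaction-energy bookkeeping
(IE_tot, two-body terms and the many-body energy IE_mb), numerical-gradient
geometry optimization, heavy-atom RMSD, exact linear least-squares fitting
of the electrostatic parameters, bounded torsion/vdW refinement, the
standard conformational error metrics (RMSE(0), RMSE(each), MAE(each), MRE,
R²), and deterministic synthetic fixtures (water clusters, polyols, an
idealized pyranose template, dipole rigs).

## Worked example

Generate an ideal hydrogen-bonded water dimer and evaluate it:

```sh
pbdp fixtures water-dimer --xyz dimer.xyz --connectivity dimer.bonds
pbdp energy dimer.xyz -c dimer.bonds
```

```json
{
 "energy": {
  "counts": {"n_es_pairs": 4, "n_hbonds": 1, "n_vdw_pairs": 9},
  "e_bond": 7.639442318172752e-20, "e_angle": 8.7557033217605e-19,
  "e_dihedral": 0.0,
  "e_es_pp": -2.7710896114675365, "e_es_pi": 0.0, "e_es_ii": 0.0,
  "e_vdw": 0.6439668958639843,
  "e_orb": -0.4824386664097466,
  "e_total": -2.609561382013299
 }
}
```

The dimer is bound by −2.61 kcal·mol⁻¹: the four intermolecular O–H dipole
pairs contribute −2.77 kcal·mol⁻¹ of permanent electrostatics (induced
terms vanish under the reference-charge provider), exchange repulsion adds
+0.64, and the detected OW-HW···OW hydrogen bond contributes −0.48 through
the orbital-overlap correction.  `pbdp interact` on the same input reports
`ie_tot = −2.6096` and `ie_mb = 0` exactly — a two-molecule system has no
many-body energy.  In Python:

```python
from pbdp import molecular_dipole, default_parameters
from pbdp.fixtures import gen_pyranose_template

vec = molecular_dipole(gen_pyranose_template("alpha"), default_parameters())
print(vec.magnitude)   # 3.398282028150985 (Debye)
```

## Layout

| module | contents |
|---|---|
| `pbdp.model` | atoms/bonds/typing, topology, dipole-site assignment, pair lists |
| `pbdp.params` | parameter schema, JSON I/O, validation, vdW combination |
| `pbdp.charges` | charge providers (table / file / external engine), δμ |
| `pbdp.energy` | all energy terms, hydrogen-bond detection, molecular dipoles |
| `pbdp.cluster` | IE_tot, two-body terms, many-body decomposition |
| `pbdp.optimize` | numerical gradients, minimization, Kabsch RMSD |
| `pbdp.fitstats` | dipole fit (Model/Results), torsion/vdW refinement, metrics |
| `pbdp.fixtures` | deterministic synthetic structures and charge providers |
| `pbdp.cli` | `pbdp` command-line interface |

See `docs/methods.md` for the model's assumptions, parameter conventions
and known limitations.
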