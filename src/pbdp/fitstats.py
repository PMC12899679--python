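"""Parameter fitting and benchmark error metrics.

Two fitting procedures are provided:

* :class:`DipoleFitModel` — determines permanent bond-dipole magnitudes μ0
  (per bond key) and the induced-dipole correction factor c from reference
  molecular dipole vectors.  At fixed geometries and charges the modeled
  Cartesian dipole is linear in every μ0 and in c, so the fit is an exact
  linear least-squares solve rather than a manual adjustment; ``fit()``
  returns a results object with estimates, residual diagnostics and a
  ``summary()`` table.
* :func:`refine_torsion_vdw` — bounded coordinate descent refining selected
  torsion Fourier coefficients and van der Waals parameters against a
  conformer ensemble's relative energies, with all conformers weighted
  equally and parameters confined to a ±10% box by default.

The metric conventions: RMSE(0) compares relative energies anchored at the
reference method's global-minimum conformer; RMSE(each)/MAE(each) are the
RMS and the maximum of all pairwise conformer energy-difference deviations,
which makes both shift-invariant without singling out one anchor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .charges import ChargeSet
from .energy import total_energy
from .model import MolecularSystem, assign_bond_dipoles, build_topology
from .params import EA_PER_DEBYE, ParameterSet

__all__ = [
    "DipoleObservation",
    "DipoleFitModel",
    "DipoleFitResults",
    "ConformerEnsemble",
    "RefineSpec",
    "RefineResult",
    "derive_q0",
    "fit_dipole_params",
    "refine_torsion_vdw",
    "rmse0",
    "rmse_each",
    "mae_each",
    "basic_metrics",
]


# ---------------------------------------------------------------------------
# q0 derivation


def derive_q0(
    systems: list[MolecularSystem],
    charge_sets: list[ChargeSet],
    atom_type: str,
) -> float:
    """Arithmetic mean partial charge over every atom of ``atom_type``."""
    values: list[float] = []
    for system, charges in zip(systems, charge_sets):
        for atom in system.atoms:
            if atom.atom_type == atom_type:
                values.append(float(charges.values[atom.index]))
    if not values:
        raise ValueError(f"no atoms of type {atom_type!r} in the given systems")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# dipole parameter fit (Model / Results)


@dataclass
class DipoleObservation:
    """One molecule with its reference dipole vector (Debye) and charges."""

    system: MolecularSystem
    reference: np.ndarray  # (3,) Debye
    charges: ChargeSet

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (3,):
            raise ValueError("reference dipole must be a 3-vector")


class DipoleFitModel:
    """Linear model for (μ0 per bond key, c) from dipole observations.

    Parameters
    ----------
    observations : list of DipoleObservation
        Fixed geometries, charges and reference Cartesian dipoles.
    params : ParameterSet
        Supplies site conventions, q0 table and the fixed μ0 values of any
        bond key not being fitted.
    free_mu0 : list of bond keys whose μ0 is estimated.
    fit_c : whether the induced correction factor c is estimated.
    """

    def __init__(
        self,
        observations: list[DipoleObservation],
        params: ParameterSet,
        free_mu0: list[str],
        fit_c: bool = True,
    ):
        if not observations:
            raise ValueError("at least one observation is required")
        self.observations = observations
        self.params = params
        self.free_mu0 = list(free_mu0)
        self.fit_c = fit_c
        n_free = len(self.free_mu0) + (1 if fit_c else 0)
        if 3 * len(observations) < n_free:
            raise ValueError(
                f"{len(observations)} observations provide "
                f"{3 * len(observations)} components for {n_free} parameters"
            )

    # -- design ------------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        ncol = len(self.free_mu0) + (1 if self.fit_c else 0)
        rows = 3 * len(self.observations)
        x = np.zeros((rows, ncol))
        y = np.zeros(rows)
        col_of = {k: i for i, k in enumerate(self.free_mu0)}
        for obs_i, obs in enumerate(self.observations):
            sl = slice(3 * obs_i, 3 * obs_i + 3)
            system = obs.system
            sites = assign_bond_dipoles(system, self.params)
            target = obs.reference.copy()
            for site in sites:
                # induced response column (linear in c) or fixed contribution
                dmu_unit = 0.0
                if site.induced_enabled:
                    atom = system.atoms[site.charge_atom]
                    q = float(obs.charges.values[site.charge_atom])
                    q0 = self.params.dipole.q0_for(atom.atom_type)
                    d = system.bond_length(site.bond)
                    dmu_unit = (q - q0) * d / EA_PER_DEBYE  # δμ at c = 1
                if site.key in col_of:
                    x[sl, col_of[site.key]] += site.axis
                else:
                    target -= site.mu0 * site.axis
                if self.fit_c:
                    x[sl, -1] += dmu_unit * site.axis
                else:
                    target -= self.params.dipole.c * dmu_unit * site.axis
            y[sl] = target
        return x, y

    def fit(self) -> "DipoleFitResults":
        x, y = self._design()
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            dead = [
                k
                for i, k in enumerate(self.free_mu0)
                if np.allclose(x[:, i], 0.0)
            ]
            if self.fit_c and np.allclose(x[:, -1], 0.0):
                dead.append("c")
            raise np.linalg.LinAlgError(
                "rank-deficient dipole fit design; unidentifiable parameters: "
                f"{dead or 'collinear columns'}"
            )
        beta, _res, _rank, _sv = np.linalg.lstsq(x, y, rcond=None)
        mu0 = dict(zip(self.free_mu0, (float(b) for b in beta)))
        c = float(beta[-1]) if self.fit_c else self.params.dipole.c
        residual = (x @ beta - y).reshape(-1, 3)
        # per-component and magnitude RMSEs on the original scale
        fitted = np.array(
            [obs.reference + residual[i] for i, obs in enumerate(self.observations)]
        )
        refs = np.array([obs.reference for obs in self.observations])
        comp_rmse = np.sqrt(np.mean((fitted - refs) ** 2, axis=0))
        mag_rmse = float(
            np.sqrt(
                np.mean(
                    (
                        np.linalg.norm(fitted, axis=1)
                        - np.linalg.norm(refs, axis=1)
                    )
                    ** 2
                )
            )
        )
        return DipoleFitResults(
            model=self,
            mu0=mu0,
            c=c,
            component_rmse=tuple(float(v) for v in comp_rmse),
            magnitude_rmse=mag_rmse,
            n_obs=len(self.observations),
        )


@dataclass
class DipoleFitResults:
    model: DipoleFitModel
    mu0: dict[str, float]
    c: float
    component_rmse: tuple[float, float, float]
    magnitude_rmse: float
    n_obs: int

    @property
    def params(self) -> dict[str, float]:
        out = dict(self.mu0)
        if self.model.fit_c:
            out["c"] = self.c
        return out

    def apply(self, params: ParameterSet) -> ParameterSet:
        """Write the fitted values into (a validated copy of) a parameter set."""
        import copy

        new = copy.deepcopy(params)
        for key, val in self.mu0.items():
            new.dipole.mu0[key] = val
        if self.model.fit_c:
            new.dipole.c = self.c
        new.validate()
        return new

    def summary(self) -> str:
        lines = [
            "Bond-dipole electrostatic fit",
            "=" * 45,
            f"observations              {self.n_obs:>8d}",
            f"fitted parameters         {len(self.params):>8d}",
            "",
            f"{'parameter':<18s}{'estimate':>12s}",
            "-" * 30,
        ]
        for key, val in self.mu0.items():
            lines.append(f"mu0({key})".ljust(18) + f"{val:12.4f}  D")
        if self.model.fit_c:
            lines.append("c".ljust(18) + f"{self.c:12.4f}")
        rx, ry, rz = self.component_rmse
        lines += [
            "-" * 30,
            f"RMSE mu_x/mu_y/mu_z   {rx:.4f} / {ry:.4f} / {rz:.4f}  D",
            f"RMSE |mu|             {self.magnitude_rmse:.4f}  D",
        ]
        return "\n".join(lines)


def fit_dipole_params(
    observations: list[DipoleObservation],
    params: ParameterSet,
    free_mu0: list[str],
    fit_c: bool = True,
) -> DipoleFitResults:
    """Functional wrapper around :class:`DipoleFitModel`."""
    return DipoleFitModel(observations, params, free_mu0, fit_c).fit()


# ---------------------------------------------------------------------------
# torsion / vdW refinement


@dataclass
class ConformerEnsemble:
    """Conformers of one molecule with reference energies (kcal·mol⁻¹)."""

    systems: list[MolecularSystem]
    ref_energies: np.ndarray
    ref_min_index: int | None = None

    def __post_init__(self) -> None:
        self.ref_energies = np.asarray(self.ref_energies, dtype=float)
        if len(self.systems) != len(self.ref_energies):
            raise ValueError("systems and reference energies differ in length")
        if len(self.systems) < 2:
            raise ValueError("an ensemble needs at least 2 conformers")
        if self.ref_min_index is None:
            self.ref_min_index = int(np.argmin(self.ref_energies))


#: parameter address kinds accepted by RefineSpec
_REFINE_KINDS = ("dihedral_v", "vdw_epsilon", "vdw_rmin")


@dataclass
class RefineSpec:
    """Free parameters for refinement.

    Entries are ``("dihedral_v", key, term_index)``, ``("vdw_epsilon", type)``
    or ``("vdw_rmin", type)``.  ``bound_fraction`` is the half-width of the
    multiplicative box around each initial value (0.10 = ±10%).
    """

    entries: list[tuple]
    bound_fraction: float = 0.10
    max_sweeps: int = 40
    min_step: float = 1e-5  # as a fraction of the box width

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("refine spec names no free parameters")
        for entry in self.entries:
            if entry[0] not in _REFINE_KINDS:
                raise ValueError(f"unknown refine entry kind {entry[0]!r}")


def _get_param(params: ParameterSet, entry: tuple) -> float:
    kind = entry[0]
    if kind == "dihedral_v":
        _, key, idx = entry
        return params.bonded.dihedrals[key][idx][0]
    if kind == "vdw_epsilon":
        return params.vdw.epsilon[entry[1]]
    return params.vdw.rmin[entry[1]]


def _set_param(params: ParameterSet, entry: tuple, value: float) -> None:
    kind = entry[0]
    if kind == "dihedral_v":
        _, key, idx = entry
        vn, n, gamma = params.bonded.dihedrals[key][idx]
        params.bonded.dihedrals[key][idx] = (value, n, gamma)
    elif kind == "vdw_epsilon":
        params.vdw.epsilon[entry[1]] = value
    else:
        params.vdw.rmin[entry[1]] = value


@dataclass
class RefineResult:
    params: ParameterSet
    objective_trace: list[float]
    values: dict[str, float]

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


def _ensemble_objective(
    params: ParameterSet, ensemble: ConformerEnsemble, charge_provider
) -> float:
    model = np.array(
        [
            total_energy(s, params, charge_provider).e_total
            for s in ensemble.systems
        ]
    )
    return rmse0(model, ensemble.ref_energies, ensemble.ref_min_index)


def refine_torsion_vdw(
    params: ParameterSet,
    ensemble: ConformerEnsemble,
    spec: RefineSpec,
    charge_provider=None,
) -> RefineResult:
    """Bounded coordinate descent on the ensemble relative-energy RMSE.

    Each free parameter moves within ``[v·(1−f), v·(1+f)]`` around its
    initial value v; all conformers carry equal weight.  The objective
    trace is non-increasing across accepted steps.
    """
    import copy

    work = copy.deepcopy(params)
    lo_hi: list[tuple[float, float]] = []
    for entry in spec.entries:
        v = _get_param(work, entry)
        lo = v - abs(v) * spec.bound_fraction
        hi = v + abs(v) * spec.bound_fraction
        lo_hi.append((lo, hi))

    obj = _ensemble_objective(work, ensemble, charge_provider)
    trace = [obj]
    step_frac = 0.5
    while step_frac * spec.bound_fraction >= spec.min_step and len(trace) < 10_000:
        improved = False
        for entry, (lo, hi) in zip(spec.entries, lo_hi):
            width = hi - lo
            if width == 0.0:
                continue
            v = _get_param(work, entry)
            for cand in (v + step_frac * width, v - step_frac * width):
                cand = min(hi, max(lo, cand))
                if cand == v:
                    continue
                _set_param(work, entry, cand)
                try:
                    cand_obj = _ensemble_objective(work, ensemble, charge_provider)
                except Exception:
                    cand_obj = math.inf
                if cand_obj < obj - 1e-12:
                    obj = cand_obj
                    trace.append(obj)
                    improved = True
                    break
                _set_param(work, entry, v)
        if not improved:
            step_frac *= 0.5
        if len(trace) > spec.max_sweeps * max(1, len(spec.entries)) * 4:
            break

    values = {}
    for entry in spec.entries:
        label = ":".join(str(p) for p in entry)
        values[label] = _get_param(work, entry)
    work.validate()
    return RefineResult(params=work, objective_trace=trace, values=values)


# ---------------------------------------------------------------------------
# error metrics


def _check_lengths(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("energy series must be 1-D and of equal length")
    return a, b


def rmse0(
    model_energies: np.ndarray,
    ref_energies: np.ndarray,
    ref_min_index: int | None = None,
) -> float:
    """RMSE of relative energies, both series anchored at the reference
    method's global-minimum conformer."""
    model, ref = _check_lengths(model_energies, ref_energies)
    if ref_min_index is None:
        ref_min_index = int(np.argmin(ref))
    dm = model - model[ref_min_index]
    dr = ref - ref[ref_min_index]
    return float(np.sqrt(np.mean((dm - dr) ** 2)))


def _pairwise_deviations(model: np.ndarray, ref: np.ndarray) -> np.ndarray:
    devs = [
        (model[i] - model[j]) - (ref[i] - ref[j])
        for i, j in itertools.combinations(range(len(model)), 2)
    ]
    return np.asarray(devs)


def rmse_each(model_energies: np.ndarray, ref_energies: np.ndarray) -> float:
    """RMS over all unordered conformer pairs of the energy-difference error."""
    model, ref = _check_lengths(model_energies, ref_energies)
    if len(model) < 2:
        raise ValueError("need at least 2 conformers")
    return float(np.sqrt(np.mean(_pairwise_deviations(model, ref) ** 2)))


def mae_each(model_energies: np.ndarray, ref_energies: np.ndarray) -> float:
    """Maximum absolute pairwise energy-difference error."""
    model, ref = _check_lengths(model_energies, ref_energies)
    if len(model) < 2:
        raise ValueError("need at least 2 conformers")
    return float(np.max(np.abs(_pairwise_deviations(model, ref))))


def basic_metrics(model: np.ndarray, ref: np.ndarray) -> dict[str, float]:
    """{rmse, mre, r2} of a model series against a reference series.

    MRE averages |model−ref|/|ref| over nonzero references (zero references
    are excluded with a warning); R² is 1 − SS_res/SS_tot about the
    reference mean.
    """
    m, r = _check_lengths(model, ref)
    rmse = float(np.sqrt(np.mean((m - r) ** 2)))
    nz = r != 0.0
    if not np.all(nz):
        warnings.warn("zero reference values excluded from MRE")
    mre = float(np.mean(np.abs(m[nz] - r[nz]) / np.abs(r[nz]))) if nz.any() else math.nan
    ss_res = float(np.sum((m - r) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return {"rmse": rmse, "mre": mre, "r2": r2}
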