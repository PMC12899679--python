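"""Numerical-gradient geometry minimization and structural comparison.

Analytic gradients of the induced-dipole and orbital terms are not
implemented; all forces come from central finite differences of the total
energy, and minimization is steepest descent with a backtracking line
search (a quasi-Newton option wraps scipy's L-BFGS-B on the same numerical
gradient).  Convergence follows an energy-change tolerance plus an RMS
gradient criterion of 0.01 kcal·mol⁻¹·Å⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import total_energy
from .model import MolecularSystem, Topology, build_topology
from .params import ParameterSet

__all__ = [
    "MinimizeOptions",
    "MinimizationResult",
    "numerical_gradient",
    "minimize",
    "superpose_rmsd",
]


def _energy_at(
    system: MolecularSystem,
    coords: np.ndarray,
    params: ParameterSet,
    charge_provider,
    topology: Topology,
) -> float:
    system.set_coords(coords)
    return total_energy(system, params, charge_provider, topology).e_total


def numerical_gradient(
    system: MolecularSystem,
    params: ParameterSet,
    charge_provider=None,
    h: float = 1e-4,
    topology: Topology | None = None,
) -> np.ndarray:
    """Central-difference gradient, (n_atoms, 3), kcal·mol⁻¹·Å⁻¹.

    Geometry-independent charge providers (``geometry_dependent = False``)
    are evaluated once and reused for all displaced geometries.
    """
    if h <= 0:
        raise ValueError("finite-difference step must be positive")
    if topology is None:
        topology = build_topology(system)
    work = system.copy()
    provider = charge_provider
    if provider is not None and not getattr(provider, "geometry_dependent", True):
        frozen = provider(work)
        provider = lambda _sys, _c=frozen: _c  # noqa: E731
    x0 = system.coords
    grad = np.zeros_like(x0)
    for i in range(x0.shape[0]):
        for k in range(3):
            xp = x0.copy()
            xp[i, k] += h
            ep = _energy_at(work, xp, params, provider, topology)
            xm = x0.copy()
            xm[i, k] -= h
            em = _energy_at(work, xm, params, provider, topology)
            grad[i, k] = (ep - em) / (2.0 * h)
    return grad


@dataclass
class MinimizeOptions:
    method: str = "steepest-descent"  # or "lbfgs"
    max_iter: int = 500
    tol_energy: float = 1e-6  # kcal/mol, consecutive-step change
    n_consec: int = 3
    tol_rms_grad: float = 0.01  # kcal/mol/Å
    h: float = 1e-4  # finite-difference step, Å
    initial_step: float = 0.05  # Å along the normalized gradient
    backtrack: float = 0.5
    max_backtracks: int = 20


@dataclass
class MinimizationResult:
    system: MolecularSystem
    energies: list[float] = field(default_factory=list)
    converged: bool = False
    reason: str = ""
    iterations: int = 0

    @property
    def final_energy(self) -> float:
        return self.energies[-1]


def minimize(
    system: MolecularSystem,
    params: ParameterSet,
    charge_provider=None,
    options: MinimizeOptions | None = None,
) -> MinimizationResult:
    """Minimize the total energy on the numerical gradient.

    Accepted steps never increase the energy; the trajectory records the
    energy after every accepted step.
    """
    opts = options or MinimizeOptions()
    topology = build_topology(system)
    work = system.copy()

    def energy_of(coords: np.ndarray) -> float:
        return _energy_at(work, coords, params, charge_provider, topology)

    x = system.coords
    e = energy_of(x)
    if not np.isfinite(e):
        raise ValueError("non-finite starting energy")

    if opts.method == "lbfgs":
        return _minimize_lbfgs(system, work, x, e, params, charge_provider, topology, opts)
    if opts.method != "steepest-descent":
        raise ValueError(f"unknown minimizer {opts.method!r}")

    result = MinimizationResult(system=system.copy(), energies=[e])
    step = opts.initial_step
    consec_small = 0
    for it in range(1, opts.max_iter + 1):
        work.set_coords(x)
        grad = numerical_gradient(work, params, charge_provider, opts.h, topology)
        rms = float(np.sqrt(np.mean(grad**2)))
        if rms < opts.tol_rms_grad:
            result.converged = True
            result.reason = f"RMS gradient {rms:.3e} below {opts.tol_rms_grad}"
            break
        gnorm = float(np.linalg.norm(grad))
        direction = -grad / gnorm
        # backtracking line search: shrink until the energy decreases
        trial_step = step
        accepted = False
        for _ in range(opts.max_backtracks):
            x_new = x + trial_step * direction
            e_new = energy_of(x_new)
            if np.isfinite(e_new) and e_new <= e:
                accepted = True
                break
            trial_step *= opts.backtrack
        if not accepted:
            result.converged = True
            result.reason = "line search exhausted (at numerical floor)"
            break
        de = e - e_new
        x, e = x_new, e_new
        result.energies.append(e)
        result.iterations = it
        # grow the step cautiously after a clean accept at full length
        step = min(trial_step * 1.5, 0.2)
        if de < opts.tol_energy:
            consec_small += 1
            if consec_small >= opts.n_consec:
                result.converged = True
                result.reason = (
                    f"|ΔE| < {opts.tol_energy} for {opts.n_consec} steps"
                )
                break
        else:
            consec_small = 0
    else:
        result.reason = "maximum iterations reached"

    result.system.set_coords(x)
    return result


def _minimize_lbfgs(
    system, work, x0, e0, params, charge_provider, topology, opts
) -> MinimizationResult:
    from scipy.optimize import minimize as sp_minimize

    trace = [e0]

    def fun(flat: np.ndarray) -> float:
        return _energy_at(work, flat.reshape(-1, 3), params, charge_provider, topology)

    def jac(flat: np.ndarray) -> np.ndarray:
        work.set_coords(flat.reshape(-1, 3))
        return numerical_gradient(work, params, charge_provider, opts.h, topology).ravel()

    res = sp_minimize(
        fun,
        x0.ravel(),
        jac=jac,
        method="L-BFGS-B",
        options={"maxiter": opts.max_iter, "ftol": opts.tol_energy},
    )
    trace.append(float(res.fun))
    out = MinimizationResult(
        system=system.copy(),
        energies=trace,
        converged=bool(res.success),
        reason=str(res.message),
        iterations=int(res.nit),
    )
    out.system.set_coords(res.x.reshape(-1, 3))
    return out


def superpose_rmsd(
    model: MolecularSystem,
    reference: MolecularSystem,
    heavy_only: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares superposition; returns (rotation, translation, RMSD Å).

    Correspondence is positional (atom order).  With ``heavy_only`` the fit
    and the RMSD use non-hydrogen atoms only.  The rotation is proper
    (det = +1); ``rotation @ (model − model_centroid) + translation``
    overlays the model onto the reference frame.
    """
    sel_m = [a.index for a in model.atoms if not heavy_only or a.element != "H"]
    sel_r = [a.index for a in reference.atoms if not heavy_only or a.element != "H"]
    if len(sel_m) != len(sel_r) or not sel_m:
        raise ValueError(
            f"atom count mismatch: {len(sel_m)} model vs {len(sel_r)} reference"
        )
    p = model.coords[sel_m]
    q = reference.coords[sel_r]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = (pc @ rot.T) - qc
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    trans = q.mean(axis=0)
    return rot, trans, rmsd
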