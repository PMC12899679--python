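"""Per-atom partial-charge providers and the induced bond-dipole response.

A *charge provider* is any callable ``provider(system) -> ChargeSet``.  The
induced increment on a polar bond is

    δμ = c · (q − q0) · d / 0.20819434   [Debye]

where d is the instantaneous bond length (Å), q the partial charge (e) of
the bond's polarization-carrying atom (the positive terminal: H for X–H
bonds, C for C–O bonds), and q0 the fixed atom-type reference charge.  No
self-consistent polarization cycle is performed: δμ responds to the charges
of one evaluation only.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import BondDipoleSite, MolecularSystem
from .params import EA_PER_DEBYE, DipoleParams, MissingParameterError, ParameterSet

__all__ = [
    "ChargeSet",
    "ChargeProviderError",
    "TableChargeProvider",
    "FileChargeProvider",
    "ExternalEngineProvider",
    "EngineConfig",
    "charges_from_table",
    "charges_from_file",
    "save_charges",
    "induced_dipole",
    "update_induced_dipoles",
]


class ChargeProviderError(RuntimeError):
    """A charge provider failed to produce one finite charge per atom."""


@dataclass
class ChargeSet:
    values: np.ndarray  # e, one per atom
    provenance: str = "table"  # table | file | external-engine
    scope: str = "whole-system"  # whole-system | subsystem

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ChargeProviderError("charges must be a flat per-atom array")
        if not np.all(np.isfinite(self.values)):
            raise ChargeProviderError("non-finite charge encountered")

    def __len__(self) -> int:
        return len(self.values)


def charges_from_table(system: MolecularSystem, dipole: DipoleParams) -> ChargeSet:
    """q(atom) = q0(atom_type): geometry-independent; all δμ vanish."""
    vals = np.array([dipole.q0_for(a.atom_type) for a in system.atoms])
    return ChargeSet(vals, provenance="table")


@dataclass
class TableChargeProvider:
    """Deterministic provider returning the q0 reference charges."""

    params: ParameterSet

    #: geometry/environment independence lets callers skip re-evaluation
    geometry_dependent: bool = False

    def __call__(self, system: MolecularSystem) -> ChargeSet:
        return charges_from_table(system, self.params.dipole)


def charges_from_file(path: str | Path, system: MolecularSystem) -> ChargeSet:
    """Read one charge (e) per line, in atom order."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) != system.n_atoms:
        raise ChargeProviderError(
            f"{path}: {len(lines)} charges for {system.n_atoms} atoms"
        )
    try:
        vals = np.array([float(ln.split()[0]) for ln in lines])
    except ValueError as exc:
        raise ChargeProviderError(f"{path}: non-numeric charge line") from exc
    return ChargeSet(vals, provenance="file")


def save_charges(charges: ChargeSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{q:.10f}\n" for q in charges.values))


@dataclass
class FileChargeProvider:
    path: str | Path
    geometry_dependent: bool = False

    def __call__(self, system: MolecularSystem) -> ChargeSet:
        return charges_from_file(self.path, system)


@dataclass
class EngineConfig:
    """Adapter contract for an external semiempirical charge engine.

    ``command`` is invoked as ``command <xyzfile>``; per-atom charges are
    pulled from stdout with ``output_regex`` (first capture group, one match
    per atom, in atom order).
    """

    command: str
    input_dialect: str = "xyz"
    output_regex: str = r"^\s*\S+\s+(-?\d+\.\d+)\s*$"
    timeout: float = 300.0


@dataclass
class ExternalEngineProvider:
    config: EngineConfig
    scope: str = "whole-system"
    geometry_dependent: bool = True

    def __call__(self, system: MolecularSystem) -> ChargeSet:
        from .io import write_xyz

        if self.config.input_dialect != "xyz":
            raise ChargeProviderError(
                f"unsupported engine input dialect {self.config.input_dialect!r}"
            )
        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "geom.xyz"
            write_xyz(system, xyz)
            try:
                proc = subprocess.run(
                    self.config.command.split() + [str(xyz)],
                    capture_output=True,
                    text=True,
                    timeout=self.config.timeout,
                )
            except FileNotFoundError as exc:
                raise ChargeProviderError(
                    f"charge engine {self.config.command!r} not found; use the "
                    "table provider or a charge file instead"
                ) from exc
        if proc.returncode != 0:
            raise ChargeProviderError(
                f"charge engine exited {proc.returncode}: {proc.stderr[:500]}"
            )
        matches = re.findall(self.config.output_regex, proc.stdout, re.MULTILINE)
        if len(matches) != system.n_atoms:
            raise ChargeProviderError(
                f"engine output yielded {len(matches)} charges for "
                f"{system.n_atoms} atoms; output began: {proc.stdout[:300]!r}"
            )
        return ChargeSet(
            np.array([float(m) for m in matches]),
            provenance="external-engine",
            scope=self.scope,
        )


# ---------------------------------------------------------------------------
# induced dipoles


def induced_dipole(
    d: float,
    q: float,
    q0: float,
    c: float,
    enabled: bool = True,
) -> float:
    """δμ = c(q − q0)d, converted from e·Å to Debye; 0 when disabled."""
    if not enabled:
        return 0.0
    return c * (q - q0) * d / EA_PER_DEBYE


def update_induced_dipoles(
    sites: list[BondDipoleSite],
    system: MolecularSystem,
    charges: ChargeSet,
    params: ParameterSet,
) -> list[BondDipoleSite]:
    """Fill δμ on every site from a charge set (in place; returns sites)."""
    if len(charges) != system.n_atoms:
        raise ChargeProviderError("charge set size does not match system")
    for site in sites:
        if not site.induced_enabled:
            site.delta_mu = 0.0
            continue
        atom = system.atoms[site.charge_atom]
        if atom.atom_type is None:
            raise MissingParameterError("atom types required for induced dipoles")
        q = float(charges.values[site.charge_atom])
        q0 = params.dipole.q0_for(atom.atom_type)
        d = system.bond_length(site.bond)
        site.delta_mu = induced_dipole(d, q, q0, params.dipole.c, True)
    return sites
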