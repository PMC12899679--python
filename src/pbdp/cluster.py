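"""Supermolecular interaction-energy bookkeeping for multi-molecule systems.

All quantities are evaluated at the fixed cluster geometry (no monomer
relaxation), so bonded terms cancel identically in every difference:

    IE_tot   = E(cluster) − Σ_k E(monomer k)
    ΔE₂(i,j) = E(dimer ij) − E(i) − E(j)
    IE_mb    = IE_tot − Σ_{i<j} ΔE₂(i,j)

The charge provider is invoked once per evaluated (sub)system.  With an
environment-independent provider every term is pairwise additive and IE_mb
vanishes; a nonzero IE_mb is attributable entirely to whole-system versus
subsystem charge differences feeding the induced dipoles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .energy import EnergyReport, total_energy
from .model import Atom, Bond, MolecularSystem
from .params import ParameterSet

__all__ = [
    "InteractionReport",
    "subsystem",
    "interaction_energy_total",
    "two_body_energies",
    "many_body_energy",
]


@dataclass
class InteractionReport:
    ie_tot: float
    two_body: dict[tuple[int, int], float]
    ie_mb: float
    cluster_energy: float
    monomer_energies: dict[int, float]
    dimer_energies: dict[tuple[int, int], float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "ie_tot": self.ie_tot,
            "ie_mb": self.ie_mb,
            "two_body": {f"{i}-{j}": v for (i, j), v in self.two_body.items()},
            "cluster_energy": self.cluster_energy,
            "monomer_energies": {str(k): v for k, v in self.monomer_energies.items()},
        }


def subsystem(system: MolecularSystem, molecule_ids: list[int]) -> MolecularSystem:
    """Extract the selected molecules at unchanged coordinates and types."""
    if not molecule_ids:
        raise ValueError("empty molecule selection")
    wanted = set(molecule_ids)
    mol = system.molecule_id
    bad = wanted - set(range(system.n_molecules))
    if bad:
        raise ValueError(f"unknown molecule ids {sorted(bad)}")
    old_to_new: dict[int, int] = {}
    atoms: list[Atom] = []
    for a in system.atoms:
        if mol[a.index] in wanted:
            old_to_new[a.index] = len(atoms)
            atoms.append(
                Atom(len(atoms), a.element, a.position.copy(), a.atom_type)
            )
    bonds = [
        Bond(old_to_new[b.i], old_to_new[b.j])
        for b in system.bonds
        if b.i in old_to_new and b.j in old_to_new
    ]
    return MolecularSystem(atoms, bonds)


def _energy(sub: MolecularSystem, params: ParameterSet, provider) -> float:
    return total_energy(sub, params, provider).e_total


def interaction_energy_total(
    cluster: MolecularSystem, params: ParameterSet, charge_provider=None
) -> float:
    """IE_tot = E(cluster) − Σ E(monomer), all at the cluster geometry."""
    if cluster.n_molecules < 2:
        raise ValueError("interaction energy requires at least 2 molecules")
    e_cluster = _energy(cluster, params, charge_provider)
    e_monomers = sum(
        _energy(subsystem(cluster, [m]), params, charge_provider)
        for m in range(cluster.n_molecules)
    )
    return e_cluster - e_monomers


def two_body_energies(
    cluster: MolecularSystem, params: ParameterSet, charge_provider=None
) -> dict[tuple[int, int], float]:
    """ΔE₂(i,j) = E(dimer ij) − E(i) − E(j) for all molecule pairs."""
    if cluster.n_molecules < 2:
        raise ValueError("two-body energies require at least 2 molecules")
    mono = {
        m: _energy(subsystem(cluster, [m]), params, charge_provider)
        for m in range(cluster.n_molecules)
    }
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(cluster.n_molecules), 2):
        e_dimer = _energy(subsystem(cluster, [i, j]), params, charge_provider)
        out[(i, j)] = e_dimer - mono[i] - mono[j]
    return out


def many_body_energy(
    cluster: MolecularSystem, params: ParameterSet, charge_provider=None
) -> InteractionReport:
    """Full decomposition: IE_tot, all ΔE₂ and IE_mb = IE_tot − Σ ΔE₂."""
    if cluster.n_molecules < 2:
        raise ValueError("many-body decomposition requires at least 2 molecules")
    mono = {
        m: _energy(subsystem(cluster, [m]), params, charge_provider)
        for m in range(cluster.n_molecules)
    }
    e_cluster = _energy(cluster, params, charge_provider)
    ie_tot = e_cluster - sum(mono.values())
    two_body: dict[tuple[int, int], float] = {}
    dimers: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(cluster.n_molecules), 2):
        e_dimer = _energy(subsystem(cluster, [i, j]), params, charge_provider)
        dimers[(i, j)] = e_dimer
        two_body[(i, j)] = e_dimer - mono[i] - mono[j]
    ie_mb = ie_tot - sum(two_body.values())
    return InteractionReport(
        ie_tot=ie_tot,
        two_body=two_body,
        ie_mb=ie_mb,
        cluster_energy=e_cluster,
        monomer_energies=mono,
        dimer_energies=dimers,
    )
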