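"""Molecular data model: atoms, bonds, atom typing, topology and pair lists.

The model is deliberately small: Cartesian coordinates in Å, an explicit bond
list (connectivity is never perceived from distances), and atom types drawn
from a fixed carbohydrate/water alphabet:

======  =====================================================
type    meaning
======  =====================================================
CT      sp3 carbon
OS      ether/ring oxygen (two carbon neighbours)
OH      hydroxyl oxygen (one carbon, one hydrogen neighbour)
HO      hydroxyl hydrogen
H1      aliphatic hydrogen on a carbon bearing at most one oxygen
H2      aliphatic hydrogen on a carbon bearing two oxygens
OW      water oxygen (two hydrogens, no carbon)
HW      water hydrogen
======  =====================================================

Molecules are the connected components of the bond graph.  Only C, H and O
are supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MolecularSystem",
    "Topology",
    "BondDipoleSite",
    "TypingError",
    "assign_atom_types",
    "build_topology",
    "assign_bond_dipoles",
    "electrostatic_pair_list",
    "vdw_pair_list",
    "bond_element_class",
    "canonical_bond_key",
]

ATOM_TYPES = ("CT", "OS", "OH", "HO", "H1", "H2", "OW", "HW")

#: canonical ordering of elements inside a bond key: carbon, oxygen, hydrogen
_ELEMENT_RANK = {"C": 0, "O": 1, "H": 2}

#: element pairs that carry a bond dipole (C-C deliberately does not)
POLAR_ELEMENT_PAIRS = {("C", "O"), ("O", "H"), ("C", "H")}


class TypingError(ValueError):
    """Raised when an atom cannot be assigned one of the supported types."""


@dataclass
class Atom:
    index: int
    element: str
    position: np.ndarray
    atom_type: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite position")


@dataclass(frozen=True)
class Bond:
    """Undirected bond; stored once with i < j."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-loop bond")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)


def bond_element_class(ei: str, ej: str) -> tuple[str, str]:
    """Element pair of a bond in canonical (C, O, H) order."""
    return tuple(sorted((ei, ej), key=_ELEMENT_RANK.__getitem__))  # type: ignore[return-value]


def canonical_bond_key(ti: str, tj: str) -> str:
    """Type-pair key such as ``CT-OS`` or ``OH-HO`` (C before O before H)."""
    ranked = sorted((ti, tj), key=lambda t: _ELEMENT_RANK[_TYPE_ELEMENT[t]])
    return f"{ranked[0]}-{ranked[1]}"


_TYPE_ELEMENT = {
    "CT": "C",
    "OS": "O",
    "OH": "O",
    "HO": "H",
    "H1": "H",
    "H2": "H",
    "OW": "O",
    "HW": "H",
}


class MolecularSystem:
    """Atoms + bonds; molecule membership via connected components."""

    def __init__(self, atoms: list[Atom], bonds: list[Bond]):
        self.atoms = atoms
        seen: set[tuple[int, int]] = set()
        uniq: list[Bond] = []
        for b in bonds:
            key = (b.i, b.j)
            if key in seen:
                continue
            seen.add(key)
            uniq.append(b)
        self.bonds = uniq
        n = len(atoms)
        for idx, a in enumerate(atoms):
            if a.index != idx:
                raise ValueError("atom indices must be 0..n-1 in order")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references missing atom")
        self._graph: nx.Graph | None = None
        self._molecule_id: np.ndarray | None = None

    # -- derived structure ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_atoms))
            g.add_edges_from((b.i, b.j) for b in self.bonds)
            self._graph = g
        return self._graph

    @property
    def molecule_id(self) -> np.ndarray:
        """Connected-component label per atom, ordered by smallest member."""
        if self._molecule_id is None:
            comp = np.full(self.n_atoms, -1, dtype=int)
            comps = sorted(nx.connected_components(self.graph), key=min)
            for mol, members in enumerate(comps):
                for a in members:
                    comp[a] = mol
            self._molecule_id = comp
        return self._molecule_id

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1 if self.n_atoms else 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, coords):
            a.position = row.copy()

    def copy(self) -> "MolecularSystem":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        return MolecularSystem(atoms, list(self.bonds))

    def bond_length(self, bond: Bond) -> float:
        return float(
            np.linalg.norm(self.atoms[bond.i].position - self.atoms[bond.j].position)
        )

    def bond_key(self, bond: Bond) -> str:
        ti = self.atoms[bond.i].atom_type
        tj = self.atoms[bond.j].atom_type
        if ti is None or tj is None:
            raise TypingError("atom types not assigned; call assign_atom_types first")
        return canonical_bond_key(ti, tj)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.graph.neighbors(i))


# ---------------------------------------------------------------------------
# atom typing


def _neighbor_elements(system: MolecularSystem, i: int) -> list[str]:
    return [system.atoms[j].element for j in system.neighbors(i)]


def assign_atom_types(system: MolecularSystem) -> MolecularSystem:
    """Assign CT/OS/OH/HO/H1/H2/OW/HW types in place (and return the system).

    Typing is purely structural (no residue names) and idempotent.  Hydrogens
    on oxygen-free carbons are typed H1: the H1/H2 split encodes how many
    oxygens the parent carbon bears (≤1 vs 2), and an oxygen-free carbon is
    the ≤1 case.
    """
    for atom in system.atoms:
        if atom.element not in ("C", "H", "O"):
            raise TypingError(
                f"atom {atom.index}: unsupported element {atom.element!r}"
            )

    # oxygens and carbons first; hydrogens depend on their neighbour's type
    for atom in system.atoms:
        i = atom.index
        nbrs = system.neighbors(i)
        elems = _neighbor_elements(system, i)
        if atom.element == "C":
            if len(nbrs) > 4:
                raise TypingError(f"atom {i}: carbon with {len(nbrs)} bonds")
            atom.atom_type = "CT"
        elif atom.element == "O":
            n_c = elems.count("C")
            n_h = elems.count("H")
            if len(nbrs) != 2:
                raise TypingError(f"atom {i}: oxygen with {len(nbrs)} bonds")
            if n_c == 2:
                atom.atom_type = "OS"
            elif n_c == 1 and n_h == 1:
                atom.atom_type = "OH"
            elif n_h == 2:
                atom.atom_type = "OW"
            else:
                raise TypingError(f"atom {i}: untypeable oxygen environment")

    for atom in system.atoms:
        if atom.element != "H":
            continue
        i = atom.index
        nbrs = system.neighbors(i)
        if len(nbrs) != 1:
            raise TypingError(f"atom {i}: hydrogen with {len(nbrs)} bonds")
        parent = system.atoms[nbrs[0]]
        if parent.element == "O":
            atom.atom_type = {"OW": "HW", "OH": "HO"}.get(parent.atom_type or "")
            if atom.atom_type is None:
                raise TypingError(f"atom {i}: hydrogen on untypeable oxygen")
        elif parent.element == "C":
            n_ox = _neighbor_elements(system, parent.index).count("O")
            if n_ox >= 2:
                atom.atom_type = "H2"
            else:
                atom.atom_type = "H1"
        else:
            raise TypingError(f"atom {i}: hydrogen bonded to {parent.element}")
    return system


# ---------------------------------------------------------------------------
# topology


@dataclass
class Topology:
    """Angles, proper dihedrals and through-bond path distances."""

    angles: list[tuple[int, int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    _dist: dict[int, dict[int, int]] = field(repr=False, default_factory=dict)

    def bond_path_distance(self, i: int, j: int) -> int | None:
        """Minimal bond count between two atoms; None if disconnected."""
        if i == j:
            return 0
        return self._dist.get(i, {}).get(j)


def build_topology(system: MolecularSystem) -> Topology:
    """Enumerate unique angles/dihedrals and all-pairs bond-path distances."""
    g = system.graph
    angles: list[tuple[int, int, int]] = []
    for j in range(system.n_atoms):
        for i, k in itertools.combinations(system.neighbors(j), 2):
            angles.append((i, j, k))

    dihedrals: list[tuple[int, int, int, int]] = []
    for b in system.bonds:
        j, k = b.i, b.j
        for i in system.neighbors(j):
            if i == k:
                continue
            for l in system.neighbors(k):
                if l == j or l == i:
                    continue
                dihedrals.append((i, j, k, l))

    dist = {src: dict(d) for src, d in nx.all_pairs_shortest_path_length(g)}
    return Topology(angles=angles, dihedrals=dihedrals, _dist=dist)


# ---------------------------------------------------------------------------
# bond-dipole sites


@dataclass
class BondDipoleSite:
    """A polarizable point dipole on one polar bond.

    The axis is a unit vector pointing from the negative end of the bond to
    the positive end (O→C for C–O, O→H for O–H, C→H for C–H), optionally
    flipped by the per-key ``axis_sign`` parameter.  ``charge_atom`` is the
    atom whose partial charge drives the induced increment δμ (the positive
    terminal atom: the hydrogen for X–H bonds, the carbon for C–O bonds).
    """

    bond: Bond
    key: str
    center: np.ndarray
    axis: np.ndarray
    mu0: float
    delta_mu: float
    charge_atom: int
    molecule: int
    induced_enabled: bool

    @property
    def mu_total(self) -> float:
        return self.mu0 + self.delta_mu


def _polar_orientation(system: MolecularSystem, bond: Bond) -> tuple[int, int] | None:
    """(negative_atom, positive_atom) for a polar bond, None for apolar."""
    ei = system.atoms[bond.i].element
    ej = system.atoms[bond.j].element
    pair = bond_element_class(ei, ej)
    if pair not in POLAR_ELEMENT_PAIRS:
        return None
    if pair == ("C", "O"):
        neg, pos = ("O", "C")
    elif pair == ("O", "H"):
        neg, pos = ("O", "H")
    else:  # C-H
        neg, pos = ("C", "H")
    if ei == neg:
        return bond.i, bond.j
    return bond.j, bond.i


def assign_bond_dipoles(system: MolecularSystem, params) -> list[BondDipoleSite]:
    """One dipole site per polar (C–O, O–H, C–H) bond; C–C bonds are skipped.

    δμ is initialised to zero; :func:`pbdp.charges.update_induced_dipoles`
    fills it from a charge set.
    """
    from .params import MissingParameterError  # local import avoids a cycle

    sites: list[BondDipoleSite] = []
    mol = system.molecule_id
    frac = params.dipole.site_fraction
    for bond in system.bonds:
        orient = _polar_orientation(system, bond)
        if orient is None:
            continue
        neg, pos = orient
        key = system.bond_key(bond)
        if key not in params.dipole.mu0:
            raise MissingParameterError(f"no mu0 for polar bond key {key}")
        p_neg = system.atoms[neg].position
        p_pos = system.atoms[pos].position
        d = p_pos - p_neg
        length = float(np.linalg.norm(d))
        if length == 0.0:
            raise ValueError(f"zero-length bond ({bond.i},{bond.j})")
        axis = d / length * params.dipole.axis_sign.get(key, 1.0)
        sites.append(
            BondDipoleSite(
                bond=bond,
                key=key,
                center=p_neg + frac * d,
                axis=axis,
                mu0=params.dipole.mu0[key],
                delta_mu=0.0,
                charge_atom=pos,
                molecule=int(mol[bond.i]),
                induced_enabled=params.dipole.induced_enabled.get(key, False),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# pair lists


def _bonds_min_path(topology: Topology, a: Bond, b: Bond) -> int | None:
    """Bond count of the shortest through-bond path containing both bonds.

    Two bonds sharing an atom span a 2-bond path; otherwise the path is the
    two bonds plus the shortest atom path between their nearest endpoints.
    """
    if {a.i, a.j} & {b.i, b.j}:
        return 2
    best: int | None = None
    for x in (a.i, a.j):
        for y in (b.i, b.j):
            d = topology.bond_path_distance(x, y)
            if d is not None and (best is None or d < best):
                best = d
    if best is None:
        return None
    return best + 2


def electrostatic_pair_list(
    sites: list[BondDipoleSite],
    topology: Topology,
    min_bond_path: int = 3,
) -> list[tuple[int, int]]:
    """Site-index pairs entering the dipole–dipole sum.

    All intermolecular pairs are kept.  An intramolecular pair is kept iff
    the shortest covalent path containing both bonds spans at least
    ``min_bond_path`` bonds (default 3), which excludes pairs sharing an
    atom.  No distance-based scaling is applied to surviving pairs.
    """
    pairs: list[tuple[int, int]] = []
    for a, b in itertools.combinations(range(len(sites)), 2):
        sa, sb = sites[a], sites[b]
        if sa.molecule != sb.molecule:
            pairs.append((a, b))
            continue
        sep = _bonds_min_path(topology, sa.bond, sb.bond)
        if sep is not None and sep >= min_bond_path:
            pairs.append((a, b))
    return pairs


def vdw_pair_list(
    system: MolecularSystem,
    topology: Topology,
    scale_14: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Atom pairs (i, j, scale) for the 12-6 van der Waals sum.

    Intramolecular pairs at bond-path distance 1 or 2 are excluded, 1–4
    pairs (distance 3) are scaled by ``scale_14``, distance ≥4 and all
    intermolecular pairs get unit weight.
    """
    mol = system.molecule_id
    pairs: list[tuple[int, int, float]] = []
    for i, j in itertools.combinations(range(system.n_atoms), 2):
        if mol[i] != mol[j]:
            pairs.append((i, j, 1.0))
            continue
        d = topology.bond_path_distance(i, j)
        if d is None or d >= 4:
            pairs.append((i, j, 1.0))
        elif d == 3:
            pairs.append((i, j, scale_14))
    return pairs
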