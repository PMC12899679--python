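"""Synthetic structure generators: water clusters, polyols, an idealized
pyranose template, dipole test rigs and an environment-shift charge provider.

Everything here is generated programmatically — no coordinates are copied
from literature conformers.  Waters are rigid at the experimental monomer
geometry (O–H 0.9572 Å, H–O–H 104.52°); the pyranose template is an ideal
chair with ±60° ring torsions, built for typing/topology/counting tests
rather than for energetic realism.  All generators are deterministic under
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .charges import ChargeSet, charges_from_table
from .model import (
    Atom,
    Bond,
    BondDipoleSite,
    MolecularSystem,
    assign_atom_types,
)
from .params import ParameterSet

__all__ = [
    "WATER_OH",
    "WATER_ANGLE_DEG",
    "gen_water",
    "gen_water_cluster",
    "gen_water_dimer",
    "gen_alkane_chain",
    "gen_polyol_chain",
    "gen_pyranose_template",
    "gen_dipole_rig",
    "EnvironmentShiftProvider",
    "environment_shift_provider",
]

WATER_OH = 0.9572  # Å
WATER_ANGLE_DEG = 104.52

_CC = 1.520
_CO = 1.410
_OH = 0.960
_CH = 1.092
_TET = math.acos(-1.0 / 3.0)  # 109.471°


# ---------------------------------------------------------------------------
# small geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _any_perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = _unit(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _tet_complete(existing: list[np.ndarray]) -> list[np.ndarray]:
    """Unit directions completing an sp3 center to four bonds."""
    n = len(existing)
    if n == 1:
        # directions at the tetrahedral angle from u, azimuths 120° apart
        u = _unit(existing[0])
        p = _any_perp(u)
        out = []
        for k in range(3):
            az = _rot(u, 2.0 * math.pi * k / 3.0) @ p
            out.append(_unit(math.cos(_TET) * u + math.sin(_TET) * az))
        return out
    if n == 2:
        u1, u2 = (_unit(v) for v in existing)
        n1 = _unit(u1 + u2)
        n2 = _unit(np.cross(u1, u2))
        cos_gamma = float(np.dot(n1, u1))
        alpha = (-1.0 / 3.0) / cos_gamma
        alpha = max(-1.0, min(1.0, alpha))
        beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
        return [_unit(alpha * n1 + beta * n2), _unit(alpha * n1 - beta * n2)]
    if n == 3:
        return [-_unit(sum(_unit(v) for v in existing))]
    raise ValueError("need 1-3 existing bond directions")


def _hydroxyl_h(o_pos: np.ndarray, c_pos: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """Place the hydroxyl hydrogen: C–O–H ≈ 107°, tilted toward ``outward``."""
    u = _unit(o_pos - c_pos)
    perp = outward - np.dot(outward, u) * u
    if np.linalg.norm(perp) < 1e-8:
        perp = _any_perp(u)
    perp = _unit(perp)
    direction = _unit(math.cos(math.radians(73.0)) * u + math.sin(math.radians(73.0)) * perp)
    return o_pos + _OH * direction


# ---------------------------------------------------------------------------
# waters


def gen_water(
    origin: np.ndarray | None = None, rotation: np.ndarray | None = None
) -> tuple[list[str], np.ndarray]:
    """(elements, coords) of one rigid water, O first."""
    half = math.radians(WATER_ANGLE_DEG / 2.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH * math.sin(half), 0.0, WATER_OH * math.cos(half)],
            [-WATER_OH * math.sin(half), 0.0, WATER_OH * math.cos(half)],
        ]
    )
    if rotation is not None:
        coords = coords @ rotation.T
    if origin is not None:
        coords = coords + origin
    return ["O", "H", "H"], coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_water_cluster(
    n: int,
    seed: int = 0,
    min_oo: float = 2.5,
    box: float | None = None,
    max_attempts: int = 5000,
) -> MolecularSystem:
    """n rigid waters placed by rejection sampling in a cube.

    The cube is sized for roughly liquid-like packing (40 Å³ per molecule)
    unless ``box`` is given.  Oxygen–oxygen distances respect ``min_oo``.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    side = box if box is not None else max(4.0, (n * 40.0) ** (1.0 / 3.0))
    oxygens: list[np.ndarray] = []
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for _mol in range(n):
        for attempt in range(max_attempts):
            pos = rng.uniform(0.0, side, size=3)
            if all(np.linalg.norm(pos - o) >= min_oo for o in oxygens):
                break
        else:
            raise RuntimeError(
                f"could not place water {_mol + 1}/{n} after {max_attempts} "
                "attempts; enlarge the box"
            )
        oxygens.append(pos)
        elements, coords = gen_water(origin=pos, rotation=_random_rotation(rng))
        base = len(atoms)
        for el, xyz in zip(elements, coords):
            atoms.append(Atom(len(atoms), el, xyz))
        bonds += [Bond(base, base + 1), Bond(base, base + 2)]
    return assign_atom_types(MolecularSystem(atoms, bonds))


def gen_water_dimer(r_oo: float = 2.9) -> MolecularSystem:
    """Ideal linear hydrogen-bonded water dimer (donor H on the O···O line)."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    # donor: O at origin, one H pointing along +x toward the acceptor
    half = math.radians(WATER_ANGLE_DEG)
    d_o = np.array([0.0, 0.0, 0.0])
    d_h1 = np.array([WATER_OH, 0.0, 0.0])
    d_h2 = np.array([WATER_OH * math.cos(half), WATER_OH * math.sin(half), 0.0])
    # acceptor at (r_oo, 0, 0), plane perpendicular-ish, hydrogens pointing away
    a_o = np.array([r_oo, 0.0, 0.0])
    ha = math.radians(WATER_ANGLE_DEG / 2.0)
    bisector = _unit(np.array([1.0, 0.0, 1.0]))  # tilted away from the donor
    perp = _unit(np.cross(bisector, np.array([0.0, 1.0, 0.0])))
    a_h1 = a_o + WATER_OH * (math.cos(ha) * bisector + math.sin(ha) * perp)
    a_h2 = a_o + WATER_OH * (math.cos(ha) * bisector - math.sin(ha) * perp)
    for el, pos in [
        ("O", d_o), ("H", d_h1), ("H", d_h2),
        ("O", a_o), ("H", a_h1), ("H", a_h2),
    ]:
        atoms.append(Atom(len(atoms), el, pos))
    bonds += [Bond(0, 1), Bond(0, 2), Bond(3, 4), Bond(3, 5)]
    return assign_atom_types(MolecularSystem(atoms, bonds))


# ---------------------------------------------------------------------------
# chains


def _zigzag_carbons(n: int, bond: float = _CC) -> np.ndarray:
    v_plus = bond * np.array([math.cos(_TET / 2.0), math.sin(_TET / 2.0), 0.0])
    v_minus = bond * np.array([math.cos(_TET / 2.0), -math.sin(_TET / 2.0), 0.0])
    pos = [np.zeros(3)]
    for k in range(1, n):
        pos.append(pos[-1] + (v_plus if k % 2 else v_minus))
    return np.array(pos)


def gen_alkane_chain(n_carbons: int) -> MolecularSystem:
    """Linear alkane CnH2n+2 (toy fixture for pair-list and scaling tests)."""
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    cpos = _zigzag_carbons(n_carbons)
    atoms = [Atom(i, "C", cpos[i]) for i in range(n_carbons)]
    bonds = [Bond(i, i + 1) for i in range(n_carbons - 1)]

    def add_h(direction: np.ndarray, c_idx: int) -> None:
        atoms.append(Atom(len(atoms), "H", cpos[c_idx] + _CH * direction))
        bonds.append(Bond(c_idx, len(atoms) - 1))

    for i in range(n_carbons):
        existing = []
        if i > 0:
            existing.append(cpos[i - 1] - cpos[i])
        if i < n_carbons - 1:
            existing.append(cpos[i + 1] - cpos[i])
        if not existing:  # methane
            existing = [np.array([0.0, 0.0, 1.0])]
            add_h(np.array([0.0, 0.0, 1.0]), i)
        for d in _tet_complete(existing):
            add_h(d, i)
    return assign_atom_types(MolecularSystem(atoms, bonds))


def gen_polyol_chain(n_carbons: int) -> MolecularSystem:
    """Alditol-like chain: every carbon bears one hydroxyl.

    HOCH₂–(CHOH)ₙ₋₂–CH₂OH; end carbons carry two hydrogens, inner carbons
    one.  Hydroxyls alternate above/below the carbon plane.
    """
    if n_carbons < 2:
        raise ValueError("need at least two carbons")
    cpos = _zigzag_carbons(n_carbons)
    atoms = [Atom(i, "C", cpos[i]) for i in range(n_carbons)]
    bonds = [Bond(i, i + 1) for i in range(n_carbons - 1)]

    def add(element: str, pos: np.ndarray, parent: int) -> int:
        atoms.append(Atom(len(atoms), element, pos))
        bonds.append(Bond(parent, len(atoms) - 1))
        return len(atoms) - 1

    for i in range(n_carbons):
        existing = []
        if i > 0:
            existing.append(cpos[i - 1] - cpos[i])
        if i < n_carbons - 1:
            existing.append(cpos[i + 1] - cpos[i])
        dirs = _tet_complete(existing)
        # hydroxyl alternates sides: pick the direction with ±z preference
        want_up = i % 2 == 0
        dirs.sort(key=lambda d: -d[2] if want_up else d[2])
        o_dir, h_dirs = dirs[0], dirs[1:]
        o_pos = cpos[i] + _CO * o_dir
        o_idx = add("O", o_pos, i)
        outward = o_pos - cpos[i] + np.array([0.0, 0.0, 0.3 if want_up else -0.3])
        h_o = _hydroxyl_h(o_pos, cpos[i], outward)
        add("H", h_o, o_idx)
        for d in h_dirs:
            add("H", cpos[i] + _CH * d, i)
    return assign_atom_types(MolecularSystem(atoms, bonds))


# ---------------------------------------------------------------------------
# pyranose template


def gen_pyranose_template(anomer: str = "alpha") -> MolecularSystem:
    """Idealized chair-ring aldohexopyranose, C₆H₁₂O₆, 24 atoms.

    Ring atoms (O5, C1…C5) sit on an ideal chair; C1 is the anomeric carbon
    carrying the exocyclic hydroxyl axially (alpha) or equatorially (beta).
    C2–C4 hydroxyls are equatorial, C5 bears the exocyclic CH₂OH arm.  The
    template exercises typing (CT/OS/OH/HO/H1/H2), topology and dipole-site
    assignment; it is not a literature conformer.
    """
    if anomer not in ("alpha", "beta"):
        raise ValueError("anomer must be 'alpha' or 'beta'")
    # ideal chair: radius a and pucker q chosen for ~1.52 Å ring bonds
    q = 0.25
    a = math.sqrt(1.52**2 - 4.0 * q * q)
    ring_pos = []
    for k in range(6):
        ang = math.pi / 3.0 * k
        ring_pos.append(
            np.array([a * math.cos(ang), a * math.sin(ang), q * (-1.0) ** k])
        )
    # ring order: O5, C1, C2, C3, C4, C5
    elements = ["O", "C", "C", "C", "C", "C"]
    atoms = [Atom(i, el, ring_pos[i]) for i, el in enumerate(elements)]
    bonds = [Bond(i, (i + 1) % 6) for i in range(6)]
    O5, C1, C2, C3, C4, C5 = range(6)

    def add(element: str, pos: np.ndarray, parent: int) -> int:
        atoms.append(Atom(len(atoms), element, pos))
        bonds.append(Bond(parent, len(atoms) - 1))
        return len(atoms) - 1

    centroid = np.mean(ring_pos, axis=0)

    def substituent_dirs(c: int) -> tuple[np.ndarray, np.ndarray]:
        """(axial, equatorial) unit directions at ring carbon ``c``."""
        nbrs = [(c - 1) % 6, (c + 1) % 6]
        existing = [ring_pos[n] - ring_pos[c] for n in nbrs]
        d1, d2 = _tet_complete(existing)
        return (d1, d2) if abs(d1[2]) >= abs(d2[2]) else (d2, d1)

    def add_hydroxyl(c: int, direction: np.ndarray) -> None:
        o_pos = atoms[c].position + _CO * direction
        o_idx = add("O", o_pos, c)
        outward = o_pos - centroid
        add("H", _hydroxyl_h(o_pos, atoms[c].position, outward), o_idx)

    for c in (C1, C2, C3, C4):
        ax, eq = substituent_dirs(c)
        if c == C1:
            o_dir, h_dir = (ax, eq) if anomer == "alpha" else (eq, ax)
        else:
            o_dir, h_dir = eq, ax
        add_hydroxyl(c, o_dir)
        add("H", atoms[c].position + _CH * h_dir, c)

    # C5: exocyclic CH2OH equatorial, ring hydrogen axial
    ax, eq = substituent_dirs(C5)
    c6_pos = atoms[C5].position + _CC * eq
    c6 = add("C", c6_pos, C5)
    add("H", atoms[C5].position + _CH * ax, C5)
    arm_dirs = _tet_complete([atoms[C5].position - c6_pos])
    add_hydroxyl_dir = arm_dirs[0]
    o6_pos = c6_pos + _CO * add_hydroxyl_dir
    o6 = add("O", o6_pos, c6)
    add("H", _hydroxyl_h(o6_pos, c6_pos, o6_pos - centroid), o6)
    for d in arm_dirs[1:]:
        add("H", c6_pos + _CH * d, c6)

    return assign_atom_types(MolecularSystem(atoms, bonds))


# ---------------------------------------------------------------------------
# dipole rigs


def gen_dipole_rig(
    alpha: float,
    alpha_prime: float,
    beta: float,
    r: float,
    mu_i: float = 1.0,
    mu_j: float = 1.0,
    delta_mu_i: float = 0.0,
    delta_mu_j: float = 0.0,
) -> tuple[BondDipoleSite, BondDipoleSite]:
    """Two free-standing dipole sites realizing the requested geometry.

    Angles in radians: ``alpha`` between site i's axis and the center line
    i→j, ``alpha_prime`` between site j's axis and the line j→i, ``beta``
    the azimuthal dihedral.  The sites carry synthetic bonds and are meant
    for direct evaluation of the pair-energy formula.
    """
    if r <= 0:
        raise ValueError("center separation must be positive")
    axis_i = np.array([math.cos(alpha), 0.0, math.sin(alpha)])
    axis_j = np.array(
        [
            -math.cos(alpha_prime),
            math.sin(alpha_prime) * math.sin(beta),
            math.sin(alpha_prime) * math.cos(beta),
        ]
    )
    site_i = BondDipoleSite(
        bond=Bond(0, 1), key="RIG", center=np.zeros(3), axis=axis_i,
        mu0=mu_i, delta_mu=delta_mu_i, charge_atom=1, molecule=0,
        induced_enabled=False,
    )
    site_j = BondDipoleSite(
        bond=Bond(2, 3), key="RIG", center=np.array([r, 0.0, 0.0]), axis=axis_j,
        mu0=mu_j, delta_mu=delta_mu_j, charge_atom=3, molecule=1,
        induced_enabled=False,
    )
    return site_i, site_j


# ---------------------------------------------------------------------------
# environment-shift charge provider


@dataclass
class EnvironmentShiftProvider:
    """q0-table charges, plus Δq on every hydrogen when ≥2 molecules present.

    The minimal non-additive provider: subsystem evaluations of monomers see
    unshifted charges while dimers and the full cluster see shifted ones,
    which makes the many-body energy nonzero and hand-computable.
    """

    params: ParameterSet
    delta_q: float = 0.0
    geometry_dependent: bool = False

    def __call__(self, system: MolecularSystem) -> ChargeSet:
        base = charges_from_table(system, self.params.dipole)
        if system.n_molecules >= 2 and self.delta_q != 0.0:
            vals = base.values.copy()
            for atom in system.atoms:
                if atom.element == "H":
                    vals[atom.index] += self.delta_q
            return ChargeSet(vals, provenance="table", scope="whole-system")
        return base


def environment_shift_provider(
    params: ParameterSet, delta_q: float
) -> EnvironmentShiftProvider:
    return EnvironmentShiftProvider(params=params, delta_q=delta_q)
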