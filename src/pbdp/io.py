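"""Structure file I/O: XYZ + companion connectivity, and a PDB subset.

All file formats use 1-based atom indices; everything in memory is 0-based.
The XYZ dialect is the plain count/comment/element-x-y-z form; connectivity
is a companion text file with one ``i j`` bond per line.  The PDB reader
consumes ATOM/HETATM coordinates and CONECT records only (no residue logic,
no bond perception from distances).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Atom, Bond, MolecularSystem

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_connectivity",
    "write_connectivity",
    "load_system",
    "save_system",
    "read_pdb",
]


class FileFormatError(ValueError):
    pass


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, str]:
    """(elements, coords (N,3) Å, comment) from an XYZ file."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FileFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FileFormatError(f"{path}: bad atom count line") from exc
    comment = lines[1] if len(lines) > 1 else ""
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise FileFormatError(f"{path}: expected {n} atom lines, got {len(body)}")
    elements: list[str] = []
    coords = np.empty((n, 3))
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise FileFormatError(f"{path}: malformed atom line {k + 3}")
        elements.append(parts[0].capitalize())
        try:
            coords[k] = [float(x) for x in parts[1:4]]
        except ValueError as exc:
            raise FileFormatError(f"{path}: non-numeric coordinate, line {k + 3}") from exc
    return elements, coords, comment


def write_xyz(system: MolecularSystem, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for a in system.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_connectivity(path: str | Path) -> list[tuple[int, int]]:
    """0-based bond pairs from a 1-based ``i j`` per-line file."""
    bonds: list[tuple[int, int]] = []
    for ln_no, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = ln.split("#")[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise FileFormatError(f"{path}: line {ln_no}: expected two indices")
        i, j = int(parts[0]), int(parts[1])
        if i < 1 or j < 1:
            raise FileFormatError(f"{path}: line {ln_no}: indices are 1-based")
        bonds.append((i - 1, j - 1))
    return bonds


def write_connectivity(system: MolecularSystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in system.bonds:
            fh.write(f"{b.i + 1} {b.j + 1}\n")


def load_system(
    xyz_path: str | Path, connectivity_path: str | Path
) -> MolecularSystem:
    """Build a system from an XYZ file plus its companion bond list."""
    elements, coords, _ = read_xyz(xyz_path)
    bonds = read_connectivity(connectivity_path)
    atoms = [Atom(i, el, xyz) for i, (el, xyz) in enumerate(zip(elements, coords))]
    return MolecularSystem(atoms, [Bond(i, j) for i, j in bonds])


def save_system(
    system: MolecularSystem,
    xyz_path: str | Path,
    connectivity_path: str | Path,
    comment: str = "",
) -> None:
    write_xyz(system, xyz_path, comment)
    write_connectivity(system, connectivity_path)


_PDB_ELEMENTS = {"C", "O", "H"}


def read_pdb(path: str | Path) -> MolecularSystem:
    """ATOM/HETATM coordinates + CONECT bonds (1-based serials).

    The element is taken from columns 77–78 when present, else from the
    first letter of the atom name.  Records without CONECT partners yield
    single-atom molecules, matching the connected-component convention.
    """
    serial_to_idx: dict[int, int] = {}
    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    for ln in Path(path).read_text().splitlines():
        rec = ln[:6].strip()
        if rec in ("ATOM", "HETATM"):
            serial = int(ln[6:11])
            name = ln[12:16].strip()
            x = float(ln[30:38])
            y = float(ln[38:46])
            z = float(ln[46:54])
            element = ln[76:78].strip().capitalize() if len(ln) >= 78 else ""
            if not element:
                element = name[0].upper()
            if element not in _PDB_ELEMENTS:
                raise FileFormatError(
                    f"{path}: unsupported element {element!r} (serial {serial})"
                )
            serial_to_idx[serial] = len(atoms)
            atoms.append(Atom(len(atoms), element, np.array([x, y, z])))
        elif rec == "CONECT":
            fields = ln.split()
            base = int(fields[1])
            for other in fields[2:]:
                pair = tuple(sorted((base, int(other))))
                bonds.add(pair)  # type: ignore[arg-type]
    try:
        bond_list = [Bond(serial_to_idx[i], serial_to_idx[j]) for i, j in bonds]
    except KeyError as exc:
        raise FileFormatError(f"{path}: CONECT references unknown serial {exc}") from exc
    return MolecularSystem(atoms, bond_list)
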