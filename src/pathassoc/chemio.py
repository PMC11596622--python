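"""Reading and writing CTAB V2000 molfiles as heavy-atom molecular graphs.

Compounds arrive as one molfile per compound (the filename stem is the
compound identifier).  Only the connection table is kept: element symbols,
formal charges, and bonds with their integer order (4 = aromatic, retained
as written; no kekulization).  Coordinates are parsed positionally and
discarded.  Hydrogens are removed explicitly with :func:`strip_hydrogens`
because every downstream quantity -- atom colors, compound size, pathway
size -- is defined on the hydrogen-free graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path


class MolfileError(ValueError):
    """Malformed or unsupported molfile content."""


class EmptyMoleculeError(MolfileError):
    """A molecule with no atoms (or no heavy atoms) where one is required."""


@dataclass(frozen=True)
class Molecule:
    """A molecular graph over explicit atoms.

    Parameters
    ----------
    compound_id : str
        Identifier of the compound (typically the molfile stem).
    atoms : tuple of (str, int)
        Ordered ``(element, formal_charge)`` pairs.
    bonds : tuple of (int, int, int)
        ``(i, j, order)`` with 0-based endpoints, ``i < j``, no duplicates.
    size : int
        Number of non-hydrogen atoms.  Equals ``len(atoms)`` once
        hydrogens have been stripped.
    """

    compound_id: str
    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, int], ...]
    size: int = field(default=-1)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise MolfileError(
                    f"{self.compound_id}: bond ({i}, {j}) references an "
                    f"atom outside 0..{n - 1}"
                )
            if i == j:
                raise MolfileError(f"{self.compound_id}: self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MolfileError(
                    f"{self.compound_id}: duplicate bond between atoms {i} and {j}"
                )
            seen.add(key)
        if self.size < 0:
            object.__setattr__(
                self, "size", sum(1 for el, _ in self.atoms if el != "H")
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency list of ``(neighbor_index, bond_order)`` per atom."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


def parse_molfile(text: str, compound_id: str | None = None) -> Molecule:
    """Parse a CTAB V2000 molfile into a :class:`Molecule`.

    Hydrogens are *not* removed here.  Formal charges come from ``M  CHG``
    property lines; the legacy atom-block charge column is ignored.  V3000
    files are rejected.

    Raises
    ------
    MolfileError
        Malformed counts line, truncated atom/bond block, out-of-range
        bond endpoint, or a V3000 connection table.
    EmptyMoleculeError
        The counts line declares zero atoms.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile has fewer than 4 lines (no counts line)")
    if compound_id is None:
        compound_id = lines[0].strip() or "unnamed"
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError(f"{compound_id}: V3000 molfiles are not supported")
    if "V2000" not in counts:
        raise MolfileError(
            f"{compound_id}: counts line (line 4) lacks the V2000 tag: {counts!r}"
        )
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise MolfileError(
            f"{compound_id}: cannot read atom/bond counts from line 4: {counts!r}"
        ) from exc
    if n_atoms == 0:
        raise EmptyMoleculeError(f"{compound_id}: molfile declares zero atoms")

    atom_lines = lines[4 : 4 + n_atoms]
    if len(atom_lines) < n_atoms:
        raise MolfileError(
            f"{compound_id}: counts line declares {n_atoms} atoms but the "
            f"atom block has only {len(atom_lines)} lines"
        )
    elements: list[str] = []
    for i, ln in enumerate(atom_lines):
        # fixed-width: x(10) y(10) z(10) space symbol(3)
        symbol = ln[31:34].strip() if len(ln) >= 32 else ""
        if not symbol or not symbol.isalpha():
            raise MolfileError(
                f"{compound_id}: counts line declares {n_atoms} atoms but "
                f"line {i + 1} of the atom block is not an atom line: {ln!r}"
            )
        elements.append(symbol)

    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(bond_lines) < n_bonds:
        raise MolfileError(
            f"{compound_id}: counts line declares {n_bonds} bonds but the "
            f"bond block has only {len(bond_lines)} lines"
        )
    bonds: list[tuple[int, int, int]] = []
    for ln in bond_lines:
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except ValueError as exc:
            raise MolfileError(f"{compound_id}: malformed bond line: {ln!r}") from exc
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise MolfileError(
                f"{compound_id}: bond line references atom outside "
                f"1..{n_atoms}: {ln!r}"
            )
        lo, hi = min(a, b), max(a, b)
        bonds.append((lo, hi, order))

    charges = {i: 0 for i in range(n_atoms)}
    for ln in lines[4 + n_atoms + n_bonds :]:
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n_entries = int(fields[2])
            vals = fields[3 : 3 + 2 * n_entries]
            for k in range(n_entries):
                idx = int(vals[2 * k]) - 1
                chg = int(vals[2 * k + 1])
                if not 0 <= idx < n_atoms:
                    raise MolfileError(
                        f"{compound_id}: M  CHG references atom {idx + 1} "
                        f"outside 1..{n_atoms}"
                    )
                charges[idx] = chg
        elif ln.startswith("M  END"):
            break

    atoms = tuple((el, charges[i]) for i, el in enumerate(elements))
    return Molecule(compound_id=compound_id, atoms=atoms, bonds=tuple(bonds))


def strip_hydrogens(mol: Molecule) -> Molecule:
    """Remove explicit hydrogen atoms and their bonds.

    Surviving atoms keep their relative order; bond endpoints are remapped.
    Idempotent.  Raises :class:`EmptyMoleculeError` if nothing remains.
    """
    keep = [i for i, (el, _) in enumerate(mol.atoms) if el != "H"]
    if not keep:
        raise EmptyMoleculeError(
            f"{mol.compound_id}: molecule consists only of hydrogens"
        )
    if len(keep) == mol.n_atoms:
        return replace(mol, size=mol.n_atoms)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = tuple(mol.atoms[i] for i in keep)
    bonds = tuple(
        (remap[i], remap[j], order)
        for i, j, order in mol.bonds
        if i in remap and j in remap
    )
    return Molecule(
        compound_id=mol.compound_id, atoms=atoms, bonds=bonds, size=len(atoms)
    )


def write_molfile(mol: Molecule, title: str | None = None) -> str:
    """Serialize a molecule as a minimal V2000 molfile (zero coordinates).

    Round-trips through :func:`parse_molfile`: the parsed graph equals the
    input graph (same atom order, charges, bonds).
    """
    lines = [title if title is not None else mol.compound_id, "", ""]
    lines.append(f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, _chg in mol.atoms:
        lines.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in mol.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    charged = [(i + 1, chg) for i, (_, chg) in enumerate(mol.atoms) if chg != 0]
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        parts = "".join(f"{idx:4d}{chg:4d}" for idx, chg in chunk)
        lines.append(f"M  CHG{len(chunk):3d}{parts}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_molfile_dir(path: str | Path) -> list[Molecule]:
    """Parse every ``*.mol`` file in a directory; stems become compound ids."""
    path = Path(path)
    mols = []
    for f in sorted(path.glob("*.mol")):
        mols.append(parse_molfile(f.read_text(), compound_id=f.stem))
    return mols


def molecules_equal(a: Molecule, b: Molecule) -> bool:
    """Graph equality at fixed atom order (id excluded)."""
    return a.atoms == b.atoms and sorted(a.bonds) == sorted(b.bonds)
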