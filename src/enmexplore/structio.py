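"""Structure I/O and geometric primitives.

Reads and writes PDB files through Biopython, keeps an array-backed
in-memory representation, and provides the superposition, RMSD and
radius-of-gyration operations used throughout the pipeline.

Conventions
-----------
* Coordinates are in Angstrom everywhere.
* Residues carry a 0-based, globally contiguous internal index; the
  author-assigned (chain, resseq, icode) numbering is preserved only for
  round-tripping to PDB.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altLoc label order).
* HETATM residues are dropped by default; ``keep_hetatm=True`` retains
  them as ordinary residues.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "AtomRecord",
    "Structure",
    "CoarseModel",
    "Superposition",
    "StructureError",
    "AlignmentError",
    "read_pdb",
    "write_pdb",
    "coarse_grain",
    "superpose",
    "rmsd_ca",
    "radius_of_gyration",
    "kabsch",
    "kabsch_rmsd_many",
]


class StructureError(ValueError):
    """Malformed or empty structural content."""


class AlignmentError(ValueError):
    """Atom selections that cannot be paired one-to-one."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    is_heavy: bool


@dataclasses.dataclass(frozen=True)
class ResidueKey:
    chain_id: str
    resseq: int
    icode: str
    resname: str


class Structure:
    """All-atom structure backed by parallel numpy arrays.

    Atom order is stable under a read -> write -> read round trip.
    """

    def __init__(
        self,
        coords: np.ndarray,
        names: Sequence[str],
        elements: Sequence[str],
        serials: Sequence[int],
        atom_residue: np.ndarray,
        residue_table: Sequence[ResidueKey],
    ):
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self.names = list(names)
        self.elements = [e.upper() for e in elements]
        self.serials = np.asarray(serials, dtype=int)
        self.atom_residue = np.asarray(atom_residue, dtype=int)
        self.residue_table = list(residue_table)
        n = len(self.names)
        if not (len(self.elements) == len(self.serials) == len(self.atom_residue) == self.coords.shape[0] == n):
            raise StructureError("inconsistent atom array lengths")
        if self.n_residues and not np.array_equal(
            np.unique(self.atom_residue), np.arange(self.n_residues)
        ):
            raise StructureError("residue indices must be 0-based and contiguous")
        self.is_heavy = np.array([e != "H" for e in self.elements], dtype=bool)
        for i in range(self.n_residues):
            if not self.is_heavy[self.atom_residue == i].any():
                raise StructureError(f"residue {i} has no heavy atoms")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residue_table)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for key in self.residue_table:
            if key.chain_id not in seen:
                seen.append(key.chain_id)
        return seen

    def chain_spans(self) -> dict[str, tuple[int, int]]:
        """Half-open residue-index range per chain."""
        spans: dict[str, tuple[int, int]] = {}
        for i, key in enumerate(self.residue_table):
            if key.chain_id not in spans:
                spans[key.chain_id] = (i, i + 1)
            else:
                lo, _ = spans[key.chain_id]
                spans[key.chain_id] = (lo, i + 1)
        return spans

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            ri = int(self.atom_residue[i])
            yield AtomRecord(
                serial=int(self.serials[i]),
                name=self.names[i],
                element=self.elements[i],
                residue_index=ri,
                chain_id=self.residue_table[ri].chain_id,
                position=self.coords[i].copy(),
                is_heavy=bool(self.is_heavy[i]),
            )

    def ca_indices(self, chains: Sequence[str] | None = None) -> np.ndarray:
        mask = np.array(
            [n.strip() == "CA" and e == "C" for n, e in zip(self.names, self.elements)],
            dtype=bool,
        )
        if chains is not None:
            chainset = set(chains)
            chain_of_atom = np.array(
                [self.residue_table[r].chain_id for r in self.atom_residue]
            )
            mask &= np.isin(chain_of_atom, list(chainset))
        return np.nonzero(mask)[0]

    def ca_coords(self, chains: Sequence[str] | None = None) -> np.ndarray:
        idx = self.ca_indices(chains)
        if idx.size == 0:
            raise StructureError("no C-alpha atoms in selection")
        return self.coords[idx]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy sharing topology with replaced coordinates."""
        new = object.__new__(Structure)
        new.coords = np.asarray(coords, dtype=float).reshape(self.coords.shape).copy()
        new.names = self.names
        new.elements = self.elements
        new.serials = self.serials
        new.atom_residue = self.atom_residue
        new.residue_table = self.residue_table
        new.is_heavy = self.is_heavy
        return new

    def subset_chains(self, chains: Sequence[str]) -> "Structure":
        chainset = set(chains)
        keep_res = [i for i, k in enumerate(self.residue_table) if k.chain_id in chainset]
        if not keep_res:
            raise StructureError(f"no residues in chains {sorted(chainset)}")
        remap = {old: new for new, old in enumerate(keep_res)}
        keep_atoms = np.isin(self.atom_residue, keep_res)
        return Structure(
            coords=self.coords[keep_atoms],
            names=[n for n, k in zip(self.names, keep_atoms) if k],
            elements=[e for e, k in zip(self.elements, keep_atoms) if k],
            serials=self.serials[keep_atoms],
            atom_residue=np.array([remap[r] for r in self.atom_residue[keep_atoms]]),
            residue_table=[self.residue_table[i] for i in keep_res],
        )


@dataclasses.dataclass
class CoarseModel:
    """One node per residue at the mean heavy-atom position."""

    centroids: np.ndarray  # (N, 3)
    membership: list[np.ndarray]  # residue index -> atom indices
    n_nodes: int


@dataclasses.dataclass
class Superposition:
    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    selection: str

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ----------------------------------------------------------------------
# PDB I/O
# ----------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit() or stripped[0] == "H":
        return "H" if stripped.lstrip("0123456789").startswith("H") else stripped[0]
    return stripped[0]


def read_pdb(path: str | Path, model_index: int = 0, keep_hetatm: bool = False) -> Structure:
    """Parse one model of a PDB file into a :class:`Structure`.

    Alternate locations collapse to the highest-occupancy atom; hydrogens
    are retained but flagged; water and (by default) other HETATM residues
    are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio = parser.get_structure("s", str(path))
        except Exception as exc:  # Biopython raises assorted ValueErrors
            raise StructureError(f"unparseable PDB file {path}: {exc}") from exc
    models = list(bio.get_models())
    if model_index >= len(models):
        raise StructureError(f"model {model_index} not present ({len(models)} models)")
    model = models[model_index]

    coords, names, elements, serials, atom_residue = [], [], [], [], []
    residue_table: list[ResidueKey] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag == "W":
                continue
            if hetflag.strip() and residue.resname not in _STANDARD_AA and not keep_hetatm:
                continue
            atoms = []
            for atom in residue.get_unpacked_list():
                atoms.append(atom)
            # resolve altLocs: highest occupancy wins, label order breaks ties
            by_name: dict[str, list] = {}
            for atom in atoms:
                by_name.setdefault(atom.get_name(), []).append(atom)
            chosen = []
            for name, group in by_name.items():
                group.sort(key=lambda a: (-(a.get_occupancy() or 1.0), a.get_altloc()))
                chosen.append(group[0])
            chosen.sort(key=lambda a: a.get_serial_number() or 0)
            if not chosen:
                continue
            ri = len(residue_table)
            residue_table.append(
                ResidueKey(chain.id, int(resseq), icode.strip() or "", residue.resname)
            )
            for atom in chosen:
                coords.append(atom.get_coord())
                names.append(atom.get_name())
                element = (atom.element or "").strip() or _guess_element(atom.get_name())
                elements.append(element)
                serials.append(atom.get_serial_number() or len(serials) + 1)
                atom_residue.append(ri)
    if not residue_table:
        raise StructureError(f"model {model_index} of {path} contains no residues")
    return Structure(
        np.asarray(coords, dtype=float), names, elements, serials,
        np.asarray(atom_residue), residue_table,
    )


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: one-letter elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(
    structures: Structure | Sequence[Structure],
    path: str | Path,
    model_index: int | None = None,
) -> None:
    """Write one structure (plain ATOM records) or several (MODEL blocks).

    Author residue numbering is preserved. Coordinates are emitted at the
    standard three-decimal PDB precision.
    """
    if isinstance(structures, Structure):
        ensemble = [structures]
        multi = model_index is not None
    else:
        ensemble = list(structures)
        multi = True
    path = Path(path)
    lines: list[str] = []
    for mi, s in enumerate(ensemble, start=(model_index or 1) if model_index else 1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 0
        prev_chain = None
        for atom in s.atoms():
            key = s.residue_table[atom.residue_index]
            if prev_chain is not None and key.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = key.chain_id
            serial += 1
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)} "
                f"{key.resname:>3s} {key.chain_id:1s}{key.resseq:4d}{key.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Geometry
# ----------------------------------------------------------------------

def coarse_grain(structure: Structure) -> CoarseModel:
    """One node per residue at the mean of its heavy-atom positions."""
    centroids = np.empty((structure.n_residues, 3))
    membership: list[np.ndarray] = []
    for i in range(structure.n_residues):
        atom_idx = np.nonzero(structure.atom_residue == i)[0]
        heavy = atom_idx[structure.is_heavy[atom_idx]]
        if heavy.size == 0:
            raise StructureError(f"residue {i} has no heavy atoms")
        centroids[i] = structure.coords[heavy].mean(axis=0)
        membership.append(atom_idx)
    return CoarseModel(centroids=centroids, membership=membership, n_nodes=structure.n_residues)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with det(rotation) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise AlignmentError(
            f"selection size mismatch: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise StructureError("need at least 3 points for a rigid fit")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    ssd = (P * P).sum() + (Q * Q).sum() - 2.0 * (S[0] + S[1] + d * S[2])
    rmsd = float(np.sqrt(max(ssd, 0.0) / mobile.shape[0]))
    t = rc - R @ mc
    return R, t, rmsd


def kabsch_rmsd_many(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Batched optimal-fit RMSD between paired coordinate sets.

    X, Y: (m, N, 3). Returns (m,) RMSDs. Used by clustering where many
    pairs are compared at once.
    """
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    H = np.einsum("mni,mnj->mij", X, Y)
    _, S, _ = np.linalg.svd(H)
    det = np.linalg.det(H)
    s3 = np.where(det < 0, -S[:, 2], S[:, 2])
    ssd = (X * X).sum(axis=(1, 2)) + (Y * Y).sum(axis=(1, 2)) - 2.0 * (S[:, 0] + S[:, 1] + s3)
    n = X.shape[1]
    return np.sqrt(np.maximum(ssd, 0.0) / n)


def _selection_coords(structure: Structure, selection: str) -> np.ndarray:
    if selection == "ca":
        return structure.ca_coords()
    if selection == "heavy":
        return structure.coords[structure.is_heavy]
    if selection == "all":
        return structure.coords
    raise ValueError(f"unknown selection {selection!r}")


def superpose(mobile: Structure, reference: Structure, selection: str = "ca") -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference``."""
    m = _selection_coords(mobile, selection)
    r = _selection_coords(reference, selection)
    R, t, rmsd = kabsch(m, r)
    return Superposition(rotation=R, translation=t, rmsd=rmsd, selection=selection)


def _common_ca(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Pair C-alpha coordinates by author numbering within shared chains.

    Both structures are restricted to their common (chain, resseq, icode)
    residue set; no sequence alignment is attempted.
    """
    def ca_map(s: Structure) -> dict[tuple[str, int, str], int]:
        out = {}
        for ai in s.ca_indices():
            key = s.residue_table[int(s.atom_residue[ai])]
            out[(key.chain_id, key.resseq, key.icode)] = ai
        return out

    ma, mb = ca_map(a), ca_map(b)
    common = [k for k in ma if k in mb]
    if len(common) == len(ma) == len(mb):
        return a.coords[[ma[k] for k in common]], b.coords[[mb[k] for k in common]]
    if not common:
        # fall back to pairing by order when numbering schemes are disjoint
        ia, ib = a.ca_indices(), b.ca_indices()
        if ia.size != ib.size:
            raise AlignmentError(
                f"C-alpha counts differ ({ia.size} vs {ib.size}) and no common numbering"
            )
        return a.coords[ia], b.coords[ib]
    return a.coords[[ma[k] for k in common]], b.coords[[mb[k] for k in common]]


def rmsd_ca(a: Structure, b: Structure, chains: Sequence[str] | None = None) -> float:
    """Optimal-fit C-alpha RMSD between two structures (Angstrom)."""
    if chains is not None:
        a = a.subset_chains(chains)
        b = b.subset_chains(chains)
    ca_a, ca_b = _common_ca(a, b)
    _, _, rmsd = kabsch(ca_a, ca_b)
    return rmsd


def radius_of_gyration(structure: Structure, chain_subset: Sequence[str] | None = None) -> float:
    """Mass-unweighted radius of gyration over C-alpha atoms (Angstrom)."""
    ca = structure.ca_coords(chain_subset)
    center = ca.mean(axis=0)
    return float(np.sqrt(((ca - center) ** 2).sum(axis=1).mean()))
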