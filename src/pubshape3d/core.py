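"""Domain types shared across the package.

A :class:`MoleculeRecord` is a lightweight, toolkit-agnostic description of a
chemical structure (atoms, bonds, stereo bookkeeping).  Records are usually
built from an RDKit molecule via :func:`validate_record`, but synthetic
point-cloud records (no bonds, all-carbon) are first-class citizens so that
the geometric machinery can be exercised without any chemistry.

Hydrogens are kept in conformer coordinate arrays but excluded from every
RMSD / shape computation through ``heavy_indices``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AtomSpec",
    "MoleculeRecord",
    "Conformer",
    "ConformerModel",
    "ParseError",
    "validate_record",
]

# Elements of the periodic table (symbols), enough for validation.
_PERIODIC = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U",
}


class ParseError(ValueError):
    """Raised when a raw structure cannot be turned into a valid record."""


@dataclass(frozen=True)
class AtomSpec:
    """One atom: element plus the perception flags the descriptors need."""

    element: str
    is_hydrogen: bool = False
    formal_charge: int = 0
    aromatic: bool = False
    in_ring_nonaromatic: bool = False
    is_bridgehead: bool = False
    is_sp2: bool = False

    def __post_init__(self) -> None:
        if self.element not in _PERIODIC:
            raise ParseError(f"unknown element symbol {self.element!r}")
        if self.is_hydrogen and self.aromatic:
            raise ParseError("a hydrogen atom cannot be aromatic")


@dataclass
class MoleculeRecord:
    """A chemical structure plus the bookkeeping feeding eligibility.

    ``bonds`` holds ``(i, j, order, aromatic)`` tuples with atom indices into
    ``atoms``.  ``rdkit_mol`` (optional) keeps the toolkit molecule around for
    chemistry-aware operations (feature perception, descriptor counting);
    synthetic records leave it ``None``.
    """

    atoms: list[AtomSpec]
    bonds: list[tuple[int, int, int, bool]] = field(default_factory=list)
    covalent_unit_count: int = 1
    undefined_stereo_count: int = 0
    record_id: int = 0
    record_id_kind: str = "compound"
    rdkit_mol: object = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ParseError("empty atom list")
        for i, j, _order, _arom in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ParseError(f"dangling bond index ({i}, {j})")
        if self.covalent_unit_count < 1:
            raise ParseError("covalent_unit_count must be >= 1")
        if self.undefined_stereo_count < 0:
            raise ParseError("undefined_stereo_count must be >= 0")
        if self.record_id < 0:
            raise ParseError("record_id must be non-negative")
        if self.record_id_kind not in ("compound", "substance"):
            raise ParseError(f"bad record_id_kind {self.record_id_kind!r}")

    # -- derived views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_graph(self) -> nx.Graph:
        """Bond graph restricted to non-hydrogen atoms, element-labelled."""
        g = nx.Graph()
        for i in self.heavy_indices:
            g.add_node(i, element=self.atoms[i].element)
        heavy = set(self.heavy_indices)
        for i, j, _o, _a in self.bonds:
            if i in heavy and j in heavy:
                g.add_edge(i, j)
        return g

    @classmethod
    def from_point_cloud(
        cls, n_atoms: int, record_id: int = 0, element: str = "C"
    ) -> "MoleculeRecord":
        """Bond-less all-heavy record used for synthetic shape ensembles."""
        return cls(
            atoms=[AtomSpec(element=element) for _ in range(n_atoms)],
            bonds=[],
            covalent_unit_count=1,
            record_id=record_id,
        )


@dataclass
class Conformer:
    """One 3-D coordinate set (Å) for a molecule; hydrogens included.

    ``energy`` is the force-field energy minus coulombic terms (kcal/mol) and
    may be absent.  ``elements`` optionally carries per-atom symbols so shape
    code can pick van der Waals radii without a parent molecule.
    """

    coords: np.ndarray
    heavy_indices: Optional[Sequence[int]] = None
    energy: Optional[float] = None
    local_id: int = 0
    elements: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n = len(self.coords)
        if self.heavy_indices is None:
            self.heavy_indices = list(range(n))
        else:
            self.heavy_indices = list(self.heavy_indices)
            if any(not (0 <= i < n) for i in self.heavy_indices):
                raise ValueError("heavy_indices out of range")
        if self.local_id < 0:
            raise ValueError("local_id must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[np.asarray(self.heavy_indices, dtype=int)]

    def heavy_elements(self) -> list[str]:
        if self.elements is None:
            return ["C"] * len(self.heavy_indices)
        return [self.elements[i] for i in self.heavy_indices]

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        return Conformer(
            coords=np.asarray(coords, dtype=float),
            heavy_indices=list(self.heavy_indices),
            energy=self.energy,
            local_id=self.local_id,
            elements=None if self.elements is None else list(self.elements),
        )


@dataclass
class ConformerModel:
    """A finalized, sampled conformer ensemble for one molecule."""

    molecule: MoleculeRecord
    conformers: list[Conformer]
    sampling_rmsd: float = 0.4
    diverse_order: Optional[list[int]] = None
    #: per-conformer dicts of unrecognized SDF tags, preserved verbatim
    extra_tags: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("a conformer model needs at least one conformer")
        for c in self.conformers:
            if c.n_atoms != self.molecule.n_atoms:
                raise ValueError(
                    "conformer atom count does not match parent molecule"
                )
        if self.sampling_rmsd < 0.4 - 1e-9:
            raise ValueError("sampling_rmsd must be >= 0.4")
        # multiple-of-0.2 check with float slack
        q = self.sampling_rmsd / 0.2
        if abs(q - round(q)) > 1e-6:
            raise ValueError("sampling_rmsd must be a multiple of 0.2")
        if self.diverse_order is not None:
            if sorted(self.diverse_order) != list(range(len(self.conformers))):
                raise ValueError("diverse_order is not a permutation")

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def ordered_conformers(self) -> list[Conformer]:
        """Conformers in diverse order (identity if not yet ordered)."""
        order = self.diverse_order or list(range(self.n_conformers))
        return [self.conformers[i] for i in order]


def _bridgehead_atoms(mol) -> set[int]:
    """Atoms at the ends of a ring-fusion path of >= 2 shared bonds.

    Two SSSR rings sharing two or more bonds define a bridge; the shared-path
    endpoints (shared atoms with exactly one neighbour inside the shared set)
    are the bridgeheads.
    """
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    out: set[int] = set()
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            shared = rings[a] & rings[b]
            if len(shared) < 3:
                continue
            for idx in shared:
                atom = mol.GetAtomWithIdx(idx)
                inside = sum(
                    1 for nb in atom.GetNeighbors() if nb.GetIdx() in shared
                )
                if inside == 1:
                    out.add(idx)
    return out


def _undefined_stereo_count(mol) -> int:
    from rdkit import Chem

    count = 0
    for si in Chem.FindPotentialStereo(mol):
        if str(si.specified) == "Unspecified":
            count += 1
    return count


def validate_record(raw, record_id: int = 0, record_id_kind: str = "compound"):
    """Build a validated :class:`MoleculeRecord` from an RDKit molecule.

    ``covalent_unit_count`` is the number of connected components of the bond
    graph (isolated atoms count as their own unit).
    """
    from rdkit import Chem

    if raw is None:
        raise ParseError("raw structure failed to parse")
    mol = Chem.Mol(raw)
    Chem.SanitizeMol(mol)
    if mol.GetNumAtoms() == 0:
        raise ParseError("empty atom list")

    bridgeheads = _bridgehead_atoms(mol)
    atoms = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        is_h = atom.GetAtomicNum() == 1
        arom = atom.GetIsAromatic() and not is_h
        atoms.append(
            AtomSpec(
                element=sym,
                is_hydrogen=is_h,
                formal_charge=atom.GetFormalCharge(),
                aromatic=arom,
                in_ring_nonaromatic=atom.IsInRing() and not arom,
                is_bridgehead=atom.GetIdx() in bridgeheads,
                is_sp2=str(atom.GetHybridization()) == "SP2",
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            int(b.GetBondTypeAsDouble()),
            b.GetIsAromatic(),
        )
        for b in mol.GetBonds()
    ]

    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    g.add_edges_from((i, j) for i, j, _o, _a in bonds)
    n_units = nx.number_connected_components(g)

    return MoleculeRecord(
        atoms=atoms,
        bonds=bonds,
        covalent_unit_count=n_units,
        undefined_stereo_count=_undefined_stereo_count(mol),
        record_id=record_id,
        record_id_kind=record_id_kind,
        rdkit_mol=mol,
    )
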