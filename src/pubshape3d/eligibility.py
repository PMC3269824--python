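"""Coverage rules: which molecules receive a conformer model.

Six rules gate conformer-model construction: size (non-hydrogen atom count),
flexibility (rotatable bonds), a supported-element whitelist, a single
covalent unit, MMFF94s-typeable atoms only, and a limit on undefined stereo
centers.  The same pass computes the descriptors feeding the sampling-RMSD
regression: nha, rb and nara, combined into the effective rotor count

    er = rb + nara / 5

where nara counts non-aromatic ring atoms excluding bridgeheads and
sp2-hybridized atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MoleculeRecord

__all__ = [
    "EligibilityConfig",
    "EligibilityReport",
    "count_descriptors",
    "effective_rotor_count",
    "check_eligibility",
]

RULE_TOO_LARGE = "too_large"
RULE_TOO_FLEXIBLE = "too_flexible"
RULE_UNSUPPORTED_ELEMENT = "unsupported_element"
RULE_MULTI_COMPONENT = "multi_component"
RULE_UNSUPPORTED_ATOM_TYPE = "unsupported_atom_type"
RULE_EXCESS_UNDEFINED_STEREO = "excess_undefined_stereo"


@dataclass
class EligibilityConfig:
    """Thresholds for the six coverage rules (defaults are the production
    values: nha <= 50, rb <= 15, fewer than six undefined stereo centers,
    the eleven-element whitelist)."""

    max_heavy_atoms: int = 50
    max_rotatable_bonds: int = 15
    max_undefined_stereo: int = 5  # "fewer than six"
    allowed_elements: frozenset[str] = frozenset(
        {"H", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
    )
    # "strict" excludes amide C-N bonds; "default" is the plain RDKit count.
    rotor_definition: str = "strict"
    check_mmff_types: bool = True


@dataclass
class EligibilityReport:
    eligible: bool
    failed_rules: list[str]
    nha: int
    rb: int
    nara: int
    er: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.nha, self.rb, self.nara) < 0:
            raise ValueError("descriptor counts must be non-negative")
        self.er = effective_rotor_count(self.rb, self.nara)
        assert self.eligible == (not self.failed_rules)


def _rotatable_bond_count(mol, definition: str) -> int:
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    # count on the hydrogen-suppressed graph: explicit hydrogens would make
    # terminal heavy-atom bonds look non-terminal
    mol = Chem.RemoveHs(mol)
    strict = definition == "strict"
    return int(rdMolDescriptors.CalcNumRotatableBonds(mol, strict=strict))


def count_descriptors(
    molecule: MoleculeRecord, config: EligibilityConfig | None = None
) -> tuple[int, int, int]:
    """Return ``(nha, rb, nara)`` for a molecule record.

    nha: non-hydrogen atoms.  rb: rotatable bonds (single, non-ring,
    non-terminal heavy-atom bonds; amide C-N excluded under the strict
    definition).  nara: atoms in non-aromatic rings, excluding bridgehead
    and sp2-hybridized atoms.  Records without an attached toolkit molecule
    get rb from their own bond list (no amide perception possible).
    """
    config = config or EligibilityConfig()
    nha = sum(1 for a in molecule.atoms if not a.is_hydrogen)
    nara = sum(
        1
        for a in molecule.atoms
        if a.in_ring_nonaromatic and not a.is_bridgehead and not a.is_sp2
    )
    if molecule.rdkit_mol is not None:
        rb = _rotatable_bond_count(molecule.rdkit_mol, config.rotor_definition)
    else:
        rb = _rotatable_bonds_from_graph(molecule)
    return nha, rb, nara


def _rotatable_bonds_from_graph(molecule: MoleculeRecord) -> int:
    """Fallback rotor count for toolkit-free records: single, non-ring bonds
    between heavy atoms that each have >= 2 heavy neighbours."""
    import networkx as nx

    heavy = set(molecule.heavy_indices)
    g = nx.Graph()
    g.add_nodes_from(heavy)
    g.add_edges_from(
        (i, j) for i, j, _o, _a in molecule.bonds if i in heavy and j in heavy
    )
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for k in range(len(cycle)):
            e = frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
            ring_edges.add(e)
    count = 0
    for i, j, order, arom in molecule.bonds:
        if i not in heavy or j not in heavy:
            continue
        if order != 1 or arom or frozenset((i, j)) in ring_edges:
            continue
        if g.degree[i] >= 2 and g.degree[j] >= 2:
            count += 1
    return count


def effective_rotor_count(rb: int, nara: int) -> float:
    """er = rb + nara/5, as a real number with no rounding."""
    if rb < 0 or nara < 0:
        raise ValueError("rb and nara must be non-negative")
    return rb + nara / 5.0


def _mmff_typable(mol) -> bool:
    from rdkit.Chem import AllChem

    try:
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    except Exception:
        return False
    return props is not None


def check_eligibility(
    molecule: MoleculeRecord, config: EligibilityConfig | None = None
) -> EligibilityReport:
    """Evaluate all six coverage rules; every violated rule is reported."""
    config = config or EligibilityConfig()
    nha, rb, nara = count_descriptors(molecule, config)
    failed: list[str] = []

    if nha > config.max_heavy_atoms:
        failed.append(RULE_TOO_LARGE)
    if rb > config.max_rotatable_bonds:
        failed.append(RULE_TOO_FLEXIBLE)
    if any(a.element not in config.allowed_elements for a in molecule.atoms):
        failed.append(RULE_UNSUPPORTED_ELEMENT)
    if molecule.covalent_unit_count != 1:
        failed.append(RULE_MULTI_COMPONENT)
    if (
        config.check_mmff_types
        and molecule.rdkit_mol is not None
        and not _mmff_typable(molecule.rdkit_mol)
    ):
        failed.append(RULE_UNSUPPORTED_ATOM_TYPE)
    if molecule.undefined_stereo_count > config.max_undefined_stereo:
        failed.append(RULE_EXCESS_UNDEFINED_STEREO)

    return EligibilityReport(
        eligible=not failed, failed_rules=failed, nha=nha, rb=rb, nara=nara
    )
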