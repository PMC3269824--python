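"""Pharmacophore feature perception, merging, and the color Tanimoto.

Six feature types are perceived — anion, cation, hydrogen-bond acceptor,
hydrogen-bond donor, hydrophobe, ring — each becoming a fictitious "color"
atom placed at the steric center (unweighted mean) of its member heavy
atoms.  Same-type features closer than the merge radius (1.0 Å) are merged
iteratively.  The color Tanimoto sums same-type Gaussian overlaps:

    CT = sum_f V_AB^f / (sum_f V_AA^f + sum_f V_BB^f - sum_f V_AB^f)

The perception rules are an explicit, documented substructure set evaluated
at an assumed pH-7 protonation model; they are inspectable approximations,
not a claim of parity with any proprietary feature dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformer, MoleculeRecord
from . import gaussians

__all__ = [
    "FEATURE_TYPES",
    "Feature",
    "FeatureSet",
    "FeatureRuleSet",
    "perceive_features",
    "merge_features",
    "color_tanimoto",
]

FEATURE_TYPES = ("anion", "cation", "acceptor", "donor", "hydrophobe", "ring")


@dataclass
class Feature:
    """One fictitious color atom: type, member heavy atoms, position (Å)."""

    ftype: str
    member_atoms: tuple[int, ...]
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not self.member_atoms:
            raise ValueError("member_atoms must be nonempty")
        self.member_atoms = tuple(sorted(self.member_atoms))
        self.position = np.asarray(self.position, float).reshape(3)


@dataclass
class FeatureSet:
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def counts(self) -> dict:
        out = {t: 0 for t in FEATURE_TYPES}
        for f in self.features:
            out[f.ftype] += 1
        return out

    def positions_by_type(self) -> dict:
        """Per-type (k, 3) position arrays (types with no features omitted)."""
        out: dict[str, list] = {}
        for f in self.features:
            out.setdefault(f.ftype, []).append(f.position)
        return {t: np.asarray(v, float) for t, v in out.items()}

    def has_features(self) -> bool:
        return bool(self.features)


# anion / cation SMARTS evaluated at an assumed pH-7 protonation model:
# acids are treated as deprotonated, aliphatic amines/amidines/guanidines
# as protonated, whatever the drawn protonation state.
_ANION_SMARTS = (
    "[CX3](=O)[OX2H1,OX1-]",            # carboxylic acid / carboxylate
    "[SX4](=O)(=O)[OX2H1,OX1-]",        # sulfonic / sulfate O
    "[PX4](=O)[OX2H1,OX1-]",            # phosphonate / phosphate O
)
_CATION_SMARTS = (
    "[NX4+]",                                       # quaternary / protonated N
    "[NX3;H2,H1,H0;+0;!$(N-[!#6;!#1]);!$(N-[CX3]=[O,N,S]);!$(N-a);!$(N=*)]",
    "NC(=[NX2])N",                                  # guanidinium group
)


@dataclass
class FeatureRuleSet:
    """The documented perception rules; patterns are configurable."""

    anion_smarts: tuple = _ANION_SMARTS
    cation_smarts: tuple = _CATION_SMARTS
    hydrophobe_min_size: int = 2
    merge_radius: float = 1.0


DEFAULT_RULES = FeatureRuleSet()


def _steric_center(conformer: Conformer, atoms) -> np.ndarray:
    return conformer.coords[np.asarray(sorted(atoms), int)].mean(axis=0)


def _smarts_features(mol, conformer, smarts_list, ftype, taken):
    from rdkit import Chem

    out = []
    for sm in smarts_list:
        patt = Chem.MolFromSmarts(sm)
        for match in mol.GetSubstructMatches(patt):
            heavy = tuple(
                sorted(
                    i for i in match if mol.GetAtomWithIdx(i).GetAtomicNum() > 1
                )
            )
            if not heavy or heavy in taken:
                continue
            taken.add(heavy)
            out.append(
                Feature(ftype, heavy, _steric_center(conformer, heavy))
            )
    return out


def _is_acceptor(atom) -> bool:
    z = atom.GetAtomicNum()
    if z not in (7, 8) or atom.GetFormalCharge() > 0:
        return False
    if z == 8:
        return True  # all neutral/anionic oxygens accept
    # nitrogen: needs an available lone pair
    if atom.GetTotalNumHs(includeNeighbors=True) > 0 and atom.GetIsAromatic():
        return False  # pyrrole-type N
    for nb in atom.GetNeighbors():
        if nb.GetAtomicNum() == 6:
            for b in nb.GetBonds():
                other = b.GetOtherAtom(nb)
                if (
                    other.GetIdx() != atom.GetIdx()
                    and b.GetBondTypeAsDouble() >= 2
                    and other.GetAtomicNum() == 8
                ):
                    return False  # amide-type N
    return atom.GetTotalValence() <= 3


def _is_donor(atom) -> bool:
    return (
        atom.GetAtomicNum() in (7, 8)
        and atom.GetTotalNumHs(includeNeighbors=True) > 0
    )


def _hydrophobe_groups(mol, min_size):
    import networkx as nx

    halogens = {9, 17, 35, 53}
    candidates = set()
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z in halogens:
            candidates.add(atom.GetIdx())
        elif z == 6 and not atom.GetIsAromatic():
            polar = any(
                nb.GetAtomicNum() in (7, 8, 15, 16) for nb in atom.GetNeighbors()
            )
            if not polar:
                candidates.add(atom.GetIdx())
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in candidates and j in candidates:
            g.add_edge(i, j)
    return [
        tuple(sorted(comp))
        for comp in nx.connected_components(g)
        if len(comp) >= min_size
    ]


def perceive_features(
    molecule: MoleculeRecord,
    conformer: Conformer,
    rules: FeatureRuleSet | None = None,
) -> FeatureSet:
    """Apply the documented rules and place color atoms at steric centers.

    Records without a toolkit molecule (synthetic point clouds) perceive no
    features.  The result is finalized through :func:`merge_features`.
    """
    rules = rules or DEFAULT_RULES
    mol = molecule.rdkit_mol
    if mol is None:
        return FeatureSet([])
    if conformer.n_atoms != molecule.n_atoms:
        raise ValueError("conformer does not belong to molecule")

    feats: list[Feature] = []
    taken: set = set()
    feats += _smarts_features(mol, conformer, rules.anion_smarts, "anion", taken)
    feats += _smarts_features(mol, conformer, rules.cation_smarts, "cation", taken)
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if _is_acceptor(atom):
            feats.append(
                Feature("acceptor", (idx,), _steric_center(conformer, (idx,)))
            )
        if _is_donor(atom):
            feats.append(
                Feature("donor", (idx,), _steric_center(conformer, (idx,)))
            )
    for group in _hydrophobe_groups(mol, rules.hydrophobe_min_size):
        feats.append(Feature("hydrophobe", group, _steric_center(conformer, group)))
    for ring in mol.GetRingInfo().AtomRings():
        ring = tuple(sorted(ring))
        feats.append(Feature("ring", ring, _steric_center(conformer, ring)))

    return merge_features(FeatureSet(feats), rules.merge_radius, conformer)


def merge_features(
    fs: FeatureSet, radius: float = 1.0, conformer: Conformer | None = None
) -> FeatureSet:
    """Iteratively merge closest same-type features within ``radius`` Å.

    The merged feature's member set is the union and its position the steric
    center of the union (recomputed from the conformer when available, else
    the member-count-weighted mean of the two positions).  Equidistant pairs
    break ties by lowest (type, smallest member index).  Idempotent.
    """
    feats = list(fs.features)
    while True:
        best = None
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                if feats[i].ftype != feats[j].ftype:
                    continue
                d = float(np.linalg.norm(feats[i].position - feats[j].position))
                if d > radius:
                    continue
                key = (
                    d,
                    FEATURE_TYPES.index(feats[i].ftype),
                    min(feats[i].member_atoms + feats[j].member_atoms),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        fi, fj = feats[i], feats[j]
        members = tuple(sorted(set(fi.member_atoms) | set(fj.member_atoms)))
        if conformer is not None:
            pos = _steric_center(conformer, members)
        else:
            ni, nj = len(fi.member_atoms), len(fj.member_atoms)
            pos = (fi.position * ni + fj.position * nj) / (ni + nj)
        merged = Feature(fi.ftype, members, pos)
        feats = [f for k, f in enumerate(feats) if k not in (i, j)] + [merged]
    return FeatureSet(feats)


def color_tanimoto(
    a: FeatureSet,
    b: FeatureSet,
    transform=None,
    color_radius: float = 1.0,
    gaussian_height: float = 2.7,
) -> float:
    """CT between two feature sets; ``transform`` (if given) poses b.

    Overlaps are computed only between same-type color atoms, modeled as
    fixed-radius Gaussians.  Empty-vs-empty returns 0 by convention (the
    featureless case is handled by a separate shape-only threshold in
    neighboring).
    """
    alpha = float(
        gaussians.alphas_for_radii(
            np.array([color_radius]), gaussian_height
        )[0]
    )
    fa = a.positions_by_type()
    fb = b.positions_by_type()
    if transform is not None:
        fb = {t: transform.apply(p) for t, p in fb.items()}

    def cross(x, y):
        total = 0.0
        for t, px in x.items():
            py = y.get(t)
            if py is None:
                continue
            ax = np.full(len(px), alpha)
            ay = np.full(len(py), alpha)
            total += gaussians.cross_overlap(px, ax, py, ay, gaussian_height)
        return total

    v_ab = cross(fa, fb)
    denom = cross(fa, fa) + cross(fb, fb) - v_ab
    if denom <= 0:
        return 0.0
    return min(1.0, max(0.0, v_ab / denom))
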