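"""Deterministic fixtures: toy molecules and synthetic conformer ensembles.

Three families of inputs are generated, all reproducible under a seed:

* a toy SMILES panel (dopamine and other small drug-like molecules) embedded
  in 3-D with RDKit's distance-geometry embedder and MMFF94s energies;
* synthetic point-cloud ensembles — bond-less all-carbon "conformers" with
  controlled jitter and random rigid perturbations, including duplicate-
  group ensembles whose ground-truth group structure is known by
  construction (each group's copies stay within the jitter radius of the
  group base, groups are mutually far apart);
* degenerate cases (single atom, linear chain, symmetric ring).

Point clouds emulate shape-space structure only: they carry no bonds, no
features and no chemistry, which is exactly what the geometric machinery
(RMSD sampling, shape overlap, ordering, fingerprints) needs for oracle
tests with known answers.
"""

from __future__ import annotations

import numpy as np

from .core import Conformer, ConformerModel, MoleculeRecord, validate_record

__all__ = [
    "TOY_SMILES",
    "molecule_from_smiles",
    "embedded_model",
    "point_cloud_ensemble",
    "duplicate_group_ensemble",
    "near_duplicate_ensemble",
    "degenerate_conformer",
    "random_rigid_motion",
]

#: name -> (SMILES, PubChem CID) for the toy panel.
TOY_SMILES = {
    "dopamine": ("C1=CC(=C(C=C1CCN)O)O", 681),
    "aspirin": ("CC(=O)OC1=CC=CC=C1C(=O)O", 2244),
    "caffeine": ("CN1C=NC2=C1C(=O)N(C(=O)N2C)C", 2519),
    "benzene": ("c1ccccc1", 241),
    "ethanol": ("CCO", 702),
    "n_butane": ("CCCC", 7843),
    "cyclohexane": ("C1CCCCC1", 8078),
    "methane": ("C", 297),
    "acetate": ("CC(=O)[O-]", 175),
    "ethane": ("CC", 6324),
}


def molecule_from_smiles(smiles: str, record_id: int = 0) -> MoleculeRecord:
    """Parse, add hydrogens, and validate a molecule from SMILES."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    return validate_record(mol, record_id=record_id)


def embedded_model(
    name: str,
    n_conformers: int = 5,
    seed: int = 0,
    sample: bool = True,
):
    """Embed a toy-panel molecule and (optionally) sample its ensemble.

    Uses the distance-geometry embedder with a derived deterministic seed
    and MMFF94s energies (coulombic terms removed is not available in the
    host force field; full MMFF94s energies are used and documented).
    Returns a :class:`ConformerModel`.
    """
    from rdkit.Chem import AllChem

    from .sampling import build_conformer_model

    smiles, cid = TOY_SMILES[name]
    record = molecule_from_smiles(smiles, record_id=cid)
    mol = record.rdkit_mol
    params = AllChem.ETKDGv3()
    params.randomSeed = (seed * 7919 + 13) % (2 ** 31 - 1)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if not ids:
        raise RuntimeError(f"embedding failed for {name}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(mol, mmffVariant="MMFF94s", maxIters=200)
    except Exception:
        pass
    energies = []
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    heavy = record.heavy_indices
    raw = []
    for k, cid_ in enumerate(ids):
        coords = np.array(mol.GetConformer(cid_).GetPositions(), float)
        energy = None
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid_)
            if ff is not None:
                energy = float(ff.CalcEnergy())
        raw.append(
            Conformer(
                coords=coords,
                heavy_indices=heavy,
                energy=energy,
                local_id=k,
                elements=record.elements,
            )
        )
    if sample:
        return build_conformer_model(record, raw)
    return ConformerModel(molecule=record, conformers=raw, sampling_rmsd=0.4)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a modest random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2 ** 31 - 1))).as_matrix()
    trans = rng.uniform(-5.0, 5.0, size=3)
    return rot, trans


def _base_cloud(rng: np.random.Generator, n_atoms: int, extent: float) -> np.ndarray:
    """An anisotropic random point cloud (distinct principal extents so the
    canonical frame is well defined)."""
    scales = np.array([extent, 0.6 * extent, 0.35 * extent])
    return rng.normal(size=(n_atoms, 3)) * scales


def point_cloud_ensemble(
    n_atoms: int = 8,
    n_conformers: int = 10,
    jitter: float = 0.1,
    seed: int = 0,
    rigid_perturb: bool = True,
    extent: float = 2.0,
    record_id: int = 0,
) -> tuple[MoleculeRecord, list[Conformer]]:
    """Jittered copies of one base cloud, optionally rigidly scattered.

    With overlay-minimized RMSD, all conformers lie within a few times
    ``jitter`` of each other regardless of the rigid perturbations.
    """
    rng = np.random.default_rng(seed)
    base = _base_cloud(rng, n_atoms, extent)
    record = MoleculeRecord.from_point_cloud(n_atoms, record_id=record_id)
    conformers = []
    for k in range(n_conformers):
        coords = base + rng.normal(scale=jitter, size=base.shape)
        if rigid_perturb:
            rot, trans = random_rigid_motion(rng)
            coords = coords @ rot.T + trans
        conformers.append(
            Conformer(coords=coords, energy=float(k), local_id=k)
        )
    return record, conformers


def duplicate_group_ensemble(
    n_groups: int = 5,
    per_group: int = 10,
    jitter: float = 0.05,
    seed: int = 0,
    n_atoms: int = 8,
    extent: float = 2.0,
) -> tuple[MoleculeRecord, list[Conformer], list[int]]:
    """Ensemble of ``n_groups`` mutually distinct shapes, ``per_group``
    jittered rigidly-perturbed copies each.

    Returns ``(record, conformers, group_labels)``.  Group bases are drawn
    independently and redrawn until mutually > 8x jitter apart in overlay
    RMSD, so sampling at any RMSD between ~4x jitter and the base separation
    must recover exactly one representative per group.
    """
    from .sampling import heavy_atom_rmsd

    rng = np.random.default_rng(seed)
    record = MoleculeRecord.from_point_cloud(n_atoms)
    bases: list[np.ndarray] = []
    while len(bases) < n_groups:
        cand = _base_cloud(rng, n_atoms, extent)
        cc = Conformer(coords=cand)
        ok = all(
            heavy_atom_rmsd(cc, Conformer(coords=b), automorph=False) > 8 * jitter
            for b in bases
        )
        if ok:
            bases.append(cand)
    conformers = []
    labels = []
    lid = 0
    for g, base in enumerate(bases):
        for _ in range(per_group):
            coords = base + rng.normal(scale=jitter, size=base.shape)
            rot, trans = random_rigid_motion(rng)
            conformers.append(
                Conformer(coords=coords @ rot.T + trans, energy=float(lid), local_id=lid)
            )
            labels.append(g)
            lid += 1
    return record, conformers, labels


def near_duplicate_ensemble(
    n_conformers: int = 5000,
    jitter: float = 0.02,
    seed: int = 0,
    n_atoms: int = 8,
) -> tuple[MoleculeRecord, list[Conformer]]:
    """Thousands of near-duplicates of one shape (tests the 500 cap path)."""
    record, conformers = point_cloud_ensemble(
        n_atoms=n_atoms,
        n_conformers=n_conformers,
        jitter=jitter,
        seed=seed,
        rigid_perturb=True,
    )
    return record, conformers


def degenerate_conformer(kind: str, n_atoms: int = 6) -> Conformer:
    """Degenerate geometries: ``single_atom``, ``linear_chain``,
    ``symmetric_ring`` (regular polygon in the xy plane)."""
    if kind == "single_atom":
        return Conformer(coords=np.array([[5.0, 5.0, 5.0]]))
    if kind == "linear_chain":
        xs = np.arange(n_atoms, dtype=float) * 1.5
        coords = np.stack([xs, np.zeros(n_atoms), np.zeros(n_atoms)], axis=1)
        return Conformer(coords=coords)
    if kind == "symmetric_ring":
        theta = 2 * np.pi * np.arange(n_atoms) / n_atoms
        coords = np.stack(
            [1.4 * np.cos(theta), 1.4 * np.sin(theta), np.zeros(n_atoms)], axis=1
        )
        return Conformer(coords=coords)
    raise ValueError(f"unknown degenerate kind {kind!r}")
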