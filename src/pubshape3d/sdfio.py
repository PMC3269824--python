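"""SDF property-tag dialect, neighbor-pair files, report tables.

Conformer models are serialized as multi-record V2000 SDF files, one record
per conformer, with conformers of one compound grouped by a shared
structure id.  The tag dialect:

========================================  =======================================
PUBCHEM_CONFORMER_ID                      16-digit hex GID
PUBCHEM_CONFORMER_RMSD                    sampling RMSD, Å (%.2f)
PUBCHEM_EFFECTIVE_ROTOR_COUNT             er (%.2f)
PUBCHEM_MMFF94_ENERGY                     kcal/mol (%.4f)
PUBCHEM_CONFORMER_DIVERSEORDERING         whitespace-separated local ids
PUBCHEM_SHAPE_VOLUME                      analytic volume, Å^3 (%.3f)
PUBCHEM_SHAPE_SELFOVERLAP                 V_AA, Å^3 (%.3f)
PUBCHEM_FEATURE_SELFOVERLAP               color self overlap, Å^3 (%.3f)
PUBCHEM_SHAPE_MULTIPOLES                  14 lines: volume, Qx, Qy, Qz, 10 octopoles
PUBCHEM_PHARMACOPHORE_FEATURES            count line, then "n idx1 ... idxn type"
PUBCHEM_SHAPE_FINGERPRINT                 one "refid transform-hex" per line
========================================  =======================================

Unknown tags are preserved verbatim through a read/write round trip.
Neighbor-pair flat files are tab-separated, one pair per line: hex GIDs,
ST/CT at %.4f, then the 9 rotation elements and 3 translation components at
%.6f (rotation applied before translation).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np

from .core import Conformer, ConformerModel, MoleculeRecord, validate_record
from .features import FEATURE_TYPES, Feature, FeatureSet
from .identifiers import decode_gid, encode_gid, gid_from_hex, gid_to_hex
from .neighboring import NeighborRecord
from .shape import RigidTransform

__all__ = [
    "TAG_CONFORMER_ID",
    "read_models",
    "write_models",
    "features_to_tag",
    "features_from_tag",
    "write_neighbor_records",
    "read_neighbor_records",
    "write_eligibility_report",
]

TAG_CONFORMER_ID = "PUBCHEM_CONFORMER_ID"
TAG_RMSD = "PUBCHEM_CONFORMER_RMSD"
TAG_ER = "PUBCHEM_EFFECTIVE_ROTOR_COUNT"
TAG_ENERGY = "PUBCHEM_MMFF94_ENERGY"
TAG_DIVERSE = "PUBCHEM_CONFORMER_DIVERSEORDERING"
TAG_VOLUME = "PUBCHEM_SHAPE_VOLUME"
TAG_SELFOVERLAP = "PUBCHEM_SHAPE_SELFOVERLAP"
TAG_FEATURE_SELFOVERLAP = "PUBCHEM_FEATURE_SELFOVERLAP"
TAG_MULTIPOLES = "PUBCHEM_SHAPE_MULTIPOLES"
TAG_FEATURES = "PUBCHEM_PHARMACOPHORE_FEATURES"
TAG_FINGERPRINT = "PUBCHEM_SHAPE_FINGERPRINT"

_TYPED_TAGS = {TAG_CONFORMER_ID, TAG_RMSD, TAG_ENERGY, TAG_DIVERSE}


def features_to_tag(fs: FeatureSet) -> str:
    """Serialize a feature set: first line the count, then one line per
    feature: member count, member atom indices, type name."""
    lines = [str(len(fs))]
    for f in fs.features:
        lines.append(
            f"{len(f.member_atoms)} "
            + " ".join(str(i) for i in f.member_atoms)
            + f" {f.ftype}"
        )
    return "\n".join(lines)


def features_from_tag(text: str, conformer: Conformer) -> FeatureSet:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    count = int(lines[0])
    feats = []
    for ln in lines[1:count + 1]:
        parts = ln.split()
        n = int(parts[0])
        members = tuple(int(x) for x in parts[1:1 + n])
        ftype = parts[1 + n]
        pos = conformer.coords[np.asarray(members, int)].mean(axis=0)
        feats.append(Feature(ftype, members, pos))
    return FeatureSet(feats)


# ---------------------------------------------------------------------------
# SDF writing


def _mol_for_writing(record: MoleculeRecord):
    from rdkit import Chem

    if record.rdkit_mol is not None:
        mol = Chem.Mol(record.rdkit_mol)
        mol.RemoveAllConformers()
        return mol
    rw = Chem.RWMol()
    for spec in record.atoms:
        atom = Chem.Atom(spec.element)
        atom.SetFormalCharge(spec.formal_charge)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order, _arom in record.bonds:
        rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


def write_models(
    models: Sequence[ConformerModel],
    path: str,
    annotate: bool = False,
    fingerprints: Optional[dict] = None,
) -> None:
    """Write conformer models as multi-record SDF.

    ``annotate`` adds the computed shape/feature tags (volumes, multipoles,
    pharmacophore features, effective rotor count).  ``fingerprints`` maps
    ``(record_id, local_id)`` to a :class:`ShapeFingerprint` to serialize.
    """
    from rdkit import Chem

    from .eligibility import count_descriptors, effective_rotor_count

    writer = Chem.SDWriter(path)
    writer.SetKekulize(False)
    try:
        for model in models:
            record = model.molecule
            base = _mol_for_writing(record)
            diverse = (
                " ".join(
                    str(model.conformers[i].local_id) for i in model.diverse_order
                )
                if model.diverse_order is not None
                else None
            )
            er_text = None
            if record.rdkit_mol is not None:
                nha, rb, nara = count_descriptors(record)
                er_text = f"{effective_rotor_count(rb, nara):.2f}"
            for ci, conf in enumerate(model.conformers):
                mol = Chem.Mol(base)
                rdconf = Chem.Conformer(mol.GetNumAtoms())
                for k in range(mol.GetNumAtoms()):
                    rdconf.SetAtomPosition(
                        k, [float(v) for v in conf.coords[k]]
                    )
                mol.RemoveAllConformers()
                mol.AddConformer(rdconf, assignId=True)
                mol.SetProp("_Name", str(record.record_id))
                version = 0 if record.record_id_kind == "compound" else 1
                gid = encode_gid(record.record_id, version, conf.local_id)
                mol.SetProp(TAG_CONFORMER_ID, gid_to_hex(gid))
                mol.SetProp(TAG_RMSD, f"{model.sampling_rmsd:.2f}")
                if conf.energy is not None:
                    mol.SetProp(TAG_ENERGY, f"{conf.energy:.4f}")
                if diverse is not None:
                    mol.SetProp(TAG_DIVERSE, diverse)
                if er_text is not None:
                    mol.SetProp(TAG_ER, er_text)
                if annotate:
                    _annotate(mol, model, conf)
                if fingerprints:
                    fp = fingerprints.get((record.record_id, conf.local_id))
                    if fp is not None:
                        mol.SetProp(
                            TAG_FINGERPRINT,
                            "\n".join(
                                f"{rid} {packed:016X}"
                                for rid, packed in sorted(fp.bits.items())
                            ),
                        )
                if model.extra_tags is not None:
                    for key, value in model.extra_tags[ci].items():
                        if not mol.HasProp(key):
                            mol.SetProp(key, value)
                writer.write(mol)
    finally:
        writer.close()


def _annotate(mol, model: ConformerModel, conf: Conformer) -> None:
    from .features import color_tanimoto, perceive_features  # noqa: F401
    from .features import FeatureSet as _FS
    from . import gaussians
    from .shape import DEFAULT_PARAMS, self_overlap_volume, self_volume, steric_moments

    try:
        vol = self_volume(conf)
        mol.SetProp(TAG_VOLUME, f"{vol:.3f}")
        mol.SetProp(TAG_SELFOVERLAP, f"{self_overlap_volume(conf):.3f}")
        m = steric_moments(conf)
        values = [m.volume, m.qx, m.qy, m.qz] + [
            m.octopoles[k]
            for k in ("xxx", "yyy", "zzz", "xxy", "xxz",
                      "yyx", "yyz", "zzx", "zzy", "xyz")
        ]
        mol.SetProp(TAG_MULTIPOLES, "\n".join(f"{v:.3f}" for v in values))
    except ValueError:
        pass
    if model.molecule.rdkit_mol is not None:
        from .features import perceive_features

        fs = perceive_features(model.molecule, conf)
        mol.SetProp(TAG_FEATURES, features_to_tag(fs))
        by_type = fs.positions_by_type()
        alpha = float(
            gaussians.alphas_for_radii(
                np.array([DEFAULT_PARAMS.color_radius]),
                DEFAULT_PARAMS.gaussian_height,
            )[0]
        )
        total = 0.0
        for pos in by_type.values():
            aa = np.full(len(pos), alpha)
            total += gaussians.cross_overlap(
                pos, aa, pos, aa, DEFAULT_PARAMS.gaussian_height
            )
        mol.SetProp(TAG_FEATURE_SELFOVERLAP, f"{total:.3f}")


# ---------------------------------------------------------------------------
# SDF reading


class SdfParseError(ValueError):
    def __init__(self, path: str, index: int, message: str):
        super().__init__(f"{path}: record {index}: {message}")


def _record_from_mol(mol, record_id: int, kind: str) -> MoleculeRecord:
    from rdkit import Chem

    try:
        rec = validate_record(mol, record_id=record_id, record_id_kind=kind)
        return rec
    except Exception:
        # chemistry perception failed (e.g. bond-less point clouds): build a
        # minimal record from symbols and the bond block
        from .core import AtomSpec

        atoms = [
            AtomSpec(
                element=a.GetSymbol(),
                is_hydrogen=a.GetAtomicNum() == 1,
                formal_charge=a.GetFormalCharge(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             int(b.GetBondTypeAsDouble()), b.GetIsAromatic())
            for b in mol.GetBonds()
        ]
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(atoms)))
        g.add_edges_from((i, j) for i, j, _o, _a in bonds)
        return MoleculeRecord(
            atoms=atoms,
            bonds=bonds,
            covalent_unit_count=nx.number_connected_components(g),
            record_id=record_id,
            record_id_kind=kind,
        )


def read_models(path: str) -> list[ConformerModel]:
    """Read multi-record SDF into conformer models.

    Conformers sharing a structure id (from the GID tag, else the record
    title) are grouped into one model.  Records missing the GID tag get
    sequential local ids from 0.  All-zero z coordinates are accepted as a
    provided pose (a warning is emitted).
    """
    import warnings

    from rdkit import Chem

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    groups: list[dict] = []
    current = None
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SdfParseError(path, idx, "malformed record")
        # raw strings: numeric auto-coercion would mangle hex GIDs and
        # printed precision of preserved tags
        props = {name: mol.GetProp(name) for name in mol.GetPropNames()}
        gid = None
        if TAG_CONFORMER_ID in props:
            gid = decode_gid(gid_from_hex(str(props[TAG_CONFORMER_ID])))
            key = ("gid", gid.structure_id, gid.kind)
        else:
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            key = ("title", title, mol.GetNumAtoms())
        if current is None or current["key"] != key:
            current = {"key": key, "mols": [], "gids": []}
            groups.append(current)
        current["mols"].append((idx, mol, props))
        current["gids"].append(gid)

    models = []
    for group in groups:
        idx0, mol0, _ = group["mols"][0]
        gid0 = group["gids"][0]
        if gid0 is not None:
            record_id, kind = gid0.structure_id, gid0.kind
        else:
            title = mol0.GetProp("_Name") if mol0.HasProp("_Name") else ""
            record_id = int(title) if title.isdigit() else 0
            kind = "compound"
        record = _record_from_mol(mol0, record_id, kind)

        conformers = []
        extra_tags = []
        rmsd = 0.4
        diverse_lids = None
        for k, ((idx, mol, props), gid) in enumerate(
            zip(group["mols"], group["gids"])
        ):
            if mol.GetNumConformers() == 0:
                raise SdfParseError(path, idx, "no coordinates")
            coords = np.array(mol.GetConformer().GetPositions(), float)
            if coords.shape[0] != record.n_atoms:
                raise SdfParseError(path, idx, "atom count mismatch in group")
            if np.allclose(coords[:, 2], 0.0) and len(coords) > 3:
                warnings.warn(
                    f"{path}: record {idx} has all-zero z coordinates; "
                    "treated as the provided pose"
                )
            energy = None
            if TAG_ENERGY in props:
                energy = float(props[TAG_ENERGY])
            if TAG_RMSD in props:
                rmsd = float(props[TAG_RMSD])
            if TAG_DIVERSE in props:
                diverse_lids = [int(x) for x in str(props[TAG_DIVERSE]).split()]
            lid = gid.local_id if gid is not None else k
            conformers.append(
                Conformer(
                    coords=coords,
                    heavy_indices=record.heavy_indices,
                    energy=energy,
                    local_id=lid,
                    elements=record.elements,
                )
            )
            extra_tags.append(
                {
                    key: str(value)
                    for key, value in props.items()
                    if key not in _TYPED_TAGS
                }
            )
        diverse_order = None
        if diverse_lids is not None:
            lid_to_index = {c.local_id: i for i, c in enumerate(conformers)}
            if sorted(diverse_lids) == sorted(lid_to_index):
                diverse_order = [lid_to_index[l] for l in diverse_lids]
        models.append(
            ConformerModel(
                molecule=record,
                conformers=conformers,
                sampling_rmsd=max(0.4, rmsd),
                diverse_order=diverse_order,
                extra_tags=extra_tags,
            )
        )
    return models


# ---------------------------------------------------------------------------
# neighbor-pair flat files


def write_neighbor_records(records: Sequence[NeighborRecord], path: str) -> None:
    """One pair per line: gid_a gid_b ST CT r11..r33 t1 t2 t3 (tab-sep)."""
    with open(path, "w") as fh:
        for r in records:
            fields = [gid_to_hex(r.gid_a), gid_to_hex(r.gid_b),
                      f"{r.st:.4f}", f"{r.ct:.4f}"]
            fields += [f"{v:.6f}" for v in r.rotation.flat]
            fields += [f"{v:.6f}" for v in r.translation]
            fh.write("\t".join(fields) + "\n")


def read_neighbor_records(path: str) -> list[NeighborRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rot = np.array([float(x) for x in parts[4:13]]).reshape(3, 3)
            # re-orthonormalize against %.6f truncation
            u, _s, vt = np.linalg.svd(rot)
            rot = u @ vt
            out.append(
                NeighborRecord(
                    gid_a=gid_from_hex(parts[0]),
                    gid_b=gid_from_hex(parts[1]),
                    st=float(parts[2]),
                    ct=float(parts[3]),
                    rotation=rot,
                    translation=np.array([float(x) for x in parts[13:16]]),
                )
            )
    return out


def write_eligibility_report(rows: Sequence[dict], path: str) -> None:
    """TSV report: record_id, eligible, failed_rules, nha, rb, nara, er."""
    import pandas as pd

    frame = pd.DataFrame(
        rows,
        columns=["record_id", "eligible", "failed_rules", "nha", "rb", "nara", "er"],
    )
    frame.to_csv(path, sep="\t", index=False)
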