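"""Conformer-ensemble sampling at a size/flexibility-dependent RMSD.

The sampling RMSD is predicted from molecular size and flexibility,

    RMSD_pred = 0.219 + 0.0099 * nha + 0.040 * er,

rounded to the nearest 0.2 Å increment with a 0.4 Å floor.  The raw ensemble
is reduced so that retained conformers are mutually at least the sampling
RMSD apart (heavy-atom, superposition-minimized, optionally automorphism-
aware) while every discarded conformer stays within that RMSD of a retained
one.  If more than 500 conformers survive, the RMSD is incremented by 0.2 Å
and the ensemble re-clustered until the cap is met.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import Conformer, ConformerModel, MoleculeRecord
from .eligibility import EligibilityConfig, count_descriptors, effective_rotor_count

__all__ = [
    "SamplingConfig",
    "GeneratorConfig",
    "predict_sampling_rmsd",
    "heavy_atom_rmsd",
    "sample_ensemble",
    "build_conformer_model",
]


@dataclass
class SamplingConfig:
    rmsd_increment: float = 0.2
    rmsd_floor: float = 0.4
    max_conformers: int = 500
    use_automorphism: bool = True
    use_overlay: bool = True
    automorphism_node_budget: int = 10000

    def __post_init__(self) -> None:
        if self.rmsd_increment <= 0:
            raise ValueError("rmsd_increment must be positive")
        if self.rmsd_floor < self.rmsd_increment:
            raise ValueError("rmsd_floor must be >= rmsd_increment")
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")


@dataclass
class GeneratorConfig:
    """Contract for a pluggable conformer-generation backend (not run here):
    force-field energy window, per-stereoisomer cap, stereo enumeration."""

    energy_window: float = 25.0
    max_conformers_per_stereoisomer: int = 100000
    enumerate_undefined_stereo: bool = True

    def __post_init__(self) -> None:
        if self.energy_window <= 0:
            raise ValueError("energy_window must be positive")
        if self.max_conformers_per_stereoisomer < 1:
            raise ValueError("conformer cap must be >= 1")


def predict_sampling_rmsd(
    nha: int, er: float, config: SamplingConfig | None = None
) -> float:
    """Sampling RMSD (Å) for a molecule of given size and flexibility.

    The regression value is rounded to the nearest increment (exact midpoints
    round up) and floored at the minimum sampling RMSD.
    """
    config = config or SamplingConfig()
    if nha < 1:
        raise ValueError("nha must be >= 1")
    if er < 0:
        raise ValueError("er must be >= 0")
    pred = 0.219 + 0.0099 * nha + 0.040 * er
    inc = config.rmsd_increment
    rounded = np.floor(pred / inc + 0.5) * inc  # ties round up
    return float(max(config.rmsd_floor, round(rounded, 10)))


# ---------------------------------------------------------------------------
# RMSD


def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum RMSD between matched coordinate sets over rigid motions."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = yc.T @ xc
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= sign
    e = np.sum(xc ** 2) + np.sum(yc ** 2) - 2.0 * np.sum(s)
    return float(np.sqrt(max(0.0, e) / len(x)))


def _plain_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=-1))))


def _heavy_automorphisms(
    molecule: MoleculeRecord, node_budget: int
) -> list[np.ndarray]:
    """Element-preserving automorphisms of the heavy-atom bond graph.

    Returns permutations over heavy-atom positions (not atom indices); falls
    back to the identity when the graph has no bonds or the search exceeds
    the node budget ("prohibitively expensive" cases).
    """
    import networkx.algorithms.isomorphism as iso

    heavy = molecule.heavy_indices
    pos_of = {a: k for k, a in enumerate(heavy)}
    g = molecule.heavy_graph()
    identity = np.arange(len(heavy))
    if g.number_of_edges() == 0:
        return [identity]
    matcher = iso.GraphMatcher(
        g, g, node_match=iso.categorical_node_match("element", None)
    )
    perms: list[np.ndarray] = []
    for count, mapping in enumerate(matcher.isomorphisms_iter()):
        if count >= node_budget:
            return [identity]
        perm = np.empty(len(heavy), dtype=int)
        for src, dst in mapping.items():
            perm[pos_of[src]] = pos_of[dst]
        perms.append(perm)
    return perms or [identity]


def heavy_atom_rmsd(
    a: Conformer,
    b: Conformer,
    automorph: bool = True,
    overlay: bool = True,
    molecule: MoleculeRecord | None = None,
    config: SamplingConfig | None = None,
    _perms: list | None = None,
) -> float:
    """Heavy-atom RMSD between two conformers of the same molecule (Å).

    With ``overlay`` the RMSD is minimized over rigid superpositions; with
    ``automorph`` it is additionally minimized over element-preserving graph
    automorphisms (requires ``molecule`` with bonds; identity otherwise).
    """
    xa, xb = a.heavy_coords, b.heavy_coords
    if xa.shape != xb.shape:
        raise ValueError("conformers have mismatched heavy-atom counts")
    if len(xa) == 0:
        raise ValueError("no heavy atoms")
    dist = _kabsch_rmsd if overlay else _plain_rmsd
    if not automorph or (molecule is None and _perms is None):
        return dist(xa, xb)
    if _perms is None:
        config = config or SamplingConfig()
        _perms = _heavy_automorphisms(molecule, config.automorphism_node_budget)
    return min(dist(xa, xb[perm]) for perm in _perms)


# ---------------------------------------------------------------------------
# exclusion-region sampling


def _energy_order(conformers: list[Conformer]) -> list[int]:
    """Indices in ascending energy; missing energies sort last, ties keep
    input order (so the lowest-energy conformer is always visited first)."""
    return sorted(
        range(len(conformers)),
        key=lambda i: (
            conformers[i].energy if conformers[i].energy is not None else np.inf,
            i,
        ),
    )


def sample_ensemble(
    conformers: list[Conformer],
    rmsd: float,
    config: SamplingConfig | None = None,
    molecule: MoleculeRecord | None = None,
) -> list[int]:
    """Reduce an ensemble to representatives mutually >= ``rmsd`` apart.

    Two-stage exclusion-region clustering: a first pass partitions the
    ensemble through a hierarchy of exclusion radii (4x, 2x, 1x the sampling
    RMSD, comparing only within the parent partition), then an O(K^2) pass
    over the stage-one representatives removes edge effects.  A final
    coverage pass promotes any conformer left farther than ``rmsd`` from all
    retained representatives, so that

    * (separation) retained pairs are >= rmsd apart, and
    * (coverage) every input conformer is within rmsd of a retained one.

    Conformers are visited in ascending energy (input order on ties), making
    the lowest-energy conformer always a representative.  Returns retained
    indices into the input list, in visit order.
    """
    if rmsd <= 0:
        raise ValueError("rmsd must be positive")
    if not conformers:
        raise ValueError("empty ensemble")
    config = config or SamplingConfig()

    perms = None
    if config.use_automorphism and molecule is not None:
        perms = _heavy_automorphisms(molecule, config.automorphism_node_budget)

    def dist(i: int, j: int) -> float:
        return heavy_atom_rmsd(
            conformers[i],
            conformers[j],
            automorph=config.use_automorphism,
            overlay=config.use_overlay,
            _perms=perms,
        )

    order = _energy_order(conformers)

    # stage 1: hierarchical partition clustering (exclusion radii 4r, 2r, r);
    # members are only compared against leaders of their own parent cluster.
    levels = [4.0 * rmsd, 2.0 * rmsd, rmsd]
    partitions: list[list[int]] = [order]
    for level in levels:
        next_parts: list[list[int]] = []
        for part in partitions:
            leaders: list[int] = []
            members: dict[int, list[int]] = {}
            for i in part:
                home = None
                for lead in leaders:
                    if dist(i, lead) < level:
                        home = lead
                        break
                if home is None:
                    leaders.append(i)
                    members[i] = [i]
                else:
                    members[home].append(i)
            next_parts.extend(members[lead] for lead in leaders)
        partitions = next_parts
    reps = [part[0] for part in partitions]

    # stage 2: O(K^2) pass over representatives removes partition edge effects
    retained: list[int] = []
    for i in reps:  # reps are already in energy order
        if all(dist(i, j) >= rmsd for j in retained):
            retained.append(i)

    # coverage repair: promote anything left uncovered by the merges above
    retained_set = set(retained)
    for i in order:
        if i in retained_set:
            continue
        if all(dist(i, j) >= rmsd for j in retained):
            retained.append(i)
            retained_set.add(i)
    return retained


def build_conformer_model(
    molecule: MoleculeRecord,
    raw: list[Conformer],
    config: SamplingConfig | None = None,
    er: float | None = None,
    postprocess=None,
) -> ConformerModel:
    """Finalize a conformer model from a raw ensemble.

    Starts at the predicted sampling RMSD; while more than ``max_conformers``
    survive, the RMSD is incremented and the ensemble re-clustered.  Retained
    conformers are canonicalized to their principal steric axes and assigned
    sequential local ids in retention (energy) order.

    ``postprocess`` is an optional hook run on the raw ensemble before
    sampling — the place to plug force-field steps such as hydrogen
    relaxation (minimize with heavy atoms frozen) or a bump check removing
    conformers with excessive atom-atom interaction energies.  It receives
    the conformer list and must return the (possibly filtered) list.
    """
    from .shape import canonicalize_principal_axes

    if postprocess is not None:
        raw = list(postprocess(raw))
    if not raw:
        raise ValueError("raw ensemble is empty")
    config = config or SamplingConfig()
    if er is None:
        nha, rb, nara = count_descriptors(molecule, EligibilityConfig())
        er = effective_rotor_count(rb, nara)
    else:
        nha = len(molecule.heavy_indices)
    rmsd = predict_sampling_rmsd(nha, er, config)

    while True:
        retained = sample_ensemble(raw, rmsd, config, molecule)
        if len(retained) <= config.max_conformers:
            break
        rmsd = round(rmsd + config.rmsd_increment, 10)

    conformers = []
    for lid, idx in enumerate(retained):
        c = canonicalize_principal_axes(raw[idx])
        c.local_id = lid
        conformers.append(c)
    return ConformerModel(
        molecule=molecule, conformers=conformers, sampling_rmsd=rmsd
    )
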