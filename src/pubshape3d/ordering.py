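"""Diverse conformer ordering.

The default (first) conformer is the lowest-energy conformer of the
ensemble.  Each subsequent pick is the conformer with the smallest sum of
combo Tanimoto (shape-optimized ST plus single-point CT) to the conformers
already assigned; ties go to the largest combo sum to the still-unassigned
conformers, then to the smallest local id.  The greedy rule makes any
k-prefix of the ordering independent of the ensemble tail already ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConformerModel

__all__ = ["DiverseOrdering", "diverse_order", "diverse_order_from_matrix"]


@dataclass
class DiverseOrdering:
    order: list[int]
    combo_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.order)
        if sorted(self.order) != list(range(n)):
            raise ValueError("order is not a permutation")
        self.combo_matrix = np.asarray(self.combo_matrix, float)
        if self.combo_matrix.shape != (n, n):
            raise ValueError("combo matrix shape mismatch")


def diverse_order_from_matrix(
    combo: np.ndarray, energies: list | None = None
) -> DiverseOrdering:
    """Greedy diverse ordering from a precomputed symmetric ComboT matrix."""
    combo = np.asarray(combo, float)
    n = len(combo)
    if energies is None:
        energies = [None] * n
    start = min(
        range(n),
        key=lambda i: (energies[i] if energies[i] is not None else np.inf, i),
    )
    assigned = [start]
    unassigned = [i for i in range(n) if i != start]
    while unassigned:
        def key(i: int):
            to_assigned = float(sum(combo[i, j] for j in assigned))
            to_unassigned = float(
                sum(combo[i, j] for j in unassigned if j != i)
            )
            # minimize similarity to assigned; tie -> maximize to unassigned;
            # tie -> smallest index (local id)
            return (round(to_assigned, 12), round(-to_unassigned, 12), i)

        pick = min(unassigned, key=key)
        assigned.append(pick)
        unassigned.remove(pick)
    return DiverseOrdering(order=assigned, combo_matrix=combo)


def diverse_order(
    model: ConformerModel,
    params=None,
    rules=None,
    set_on_model: bool = True,
) -> DiverseOrdering:
    """Compute the diverse ordering of a conformer model.

    Pairwise ComboT uses shape-mode superposition optimization with a
    single-point CT at the optimized pose (features perceived from the
    parent molecule when available).
    """
    from .features import perceive_features
    from .shape import optimize_overlap

    n = model.n_conformers
    featsets = None
    if model.molecule.rdkit_mol is not None:
        featsets = [
            perceive_features(model.molecule, c, rules) for c in model.conformers
        ]
    combo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = optimize_overlap(
                model.conformers[i],
                model.conformers[j],
                mode="shape",
                params=params,
                features_a=featsets[i] if featsets else None,
                features_b=featsets[j] if featsets else None,
            )
            combo[i, j] = combo[j, i] = res.combo
    energies = [c.energy for c in model.conformers]
    ordering = diverse_order_from_matrix(combo, energies)
    if set_on_model:
        model.diverse_order = list(ordering.order)
    return ordering
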