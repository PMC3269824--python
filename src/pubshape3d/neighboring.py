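"""The "Similar Conformers" relationship, score matrices, clustering.

Two conformers are neighbors after a shape-optimized overlay when either

* both have pharmacophore features and ST > 0.795 and CT > 0.495, or
* both are featureless and ST > 0.925 (strict inequalities).

Mixed featured/featureless pairs are never neighbors.  By default the first
three diverse conformers per compound enter neighboring (at most ten).
Searches shard trivially: the corpus is split into even slices processed
independently, and the merged record set is identical for any shard count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import Conformer, ConformerModel
from .features import FeatureSet, perceive_features
from .identifiers import encode_gid
from .shape import RigidTransform, ShapeParams, optimize_overlap

__all__ = [
    "NeighborThresholds",
    "NeighborRecord",
    "RandomSimilarityStats",
    "is_neighbor",
    "neighbor_search",
    "score_matrix",
    "single_linkage_cluster",
    "random_similarity_study",
]


@dataclass
class NeighborThresholds:
    st_featured: float = 0.795
    ct_featured: float = 0.495
    st_featureless: float = 0.925
    conformers_per_compound: int = 3

    def __post_init__(self) -> None:
        for v in (self.st_featured, self.ct_featured, self.st_featureless):
            if not (0.0 < v < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")
        if not (1 <= self.conformers_per_compound <= 10):
            raise ValueError("conformers_per_compound must be in [1, 10]")


@dataclass
class NeighborRecord:
    gid_a: int
    gid_b: int
    st: float
    ct: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.st <= 1.0 and 0.0 <= self.ct <= 1.0):
            raise ValueError("scores out of range")
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)

    @property
    def key(self) -> tuple[int, int]:
        return (self.gid_a, self.gid_b)


@dataclass
class RandomSimilarityStats:
    """Monte-Carlo distribution of random-pair similarity scores."""

    mean_st: float
    sd_st: float
    mean_ct: float
    sd_ct: float
    mean_combo: float
    sd_combo: float
    n_pairs: int
    exceedance: dict = field(default_factory=dict)

    def two_sigma_threshold(self, which: str = "combo") -> float:
        mean, sd = {
            "st": (self.mean_st, self.sd_st),
            "ct": (self.mean_ct, self.sd_ct),
            "combo": (self.mean_combo, self.sd_combo),
        }[which]
        return mean + 2.0 * sd


def is_neighbor(
    st: float,
    ct: float,
    a_has_features: bool,
    b_has_features: bool,
    t: NeighborThresholds | None = None,
) -> bool:
    """Neighbor predicate; threshold equality does NOT qualify."""
    t = t or NeighborThresholds()
    if a_has_features and b_has_features:
        return st > t.st_featured and ct > t.ct_featured
    if not a_has_features and not b_has_features:
        return st > t.st_featureless
    return False


def _model_gid(model: ConformerModel, conformer: Conformer) -> int:
    version = 0 if model.molecule.record_id_kind == "compound" else 1
    return encode_gid(model.molecule.record_id, version, conformer.local_id)


def _neighbor_candidates(
    model: ConformerModel, limit: int
) -> list[tuple[Conformer, FeatureSet]]:
    confs = model.ordered_conformers()[:limit]
    return [
        (c, perceive_features(model.molecule, c))
        if model.molecule.rdkit_mol is not None
        else (c, FeatureSet([]))
        for c in confs
    ]


def neighbor_search(
    query: ConformerModel,
    corpus: Sequence[ConformerModel],
    t: NeighborThresholds | None = None,
    shards: int = 1,
    params: ShapeParams | None = None,
    prefilter: Optional[Callable[[Conformer, Conformer], bool]] = None,
    include_self: bool = True,
) -> list[NeighborRecord]:
    """Find Similar Conformers of a query model in a corpus.

    The first ``conformers_per_compound`` diverse conformers of each model
    are compared (query and corpus).  The corpus is split into ``shards``
    even contiguous slices, each processed independently; the merged result
    set is identical for any shard count.  ``prefilter(qc, cc) -> bool``
    (e.g. a fingerprint common-bit test) may skip pairs before
    optimization.  Each unordered conformer pair appears once with
    gid_a <= gid_b.
    """
    t = t or NeighborThresholds()
    if shards < 1:
        raise ValueError("shards must be >= 1")
    q_cands = _neighbor_candidates(query, t.conformers_per_compound)

    def process(models: Sequence[ConformerModel]) -> list[NeighborRecord]:
        out: list[NeighborRecord] = []
        for model in models:
            if not include_self and model is query:
                continue
            for cc, cf in _neighbor_candidates(model, t.conformers_per_compound):
                gid_c = _model_gid(model, cc)
                for qc, qf in q_cands:
                    gid_q = _model_gid(query, qc)
                    if model is query and gid_c <= gid_q:
                        continue  # avoid self pairs / duplicates
                    if prefilter is not None and not prefilter(qc, cc):
                        continue
                    res = optimize_overlap(
                        qc, cc, mode="shape", params=params,
                        features_a=qf, features_b=cf,
                    )
                    if is_neighbor(
                        res.st, res.ct, qf.has_features(), cf.has_features(), t
                    ):
                        a, b = sorted((gid_q, gid_c))
                        if a == gid_q:
                            rot, trans = res.transform.rotation, res.transform.translation
                        else:
                            inv = res.transform.inverse()
                            rot, trans = inv.rotation, inv.translation
                        out.append(
                            NeighborRecord(a, b, res.st, res.ct, rot, trans)
                        )
        return out

    bounds = np.linspace(0, len(corpus), shards + 1).astype(int)
    records: list[NeighborRecord] = []
    for k in range(shards):
        records.extend(process(corpus[bounds[k]:bounds[k + 1]]))
    records.sort(key=lambda r: r.key)
    return records


def score_matrix(
    compounds: Sequence[ConformerModel],
    mode: str = "shape",
    per_compound: int = 10,
    metric: str = "best_pair",
    score: str = "combo",
    params: ShapeParams | None = None,
    max_pairs: int = 1_000_000,
) -> np.ndarray:
    """Symmetric compound-by-compound similarity matrix.

    ``best_pair`` keeps, per compound pair, the conformer pair maximizing
    ComboT and reports the requested score (``st``, ``ct`` or ``combo``) at
    that pose; the diagonal is the metric's self-similarity (1 for ST/CT,
    2 for ComboT).  ``all_pairs`` is available pairwise via
    :func:`pairwise_conformer_scores`.
    """
    if len(compounds) < 2:
        raise ValueError("need at least two compounds")
    if metric != "best_pair":
        raise ValueError("matrix form supports metric='best_pair'")
    if not (1 <= per_compound <= 10):
        raise ValueError("per_compound must be in [1, 10]")
    cands = [_neighbor_candidates(m, per_compound) for m in compounds]
    total = sum(
        len(cands[i]) * len(cands[j])
        for i in range(len(cands))
        for j in range(i + 1, len(cands))
    )
    if total > max_pairs:
        raise ValueError(f"conformer pair budget exceeded ({total} > {max_pairs})")

    n = len(compounds)
    out = np.zeros((n, n))
    diag = {"st": 1.0, "ct": 1.0, "combo": 2.0}[score]
    np.fill_diagonal(out, diag)
    for i in range(n):
        for j in range(i + 1, n):
            best = None
            for qc, qf in cands[i]:
                for cc, cf in cands[j]:
                    res = optimize_overlap(
                        qc, cc, mode=mode, params=params,
                        features_a=qf, features_b=cf,
                    )
                    if best is None or res.combo > best.combo:
                        best = res
            value = {"st": best.st, "ct": best.ct, "combo": best.combo}[score]
            out[i, j] = out[j, i] = value
    return out


def single_linkage_cluster(matrix: np.ndarray, threshold: float) -> list[int]:
    """Single-linkage clusters: connected components at similarity > threshold.

    Returns a cluster label per compound (labels are the smallest member
    index of each component).
    """
    matrix = np.asarray(matrix, float)
    n = len(matrix)
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be square and symmetric")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    return roots


def random_similarity_study(
    corpus,
    n_pairs: int,
    seed: int,
    params: ShapeParams | None = None,
    feature_sets: Optional[Sequence[FeatureSet]] = None,
) -> RandomSimilarityStats:
    """Monte-Carlo μ/σ of ST, CT, ComboT between random conformer pairs.

    ``corpus`` is a sequence of conformers (or a callable ``rng -> list``).
    Also reports exceedance frequencies at the μ+2σ thresholds of each
    score.  Reproducible given the seed.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    conformers = corpus(rng) if callable(corpus) else list(corpus)
    if len(conformers) < 2:
        raise ValueError("corpus must contain at least two conformers")

    sts, cts, combos = [], [], []
    for _ in range(n_pairs):
        i, j = rng.choice(len(conformers), size=2, replace=False)
        fa = feature_sets[i] if feature_sets is not None else None
        fb = feature_sets[j] if feature_sets is not None else None
        res = optimize_overlap(
            conformers[i], conformers[j], mode="shape", params=params,
            features_a=fa, features_b=fb,
        )
        sts.append(res.st)
        cts.append(res.ct)
        combos.append(res.combo)
    sts, cts, combos = np.array(sts), np.array(cts), np.array(combos)

    stats = RandomSimilarityStats(
        mean_st=float(sts.mean()), sd_st=float(sts.std()),
        mean_ct=float(cts.mean()), sd_ct=float(cts.std()),
        mean_combo=float(combos.mean()), sd_combo=float(combos.std()),
        n_pairs=n_pairs,
    )
    for name, arr in (("st", sts), ("ct", cts), ("combo", combos)):
        thr = stats.two_sigma_threshold(name)
        stats.exceedance[name] = float(np.mean(arr >= thr))
    return stats
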