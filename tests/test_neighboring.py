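"""Similar-Conformers predicate, search, score matrices, clustering."""

import numpy as np
import pytest

from pubshape3d import fixtures as fx
from pubshape3d.core import ConformerModel
from pubshape3d.neighboring import (
    NeighborThresholds,
    RandomSimilarityStats,
    is_neighbor,
    neighbor_search,
    random_similarity_study,
    score_matrix,
    single_linkage_cluster,
)


class TestIsNeighbor:
    @pytest.mark.parametrize(
        "st, ct, fa, fb, expected",
        [
            (0.796, 0.496, True, True, True),   # strictly above both
            (0.80, 0.23, True, True, False),    # CT below 0.495
            (0.93, 0.0, False, False, True),    # featureless, above 0.925
            (0.95, 0.0, True, False, False),    # mixed pair never neighbors
            (0.795, 0.9, True, True, False),    # ST boundary: equality fails
            (0.9, 0.495, True, True, False),    # CT boundary: equality fails
            (0.925, 0.0, False, False, False),  # featureless boundary
        ],
    )
    def test_threshold_semantics(self, st, ct, fa, fb, expected):
        assert is_neighbor(st, ct, fa, fb) is expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            NeighborThresholds(st_featured=1.0)
        with pytest.raises(ValueError):
            NeighborThresholds(conformers_per_compound=11)


def _cloud_models(n, seed0=900, per_model=2, jitter=0.05):
    models = []
    for s in range(n):
        rec, confs = fx.point_cloud_ensemble(
            n_atoms=7, n_conformers=per_model, jitter=jitter,
            seed=seed0 + s, record_id=s + 1,
        )
        models.append(ConformerModel(molecule=rec, conformers=confs))
    return models


class TestNeighborSearch:
    def test_self_match(self):
        models = _cloud_models(1)
        records = neighbor_search(models[0], models)
        assert records  # the model's own near-duplicate conformers pair up
        assert all(r.st > 0.925 for r in records)

    def test_shard_invariance(self):
        models = _cloud_models(6)
        query = models[0]
        sets = {}
        for shards in (1, 2, 4, 6):
            recs = neighbor_search(query, models, shards=shards)
            sets[shards] = [(r.key, round(r.st, 8), round(r.ct, 8)) for r in recs]
        assert sets[1] == sets[2] == sets[4] == sets[6]

    def test_prefilter_consistency(self):
        from pubshape3d.fingerprint import (
            build_reference_set,
            fingerprint_conformer,
        )

        # near-duplicate corpus: every true neighbor pair shares a reference
        rec0, base = fx.point_cloud_ensemble(
            n_atoms=7, n_conformers=1, seed=77, record_id=1
        )
        models = []
        for s in range(4):
            coords = base[0].coords + np.random.default_rng(s).normal(
                scale=0.05, size=base[0].coords.shape
            )
            from pubshape3d.core import Conformer, MoleculeRecord

            rec = MoleculeRecord.from_point_cloud(7, record_id=s + 1)
            models.append(
                ConformerModel(
                    molecule=rec,
                    conformers=[Conformer(coords=coords, local_id=0)],
                )
            )
        refs = build_reference_set([base[0]], 0.8)
        fps = {
            id(m.conformers[0]): fingerprint_conformer(m.conformers[0], refs)
            for m in models
        }

        def prefilter(qc, cc):
            return bool(
                set(fps[id(qc)].bits) & set(fps[id(cc)].bits)
            )

        query = models[0]
        plain = neighbor_search(query, models)
        filtered = neighbor_search(query, models, prefilter=prefilter)
        assert [(r.key, round(r.st, 8)) for r in plain] == [
            (r.key, round(r.st, 8)) for r in filtered
        ]

    def test_record_transform_reproduces_pose(self):
        from pubshape3d.identifiers import decode_gid
        from pubshape3d.shape import RigidTransform, shape_tanimoto

        models = _cloud_models(2, seed0=910)
        query = models[0]
        records = neighbor_search(query, models)
        by_gid = {}
        for m in models:
            for c in m.conformers:
                from pubshape3d.neighboring import _model_gid

                by_gid[_model_gid(m, c)] = c
        for r in records:
            t = RigidTransform(r.rotation, r.translation)
            st = shape_tanimoto(by_gid[r.gid_a], by_gid[r.gid_b], t)
            assert st == pytest.approx(r.st, abs=1e-6)


class TestScoreMatrix:
    def test_symmetric_and_matches_recompute(self):
        from pubshape3d.shape import optimize_overlap

        models = _cloud_models(4, seed0=930, per_model=2)
        m = score_matrix(models, per_compound=2, score="combo")
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 2.0)
        # element-wise oracle: best conformer pair by ComboT
        best = 0.0
        for qc in models[0].conformers:
            for cc in models[1].conformers:
                best = max(best, optimize_overlap(qc, cc).combo)
        assert m[0, 1] == pytest.approx(best, abs=1e-6)

    def test_pair_budget_enforced(self):
        models = _cloud_models(3, seed0=940)
        with pytest.raises(ValueError):
            score_matrix(models, per_compound=2, max_pairs=2)

    def test_needs_two_compounds(self):
        with pytest.raises(ValueError):
            score_matrix(_cloud_models(1))


class TestSingleLinkage:
    def test_extreme_thresholds(self, rng):
        m = rng.uniform(0, 0.9, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        labels_hi = single_linkage_cluster(m, 0.95)
        assert labels_hi == list(range(6))  # all singletons
        labels_lo = single_linkage_cluster(m, -0.1)
        assert len(set(labels_lo)) == 1

    def test_matches_graph_connectivity_oracle(self, rng):
        import networkx as nx

        for _ in range(5):
            m = rng.uniform(0, 1, size=(10, 10))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            thr = 0.7
            labels = single_linkage_cluster(m, thr)
            g = nx.Graph()
            g.add_nodes_from(range(10))
            for i in range(10):
                for j in range(i + 1, 10):
                    if m[i, j] > thr:
                        g.add_edge(i, j)
            for comp in nx.connected_components(g):
                comp = sorted(comp)
                assert len({labels[i] for i in comp}) == 1
            assert len(set(labels)) == nx.number_connected_components(g)


class TestRandomSimilarityStudy:
    def test_degenerate_corpus(self, small_clouds):
        c = small_clouds[0]
        corpus = [c, c.with_coords(c.coords + 1.0), c.with_coords(c.coords)]
        stats = random_similarity_study(corpus, n_pairs=5, seed=1)
        assert stats.mean_st == pytest.approx(1.0, abs=1e-6)
        assert stats.sd_st == pytest.approx(0.0, abs=1e-6)

    def test_two_sigma_threshold_arithmetic(self):
        stats = RandomSimilarityStats(
            mean_st=0.54, sd_st=0.10, mean_ct=0.07, sd_ct=0.05,
            mean_combo=0.62, sd_combo=0.13, n_pairs=100,
        )
        assert stats.two_sigma_threshold("st") == pytest.approx(0.74)
        assert stats.two_sigma_threshold("ct") == pytest.approx(0.17)
        assert stats.two_sigma_threshold("combo") == pytest.approx(0.88)

    def test_deterministic_under_seed(self, small_clouds):
        a = random_similarity_study(small_clouds, n_pairs=6, seed=9)
        b = random_similarity_study(small_clouds, n_pairs=6, seed=9)
        assert a.mean_combo == b.mean_combo
        assert a.exceedance == b.exceedance

    def test_n_pairs_validation(self, small_clouds):
        with pytest.raises(ValueError):
            random_similarity_study(small_clouds, n_pairs=1, seed=0)
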