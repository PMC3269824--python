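"""Sampling RMSD prediction, symmetry-aware RMSD, exclusion clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pubshape3d import fixtures as fx
from pubshape3d.core import AtomSpec, Conformer, MoleculeRecord
from pubshape3d.sampling import (
    GeneratorConfig,
    SamplingConfig,
    build_conformer_model,
    heavy_atom_rmsd,
    predict_sampling_rmsd,
    sample_ensemble,
)


class TestPredictSamplingRmsd:
    @pytest.mark.parametrize(
        "nha, er, expected",
        [
            (5, 0, 0.4),    # 0.2685 rounds to 0.2, floor engages
            (20, 3, 0.6),   # 0.537 rounds to 0.6
            (50, 15, 1.4),  # 1.314 rounds to 1.4
            (1, 0, 0.4),
        ],
    )
    def test_examples(self, nha, er, expected):
        assert predict_sampling_rmsd(nha, er) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_sampling_rmsd(0, 0)
        with pytest.raises(ValueError):
            predict_sampling_rmsd(5, -1)

    @given(st.integers(1, 60), st.floats(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_result_is_positive_increment_multiple(self, nha, er):
        r = predict_sampling_rmsd(nha, er)
        assert r >= 0.4 - 1e-12
        assert abs(r / 0.2 - round(r / 0.2)) < 1e-9


def _hexagon_record():
    """Noisy hexagonal 'ring' with explicit cycle bonds (no chemistry)."""
    rng = np.random.default_rng(7)
    theta = 2 * np.pi * np.arange(6) / 6
    coords = np.stack(
        [1.4 * np.cos(theta), 1.4 * np.sin(theta), np.zeros(6)], axis=1
    )
    coords += rng.normal(scale=0.05, size=coords.shape)
    record = MoleculeRecord(
        atoms=[AtomSpec(element="C") for _ in range(6)],
        bonds=[(i, (i + 1) % 6, 1, False) for i in range(6)],
    )
    return record, Conformer(coords=coords)


class TestHeavyAtomRmsd:
    def test_identical_is_zero(self, small_clouds):
        c = small_clouds[0]
        assert heavy_atom_rmsd(c, c) == pytest.approx(0.0, abs=1e-6)

    def test_overlay_removes_rigid_motion(self, small_clouds):
        c = small_clouds[0]
        shifted = c.with_coords(c.coords + np.array([1.0, 0.0, 0.0]))
        assert heavy_atom_rmsd(c, shifted, overlay=True) == pytest.approx(0.0, abs=1e-6)
        assert heavy_atom_rmsd(c, shifted, overlay=False) == pytest.approx(1.0)

    def test_symmetry(self, small_clouds):
        a, b = small_clouds[0], small_clouds[1]
        assert heavy_atom_rmsd(a, b) == pytest.approx(heavy_atom_rmsd(b, a))

    def test_ring_relabeling_needs_automorphisms(self):
        # cyclic relabeling of a (noisy) ring: zero only when the RMSD is
        # minimized over graph automorphisms
        record, conf = _hexagon_record()
        rolled = conf.with_coords(np.roll(conf.coords, 1, axis=0))
        with_auto = heavy_atom_rmsd(rolled, conf, automorph=True, molecule=record)
        without = heavy_atom_rmsd(rolled, conf, automorph=False)
        assert with_auto == pytest.approx(0.0, abs=1e-6)
        assert without > 0.01

    def test_mismatched_counts_error(self, small_clouds):
        c = small_clouds[0]
        other = Conformer(coords=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            heavy_atom_rmsd(c, other)


def _brute_force_check(conformers, retained, rmsd):
    """O(N^2) oracle: verify coverage and separation by exhaustive RMSD."""
    for i, a in enumerate(conformers):
        if i in retained:
            continue
        assert any(
            heavy_atom_rmsd(a, conformers[j]) < rmsd for j in retained
        ), f"conformer {i} uncovered"
    for i in retained:
        for j in retained:
            if i < j:
                d = heavy_atom_rmsd(conformers[i], conformers[j])
                assert d >= rmsd - 1e-6, f"retained pair ({i},{j}) too close"


class TestSampleEnsemble:
    def test_single_conformer(self, small_clouds):
        assert sample_ensemble([small_clouds[0]], 0.4) == [0]

    def test_duplicates_collapse(self, small_clouds):
        c = small_clouds[0]
        dup = c.with_coords(c.coords.copy())
        assert len(sample_ensemble([c, dup], 0.4)) == 1

    def test_bad_rmsd(self, small_clouds):
        with pytest.raises(ValueError):
            sample_ensemble([small_clouds[0]], 0.0)
        with pytest.raises(ValueError):
            sample_ensemble([], 0.4)

    def test_coverage_and_separation_vs_oracle(self):
        _rec, confs = fx.point_cloud_ensemble(
            n_atoms=6, n_conformers=50, jitter=0.6, seed=11
        )
        retained = sample_ensemble(confs, 0.8)
        _brute_force_check(confs, set(retained), 0.8)

    def test_small_ensembles_vs_oracle(self):
        for seed in range(4):
            _rec, confs = fx.point_cloud_ensemble(
                n_atoms=5, n_conformers=20, jitter=0.5, seed=seed
            )
            retained = sample_ensemble(confs, 0.6)
            _brute_force_check(confs, set(retained), 0.6)

    def test_idempotence(self):
        _rec, confs = fx.point_cloud_ensemble(
            n_atoms=6, n_conformers=30, jitter=0.5, seed=3
        )
        retained = sample_ensemble(confs, 0.7)
        subset = [confs[i] for i in retained]
        again = sample_ensemble(subset, 0.7)
        assert again == list(range(len(subset)))

    def test_lowest_energy_always_retained(self):
        _rec, confs = fx.point_cloud_ensemble(
            n_atoms=6, n_conformers=20, jitter=0.3, seed=5
        )
        for k, c in enumerate(confs):
            c.energy = float(20 - k)  # lowest energy is the last conformer
        retained = sample_ensemble(confs, 0.5)
        assert retained[0] == len(confs) - 1

    def test_well_separated_set_fully_retained(self):
        # duplicate-free set: group bases only, mutually far apart
        _rec, confs, labels = fx.duplicate_group_ensemble(
            n_groups=6, per_group=1, jitter=0.05, seed=9
        )
        retained = sample_ensemble(confs, 0.4)
        assert sorted(retained) == list(range(6))


class TestBuildConformerModel:
    def test_single_raw_conformer(self):
        rec, confs = fx.point_cloud_ensemble(n_atoms=8, n_conformers=1, seed=0)
        model = build_conformer_model(rec, confs)
        assert model.n_conformers == 1
        assert model.sampling_rmsd == predict_sampling_rmsd(8, 0.0)

    def test_near_duplicates_respect_cap(self):
        rec, confs = fx.near_duplicate_ensemble(n_conformers=800, seed=4)
        model = build_conformer_model(rec, confs)
        assert model.n_conformers <= 500

    def test_cap_loop_coarsens_rmsd(self):
        # many distinct shapes, tiny cap: the RMSD must be incremented
        rec, confs, _ = fx.duplicate_group_ensemble(
            n_groups=8, per_group=1, jitter=0.02, seed=13
        )
        config = SamplingConfig(max_conformers=3)
        model = build_conformer_model(rec, confs, config)
        assert model.n_conformers <= 3
        assert model.sampling_rmsd > 0.4

    def test_group_count_recovered(self):
        rec, confs, labels = fx.duplicate_group_ensemble(
            n_groups=5, per_group=10, jitter=0.05, seed=21
        )
        model = build_conformer_model(rec, confs)
        assert model.n_conformers == 5

    def test_local_ids_sequential_and_canonicalized(self):
        from pubshape3d.shape import canonicalize_principal_axes

        rec, confs = fx.point_cloud_ensemble(n_atoms=8, n_conformers=5, seed=2)
        model = build_conformer_model(rec, confs)
        assert [c.local_id for c in model.conformers] == list(
            range(model.n_conformers)
        )
        for c in model.conformers:
            recanon = canonicalize_principal_axes(c)
            assert np.abs(recanon.coords - c.coords).max() < 1e-8

    def test_empty_raw_rejected(self):
        rec = MoleculeRecord.from_point_cloud(3)
        with pytest.raises(ValueError):
            build_conformer_model(rec, [])


def test_generator_config_contract():
    cfg = GeneratorConfig()
    assert cfg.energy_window == 25.0
    assert cfg.max_conformers_per_stereoisomer == 100000
    with pytest.raises(ValueError):
        GeneratorConfig(energy_window=0)


def test_sampling_config_invariants():
    with pytest.raises(ValueError):
        SamplingConfig(rmsd_floor=0.1, rmsd_increment=0.2)
    with pytest.raises(ValueError):
        SamplingConfig(max_conformers=0)
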