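import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import chisquare

from burialcrf import (
    GeneratorConfig,
    load_benchmark,
    make_benchmark,
    make_generating_params,
    preset,
    sample_dataset,
    sample_labels_given_features,
    sample_segmentation,
)
from burialcrf.model import sequence_log_score
from burialcrf.synthetic import sample_features, sample_record

from conftest import random_instance


class TestSampleSegmentation:
    def test_length_one_single_segment(self):
        cfg = GeneratorConfig(seed=0)
        segm = sample_segmentation(1, cfg, np.random.default_rng(0))
        assert len(segm) == 1 and segm.length == 1

    def test_all_coil_config_gives_one_segment(self):
        cfg = GeneratorConfig(ss_freqs={"H": 0, "E": 0, "C": 1}, seed=0)
        segm = sample_segmentation(50, cfg, np.random.default_rng(0))
        assert len(segm) == 1
        assert segm.segments[0].ss_type == "C"

    def test_adjacent_types_differ(self):
        cfg = GeneratorConfig(seed=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            segm = sample_segmentation(80, cfg, rng)
            types = [s.ss_type for s in segm]
            assert all(a != b for a, b in zip(types, types[1:]))

    def test_empirical_mean_lengths(self):
        # geometric segment lengths: empirical means within 5% of config
        # (last segment of each chain dropped: it is truncated to fit)
        cfg = GeneratorConfig(mean_len={"H": 8.0, "E": 5.0, "C": 4.0}, seed=0)
        rng = np.random.default_rng(2)
        lengths = {"H": [], "E": [], "C": []}
        while sum(len(v) for v in lengths.values()) < 10_000:
            segm = sample_segmentation(2000, cfg, rng)
            for seg in segm.segments[:-1]:
                lengths[seg.ss_type].append(len(seg))
        for t, mean in cfg.mean_len.items():
            assert np.mean(lengths[t]) == pytest.approx(mean, rel=0.05)


class TestSampleFeatures:
    def test_shapes_and_bias_columns(self):
        cfg = GeneratorConfig(n_signal_cols=3, n_noise_cols=2, seed=0)
        rng = np.random.default_rng(0)
        segm = sample_segmentation(30, cfg, rng)
        X, U = sample_features(30, segm, cfg, rng)
        assert X.shape == (30, 6)
        assert (X[:, 0] == 1).all()
        for d in (2, 3, 4):
            assert U[d].shape == (30, 4)
            assert (U[d][d:, 0] == 1).all()
            assert (U[d][d:, 1] >= 0).all()

    def test_zero_effect_size_means_no_signal(self):
        cfg = GeneratorConfig(effect_size=0.0, seed=0)
        params = make_generating_params(cfg)
        assert (params.theta == 0).all()

    def test_class_conditional_mean_shift(self):
        # with positive effect size, signal columns must separate the
        # classes a posteriori; noise columns must not
        cfg = GeneratorConfig(
            n_proteins=30, effect_size=1.5, coupling={}, seed=11
        )
        records, _ = sample_dataset(cfg)
        X = np.vstack([r.singlet_features for r in records])
        y = np.concatenate([r.labels for r in records])
        signal = X[:, 1 : 1 + cfg.n_signal_cols]
        noise = X[:, 1 + cfg.n_signal_cols :]
        gap_signal = signal[y == 1].mean(axis=0) - signal[y == 0].mean(axis=0)
        gap_noise = noise[y == 1].mean(axis=0) - noise[y == 0].mean(axis=0)
        se = 1.0 / np.sqrt((y == 1).sum())  # unit-variance columns
        assert (gap_signal > 3 * se).all()
        assert (np.abs(gap_noise) < 3 * se).all()


class TestSampleLabels:
    def test_zero_model_gives_fair_coins(self):
        rec, params = random_instance(np.random.default_rng(0), L=10)
        z = params.with_vector(np.zeros(params.to_vector().size))
        draws = sample_labels_given_features(
            rec, z, np.random.default_rng(1), size=1000
        )
        counts = np.bincount(draws.ravel(), minlength=2)
        assert chisquare(counts).pvalue > 0.01

    def test_exact_sampling_matches_enumeration(self):
        # keystone: FFBS draws distribute exactly as the enumerated law
        rng = np.random.default_rng(5)
        rec, params = random_instance(rng, L=6, weight_scale=1.5)
        draws = sample_labels_given_features(
            rec, params, np.random.default_rng(6), size=50_000
        )
        codes = draws @ (1 << np.arange(6))
        emp = np.bincount(codes, minlength=64) / draws.shape[0]
        labelings = np.array(list(itertools.product((0, 1), repeat=6)))
        scores = np.array([sequence_log_score(params, rec, y) for y in labelings])
        p = np.exp(scores - logsumexp(scores))
        ref = np.zeros(64)
        ref[labelings @ (1 << np.arange(6))] = p
        tv = 0.5 * np.abs(emp - ref).sum()
        assert tv < 0.02

    def test_strong_helix_coupling_raises_long_range_mi(self):
        from burialcrf.evaluation import mi_vs_separation

        cfg = preset("helix_coupled", n_proteins=60, seed=3)
        records, _ = sample_dataset(cfg)
        mi = mi_vs_separation(
            [r.labels for r in records], [r.segmentation for r in records], max_sep=4
        )
        h = mi[mi.ss_type == "H"].set_index("separation")["mi_bits"]
        assert h[4] > h[2] and h[3] > h[2]


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = GeneratorConfig(n_proteins=5, seed=42)
        a, _ = sample_dataset(cfg)
        b, _ = sample_dataset(cfg)
        for ra, rb in zip(a, b):
            assert ra.sequence == rb.sequence
            assert ra.ss_string() == rb.ss_string()
            assert ra.singlet_features.tobytes() == rb.singlet_features.tobytes()
            assert ra.labels.tobytes() == rb.labels.tobytes()

    def test_different_seed_differs(self):
        a, _ = sample_dataset(GeneratorConfig(n_proteins=3, seed=1))
        b, _ = sample_dataset(GeneratorConfig(n_proteins=3, seed=2))
        assert any(ra.sequence != rb.sequence for ra, rb in zip(a, b))


class TestBenchmark:
    def test_folds_equal_size_and_disjoint(self, tmp_path):
        cfg = GeneratorConfig(n_proteins=20, length_min=20, length_max=40, seed=9)
        make_benchmark(cfg, tmp_path / "bench")
        folds = load_benchmark(tmp_path / "bench")
        assert len(folds) == 5
        sizes = [len(v) for v in folds.values()]
        assert sizes == [4] * 5
        ids = [r.id for recs in folds.values() for r in recs]
        assert len(ids) == len(set(ids))

    def test_round_trip_preserves_data(self, tmp_path):
        cfg = GeneratorConfig(n_proteins=5, length_min=20, length_max=30, seed=9)
        records, _ = sample_dataset(cfg)
        make_benchmark(cfg, tmp_path / "bench")
        folds = load_benchmark(tmp_path / "bench")
        by_id = {r.id: r for recs in folds.values() for r in recs}
        for r in records:
            r2 = by_id[r.id]
            assert r2.sequence == r.sequence
            assert r2.ss_string() == r.ss_string()
            np.testing.assert_allclose(r2.singlet_features, r.singlet_features)
            np.testing.assert_array_equal(r2.labels, r.labels)

    def test_manifest_deterministic(self, tmp_path):
        cfg = GeneratorConfig(n_proteins=8, length_min=20, length_max=30, seed=4)
        d1 = make_benchmark(cfg, tmp_path / "a")
        d2 = make_benchmark(cfg, tmp_path / "b")
        assert (d1 / "manifest.json").read_text() == (d2 / "manifest.json").read_text()
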