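"""Phantom generator: determinism, monotone malignancy construction,
geometry versus closed forms, reader simulation against an enumerated
rating-noise oracle, manifest consistency."""

import itertools

import numpy as np
import pytest
from scipy import stats

from nodulenet.annotations import EXCLUDED, individual_label, panel_label
from nodulenet.synthetic import (
    PhantomConfig,
    PhantomTruth,
    generate_truth,
    latent_malignancy,
    make_samples,
    perturb_mask,
    semantic_truth,
    simulate_readers,
)


class TestGenerateTruth:
    def test_same_config_and_index_bit_identical(self):
        cfg = PhantomConfig(n_nodules=4, cube_side=24, seed=11)
        c1, t1 = generate_truth(cfg, 2)
        c2, t2 = generate_truth(cfg, 2)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(t1.true_mask, t2.true_mask)
        assert t1.latent_malignancy == t2.latent_malignancy

    def test_values_in_unit_interval(self):
        cfg = PhantomConfig(n_nodules=2, cube_side=24, seed=1)
        cube, _ = generate_truth(cfg, 0)
        assert cube.min() >= 0.0 and cube.max() <= 1.0
        assert cube.shape == (24, 24, 24)

    def test_smooth_benign_latent_in_benign_band(self):
        cfg = PhantomConfig(n_nodules=8, cube_side=24, seed=2)
        for i in range(8):
            _, truth = generate_truth(cfg, i, malignant=False)
            assert truth.latent_malignancy < 3.0

    def test_malignant_latent_in_malignant_band(self):
        cfg = PhantomConfig(n_nodules=8, cube_side=24, seed=2)
        for i in range(8):
            _, truth = generate_truth(cfg, i, malignant=True)
            assert truth.latent_malignancy >= 3.5

    def test_latent_monotone_in_spike_amplitude_and_lobes(self):
        amps = np.linspace(0, 1, 21)
        for L in range(5):
            vals = [latent_malignancy(a, L) for a in amps]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for a in (0.0, 0.4, 0.9):
            vals = [latent_malignancy(a, L) for L in range(5)]
            assert all(b >= a2 for a2, b in zip(vals, vals[1:]))

    def test_smooth_mask_volume_matches_ellipsoid_closed_form(self):
        """Spike-free, lobe-free masks voxelise (4/3)*pi*a*b*c within 10%."""
        cfg = PhantomConfig(n_nodules=6, cube_side=32, seed=4)
        for i in range(6):
            _, truth = generate_truth(cfg, i, malignant=False)
            if truth.spike_count or truth.lobe_count:
                continue
            a, b, c = truth.radii
            analytic = 4.0 / 3.0 * np.pi * a * b * c
            assert truth.true_mask.sum() == pytest.approx(analytic,
                                                          rel=0.10)

    def test_class_sequence_hits_malignant_fraction(self):
        cfg = PhantomConfig(n_nodules=50, cube_side=16,
                            malignant_fraction=0.36, seed=5)
        samples = make_samples(cfg)
        nodule_latent = {}
        for s in samples:
            nodule_latent.setdefault(s.nodule_id, s.labels["individual"])
        # noise-free fraction check needs per-nodule truth; rely on latent
        cfg0 = PhantomConfig(n_nodules=50, cube_side=16,
                             malignant_fraction=0.36, rating_noise_sd=0.0,
                             mask_jitter=0, seed=5)
        truths = [generate_truth(cfg0, i)[1].latent_malignancy > 3
                  for i in range(50)]
        assert abs(np.mean(truths) - 0.36) <= 0.05


class TestSemanticTruth:
    def test_scores_within_declared_ranges(self):
        cfg = PhantomConfig(n_nodules=10, cube_side=24, seed=6)
        for i in range(10):
            _, truth = generate_truth(cfg, i)
            scores = semantic_truth(truth, 24)
            assert 1 <= scores["internalStructure"] <= 4
            assert 1 <= scores["calcification"] <= 6
            for f in ("subtlety", "sphericity", "margin", "lobulation",
                      "spiculation", "texture"):
                assert 1 <= scores[f] <= 5

    def test_spiculation_monotone_in_amplitude(self):
        base = dict(latent_malignancy=3.0, radii=(5.0, 5.0, 5.0),
                    spike_count=5, lobe_count=0, calcified=False,
                    margin_blur=0.5, texture="solid")
        scores = [semantic_truth(PhantomTruth(spike_amp=a, **base), 24)
                  ["spiculation"] for a in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_calcification_six_means_no_core(self):
        base = dict(latent_malignancy=2.0, radii=(5.0, 5.0, 5.0),
                    spike_count=0, spike_amp=0.0, lobe_count=0,
                    margin_blur=0.5, texture="solid")
        assert semantic_truth(PhantomTruth(calcified=False, **base),
                              24)["calcification"] == 6
        assert semantic_truth(PhantomTruth(calcified=True, **base),
                              24)["calcification"] != 6


class TestSimulateReaders:
    @pytest.fixture
    def small_truth(self):
        cfg = PhantomConfig(n_nodules=1, cube_side=16, seed=7)
        _, truth = generate_truth(cfg, 0, malignant=False)
        return truth

    def test_noise_free_readers_rate_rounded_latent(self, small_truth):
        cfg = PhantomConfig(n_nodules=1, cube_side=16, rating_noise_sd=0.0,
                            mask_jitter=0, semantic_noise=False, seed=7)
        anns = simulate_readers(small_truth, cfg, np.random.default_rng(0))
        expected = int(np.clip(round(small_truth.latent_malignancy), 1, 5))
        assert all(a.malignancy == expected for a in anns)

    def test_zero_jitter_masks_equal_truth(self, small_truth):
        cfg = PhantomConfig(n_nodules=1, cube_side=16, mask_jitter=0, seed=7)
        anns = simulate_readers(small_truth, cfg, np.random.default_rng(1))
        for a in anns:
            np.testing.assert_array_equal(a.mask, small_truth.true_mask)

    def test_jittered_masks_keep_dice_at_least_07(self, small_truth):
        from nodulenet.synthetic import _dice

        cfg = PhantomConfig(n_nodules=1, cube_side=16, mask_jitter=3,
                            rating_noise_sd=1.5, seed=7)
        rng = np.random.default_rng(2)
        for _ in range(10):
            for a in simulate_readers(small_truth, cfg, rng):
                assert _dice(a.mask.astype(bool),
                             small_truth.true_mask.astype(bool)) >= 0.7

    def test_disagreement_rate_matches_enumerated_oracle(self, small_truth):
        """Monte-Carlo fraction of annotations whose individual label
        contradicts their panel label (latent 3.5, rating noise sd 0.7,
        4 readers, 2000 draws) versus exact enumeration of the
        clipped-rounded-Gaussian rating distribution, within 2 points."""
        sd, latent, R = 0.7, 3.5, 4
        # exact rating pmf: round() maps (k-0.5, k+0.5) -> k, tails clip
        edges = np.array([-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf])
        cdf = stats.norm.cdf(edges, loc=latent, scale=sd)
        pmf = np.diff(cdf)
        num = den = 0.0
        for ratings in itertools.product(range(1, 6), repeat=R):
            prob = np.prod([pmf[r - 1] for r in ratings])
            panel = panel_label(list(ratings))
            if panel == EXCLUDED:
                continue
            den += prob * R
            num += prob * sum(individual_label(r) != panel for r in ratings)
        exact = num / den

        truth = PhantomTruth(
            latent_malignancy=latent, radii=small_truth.radii,
            spike_count=0, spike_amp=0.0, lobe_count=0, calcified=False,
            margin_blur=0.5, texture="solid",
            true_mask=small_truth.true_mask, center=small_truth.center)
        cfg = PhantomConfig(n_nodules=1, cube_side=16, readers=R,
                            rating_noise_sd=sd, mask_jitter=0,
                            semantic_noise=False, seed=8)
        rng = np.random.default_rng(8)
        hits = total = 0
        for _ in range(2000):
            anns = simulate_readers(truth, cfg, rng)
            panel = panel_label([a.malignancy for a in anns])
            if panel == EXCLUDED:
                continue
            total += R
            hits += sum(individual_label(a.malignancy) != panel
                        for a in anns)
        assert hits / total == pytest.approx(exact, abs=0.02)


class TestMakeSamples:
    def test_zero_nodules_empty(self):
        cfg = PhantomConfig(n_nodules=0, cube_side=16, seed=0)
        assert make_samples(cfg) == []

    def test_one_sample_per_reader_per_nodule(self):
        cfg = PhantomConfig(n_nodules=3, readers=4, cube_side=16, seed=1)
        assert len(make_samples(cfg)) == 12

    def test_panel_labels_recomputable_from_manifest_ratings(self, tmp_path):
        from nodulenet.annotations import read_manifest
        from nodulenet.synthetic import build_dataset

        cfg = PhantomConfig(n_nodules=3, readers=4, cube_side=16, seed=9)
        manifest = build_dataset(cfg, tmp_path)
        doc = read_manifest(manifest)
        by_nodule = {}
        for rec in doc["annotations"]:
            by_nodule.setdefault(rec["nodule_key"], []).append(
                rec["malignancy"])
        for key, ratings in by_nodule.items():
            stored = doc["labels"][f"{key}/r0"]["panel"]
            assert panel_label(ratings) == stored

    def test_reproducible_from_seed(self):
        cfg = PhantomConfig(n_nodules=2, readers=2, cube_side=16, seed=13)
        s1 = make_samples(cfg)
        s2 = make_samples(cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.nodule_cube, b.nodule_cube)
            np.testing.assert_array_equal(a.mask_cube, b.mask_cube)
            assert a.labels == b.labels
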