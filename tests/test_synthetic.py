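"""Synthetic-data generator: phenotypes, atlas, ground truth, BOLD forward model."""

import dataclasses

import numpy as np
import pytest

from ecpredict.atlas import NETWORK_LABELS
from ecpredict.errors import ConfigError, StabilityError
from ecpredict.synthetic import (
    GroundTruthModel,
    SimulationConfig,
    make_atlas,
    make_ground_truth_ec,
    make_phenotypes,
    make_subject_ecs,
    planted_network_model,
    simulate_bold,
)


class TestPhenotypes:
    def test_scores_are_integers_within_bounds(self):
        phen = make_phenotypes(n_subjects=206, mean=34.7, sd=7.8, bounds=(25, 61), seed=3)
        scores = phen["ctq_total"]
        assert len(phen) == 206
        assert scores.dtype.kind == "i"
        assert scores.between(25, 61).all()

    def test_degenerate_bounds_yield_constant_score(self):
        phen = make_phenotypes(n_subjects=1, mean=34.7, sd=7.8, bounds=(30, 30), seed=0)
        assert phen["ctq_total"].tolist() == [30]

    def test_moments_match_target_at_large_n(self):
        # the truncated law itself must carry the target moments
        phen = make_phenotypes(n_subjects=10_000, seed=7)
        assert abs(phen["ctq_total"].mean() - 34.7) < 0.3
        assert abs(phen["ctq_total"].std() - 7.8) < 0.3

    @pytest.mark.parametrize("kwargs", [{"n_subjects": 0}, {"sd": -1.0}, {"bounds": (40, 30)}])
    def test_invalid_arguments_raise(self, kwargs):
        with pytest.raises(ConfigError):
            make_phenotypes(**kwargs)


class TestAtlasFactory:
    def test_default_atlas_has_100_parcels_and_7_blocks(self):
        atlas = make_atlas()
        assert atlas.n_parcels == 100
        assert atlas.networks == NETWORK_LABELS
        # contiguous blocks: label changes exactly 6 times
        changes = sum(a != b for a, b in zip(atlas.labels, atlas.labels[1:]))
        assert changes == 6

    def test_block_boundaries_at_cumulative_sums(self):
        sizes = {"Vis": 10, "SMN": 8, "DAN": 7, "VAN": 6, "Lim": 5, "FPN": 6, "DMN": 8}
        atlas = make_atlas(sizes)
        assert atlas.n_parcels == 50
        start = 0
        for lab in NETWORK_LABELS:
            idx = atlas.parcels_in(lab)
            assert idx.tolist() == list(range(start, start + sizes[lab]))
            start += sizes[lab]

    def test_singleton_networks(self, tiny_atlas):
        assert tiny_atlas.n_parcels == 7
        assert all(tiny_atlas.parcels_in(lab).size == 1 for lab in NETWORK_LABELS)

    def test_missing_or_extra_label_rejected(self):
        with pytest.raises(ConfigError):
            make_atlas({"Vis": 10})
        bad = {lab: 2 for lab in NETWORK_LABELS}
        bad["Extra"] = 1
        with pytest.raises(ConfigError):
            make_atlas(bad)


class TestGroundTruthEC:
    def test_zero_density_gives_pure_decay(self, small_atlas):
        ec = make_ground_truth_ec(small_atlas, self_strength=-0.4, off_diag_density=0.0)
        assert np.allclose(ec, -0.4 * np.eye(28))
        assert np.allclose(np.linalg.eigvals(ec).real, -0.4)

    def test_density_controls_sparsity(self, small_atlas):
        ec = make_ground_truth_ec(small_atlas, off_diag_density=0.1, seed=5)
        n_off = np.count_nonzero(ec) - 28
        # binomial(756, 0.1): mean 75.6, sd ~8.2
        assert 40 <= n_off <= 115

    @pytest.mark.parametrize("seed", range(5))
    def test_every_output_is_stable(self, small_atlas, seed):
        ec = make_ground_truth_ec(small_atlas, off_diag_sd=0.4, seed=seed)
        assert np.linalg.eigvals(ec).real.max() < 0

    def test_positive_self_strength_rejected(self, small_atlas):
        with pytest.raises(ConfigError):
            make_ground_truth_ec(small_atlas, self_strength=0.1)


class TestSubjectECs:
    def test_zero_effect_and_zero_jitter_reproduce_base(self, small_atlas):
        phen = make_phenotypes(n_subjects=5, seed=1)
        base = make_ground_truth_ec(small_atlas, seed=2)
        model = GroundTruthModel(
            base_ec=base, effect_edges=(), effect_sizes=np.array([]),
            edge_noise_sd=0.0, atlas=small_atlas, seed=0,
        )
        for ec in make_subject_ecs(model, phen):
            assert np.array_equal(ec, base)

    def test_noiseless_effect_edge_tracks_score_perfectly(self, small_atlas):
        phen = make_phenotypes(n_subjects=50, seed=1)
        base = make_ground_truth_ec(small_atlas, seed=2)
        dmn = small_atlas.parcels_in("DMN")
        edge = (int(dmn[0]), int(dmn[1]))
        model = GroundTruthModel(
            base_ec=base, effect_edges=(edge,), effect_sizes=np.array([0.1]),
            edge_noise_sd=0.0, atlas=small_atlas, seed=0,
        )
        ecs = make_subject_ecs(model, phen)
        weights = [ec[edge] for ec in ecs]
        r = np.corrcoef(weights, phen["ctq_total"])[0, 1]
        assert r > 0.999999

    def test_jittered_effect_attenuates_to_predicted_correlation(self, small_atlas):
        # slope 0.1, jitter sd chosen for population correlation ~0.3:
        # r = s / sqrt(s^2 + j^2) -> j = s * sqrt(1/r^2 - 1)
        slope, target_r = 0.1, 0.3
        jitter = slope * np.sqrt(1 / target_r**2 - 1)
        phen = make_phenotypes(n_subjects=206, seed=4)
        base = make_ground_truth_ec(small_atlas, seed=2)
        dmn = small_atlas.parcels_in("DMN")
        edge = (int(dmn[0]), int(dmn[1]))
        model = GroundTruthModel(
            base_ec=base, effect_edges=(edge,), effect_sizes=np.array([slope]),
            edge_noise_sd=jitter, atlas=small_atlas, seed=9,
        )
        ecs = make_subject_ecs(model, phen)
        weights = [ec[edge] for ec in ecs]
        r = np.corrcoef(weights, phen["ctq_total"])[0, 1]
        assert abs(r - target_r) < 0.1

    def test_cross_network_effect_edge_rejected(self, small_atlas):
        base = make_ground_truth_ec(small_atlas, seed=2)
        with pytest.raises(ConfigError, match="crosses networks"):
            GroundTruthModel(
                base_ec=base, effect_edges=((0, 27),), effect_sizes=np.array([0.1]),
                edge_noise_sd=0.0, atlas=small_atlas, seed=0,
            )

    def test_planted_model_effects_stay_inside_network(self, small_atlas):
        model = planted_network_model(small_atlas, network="FPN", n_effect_edges=6, seed=3)
        labels = np.asarray(small_atlas.labels, dtype=object)
        for t, s in model.effect_edges:
            assert labels[t] == labels[s] == "FPN"
        # alternating signs: both directions represented
        assert (model.effect_sizes > 0).any() and (model.effect_sizes < 0).any()


class TestSimulateBold:
    def test_output_shape_matches_config(self):
        atlas = make_atlas()
        ec = make_ground_truth_ec(atlas, seed=0)
        cfg = SimulationConfig(n_subjects=1, n_regions=100, n_volumes=230, seed=1)
        ts = simulate_bold(ec, cfg)
        assert ts.data.shape == (100, 230)

    def test_deterministic_given_seed(self, small_atlas):
        ec = make_ground_truth_ec(small_atlas, seed=0)
        cfg = SimulationConfig(n_subjects=1, n_regions=28, n_volumes=64, seed=42)
        a = simulate_bold(ec, cfg)
        b = simulate_bold(ec, cfg)
        assert np.array_equal(a.data, b.data)

    def test_uncoupled_regions_stay_uncorrelated(self):
        ec = np.diag([-0.5, -0.5])
        rs = []
        for seed in range(10):
            cfg = SimulationConfig(n_subjects=1, n_regions=2, n_volumes=460, seed=seed)
            ts = simulate_bold(ec, cfg)
            rs.append(np.corrcoef(ts.data)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_signals_are_band_limited_and_standardized(self, small_atlas):
        ec = make_ground_truth_ec(small_atlas, seed=3)
        cfg = SimulationConfig(n_subjects=1, n_regions=28, n_volumes=230, seed=5)
        ts = simulate_bold(ec, cfg)
        assert np.allclose(ts.data.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(ts.data.std(axis=1), 1, atol=1e-10)
        freqs = np.fft.rfftfreq(230, 2.0)
        power = np.abs(np.fft.rfft(ts.data, axis=1)) ** 2
        in_band = (freqs >= 0.01) & (freqs <= 0.1)
        assert power[:, in_band].sum() / power.sum() >= 0.9

    def test_unstable_matrix_rejected(self):
        cfg = SimulationConfig(n_subjects=1, n_regions=2, n_volumes=64, seed=0)
        with pytest.raises(StabilityError):
            simulate_bold(np.array([[0.1, 0.0], [0.0, -0.5]]), cfg)

    def test_run_shorter_than_hrf_rejected(self):
        cfg = SimulationConfig(n_subjects=1, n_regions=2, n_volumes=10, seed=0)
        with pytest.raises(ConfigError):
            simulate_bold(np.diag([-0.5, -0.5]), cfg)

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(band=(0.01, 0.3))  # above Nyquist at TR 2 s
        with pytest.raises(ConfigError):
            SimulationConfig(integration_step=3.0)
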