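"""Generator ground truth: templates, label dynamics, EEG synthesis,
forward model and cohorts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mstates as ms
from mstates.simulate import _equicorrelation, _pairing_correlation


class TestTemplates:
    def test_orthogonal_request_gives_exactly_orthogonal_maps(self, small_montage):
        T = ms.generate_templates(2, small_montage, max_abs_corr=0.0, seed=0)
        assert np.allclose(T.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(T @ T.T, np.eye(2), atol=1e-10)

    def test_deterministic_given_seed(self, montage):
        a = ms.generate_templates(4, montage, 0.5, seed=1)
        b = ms.generate_templates(4, montage, 0.5, seed=1)
        assert np.array_equal(a, b)

    def test_pairwise_correlation_bounded(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        corr = np.abs(T @ T.T)
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.5
        assert np.allclose(np.linalg.norm(T, axis=1), 1)

    def test_infeasible_bound_raises(self, small_montage):
        with pytest.raises(RuntimeError):
            # 3 maps with pairwise |corr| <= 0.01 in a 3-dim zero-mean
            # subspace is (near) impossible by random search
            ms.generate_templates(3, small_montage, 0.01, seed=0, max_tries=5)


class TestLabelSequence:
    def test_single_state_is_constant(self):
        lab = ms.generate_label_sequence(1, 100, 250.0, 100.0, seed=0)
        assert np.array_equal(lab, np.zeros(100, dtype=int))

    def test_zero_length_request(self):
        assert ms.generate_label_sequence(2, 0, 250.0, 100.0, seed=0).size == 0

    def test_empirical_mean_duration_matches_request(self):
        lab = ms.generate_label_sequence(2, 250_000, 250.0, 100.0, seed=7)
        changes = np.flatnonzero(np.diff(lab)) + 1
        seg_lens = np.diff(np.concatenate(([0], changes, [lab.size])))
        mean_ms = 1000.0 * seg_lens.mean() / 250.0
        assert abs(mean_ms - 100.0) / 100.0 < 0.05

    def test_deterministic_alternation_matrix(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        lab = ms.generate_label_sequence(
            2, 5000, 250.0, 20.0, transition_matrix=P, seed=3
        )
        changes = np.flatnonzero(np.diff(lab))
        states_at_segments = lab[np.concatenate(([0], changes + 1))]
        assert np.all(np.diff(states_at_segments) != 0)

    def test_too_short_mean_raises(self):
        with pytest.raises(ValueError):
            ms.generate_label_sequence(2, 100, 250.0, 1.0, seed=0)

    @given(st.integers(0, 1000))
    def test_segment_floor_respected(self, seed):
        lab = ms.generate_label_sequence(
            3, 2000, 250.0, 60.0, seed=seed, min_samples=10
        )
        changes = np.flatnonzero(np.diff(lab)) + 1
        seg_lens = np.diff(np.concatenate(([0], changes, [lab.size])))
        # all but the truncated final segment respect the floor
        assert np.all(seg_lens[:-1] >= 10)
        assert lab.min() >= 0 and lab.max() < 3


class TestGenerateEEG:
    def test_noiseless_maps_match_templates(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        lab = ms.generate_label_sequence(4, 2500, 250.0, 100.0, seed=2)
        rec, truth = ms.generate_eeg(T, lab, 250.0, snr=np.inf, seed=0, montage=montage)
        a = truth.envelope
        active = np.abs(a) > 1e-9
        X = rec.data[:, active]
        corr = np.abs(
            np.einsum("ct,tc->t", X / np.linalg.norm(X, axis=0), T[lab[active]])
        )
        assert np.all(corr > 1 - 1e-9)

    def test_average_reference_exact_when_noiseless(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        lab = ms.generate_label_sequence(4, 1000, 250.0, 100.0, seed=2)
        rec, _ = ms.generate_eeg(T, lab, 250.0, snr=np.inf, seed=0, montage=montage)
        assert np.allclose(rec.data.mean(axis=0), 0, atol=1e-12)

    def test_polarity_of_envelope_is_invisible_to_backfit(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        lab = ms.generate_label_sequence(4, 2500, 250.0, 100.0, seed=2)
        rec, _ = ms.generate_eeg(T, lab, 250.0, snr=np.inf, seed=0, montage=montage)
        flipped = rec.copy(data=-rec.data)
        seg_a = ms.backfit(T, rec)
        seg_b = ms.backfit(T, flipped)
        assert np.array_equal(seg_a.labels, seg_b.labels)

    def test_bit_identical_given_seed(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        lab = ms.generate_label_sequence(4, 1000, 250.0, 100.0, seed=2)
        r1, _ = ms.generate_eeg(T, lab, 250.0, snr=4.0, seed=9, montage=montage)
        r2, _ = ms.generate_eeg(T, lab, 250.0, snr=4.0, seed=9, montage=montage)
        assert np.array_equal(r1.data, r2.data)

    def test_snr_is_the_amplitude_rms_ratio(self, montage):
        T = ms.generate_templates(4, montage, 0.5, seed=1)
        lab = ms.generate_label_sequence(4, 50_000, 250.0, 100.0, seed=2)
        clean, _ = ms.generate_eeg(T, lab, 250.0, snr=np.inf, seed=5, montage=montage)
        noisy, _ = ms.generate_eeg(T, lab, 250.0, snr=4.0, seed=5, montage=montage)
        noise = noisy.data - clean.data
        ratio = np.sqrt(np.mean(clean.data**2)) / np.sqrt(np.mean(noise**2))
        assert abs(ratio - 4.0) / 4.0 < 0.02

    def test_invalid_snr_rejected(self, montage):
        T = ms.generate_templates(2, montage, 0.5, seed=1)
        with pytest.raises(ValueError):
            ms.generate_eeg(T, np.zeros(10, int), 250.0, snr=0.0, montage=montage)


class TestForwardModel:
    def test_partition_covers_all_sources(self, montage):
        lf, parc = ms.generate_forward_model(48, montage, 6, seed=0)
        assert lf.gain.shape == (19, 48)
        sizes = np.bincount(parc.region_of_source, minlength=6)
        assert sizes.sum() == 48 and sizes.min() >= 1
        assert np.allclose(np.linalg.norm(lf.gain, axis=0), 1)

    def test_identity_hook(self, montage):
        lf, parc = ms.generate_forward_model(19, montage, 19, identity=True)
        assert np.array_equal(lf.gain, np.eye(19))
        with pytest.raises(ValueError):
            ms.generate_forward_model(5, montage, 3, identity=True)

    def test_geometry_reproducible(self, montage):
        a, pa = ms.generate_forward_model(30, montage, 5, seed=3)
        b, pb = ms.generate_forward_model(30, montage, 5, seed=3)
        assert np.array_equal(a.gain, b.gain)
        assert np.array_equal(pa.region_of_source, pb.region_of_source)


class TestConnectedSources:
    def test_planted_correlation_in_latents(self, montage):
        lf, parc = ms.generate_forward_model(19, montage, 19, identity=True)
        corr = np.eye(19)
        corr[0, 1] = corr[1, 0] = 0.8
        lab = np.zeros(100_000, dtype=int)
        _, truth = ms.generate_connected_sources(
            lf, parc, {0: corr}, lab, 250.0, snr=np.inf, seed=5
        )
        emp = np.corrcoef(truth.region_latent)[0, 1]
        assert abs(emp - 0.8) < 0.05

    def test_identity_target_gives_uncorrelated_regions(self, montage):
        lf, parc = ms.generate_forward_model(19, montage, 19, identity=True)
        lab = np.zeros(50_000, dtype=int)
        _, truth = ms.generate_connected_sources(
            lf, parc, {0: np.eye(19)}, lab, 250.0, snr=np.inf, seed=1
        )
        emp = np.corrcoef(truth.region_latent)
        np.fill_diagonal(emp, 0)
        assert np.abs(emp).max() < 0.05

    def test_non_psd_target_rejected(self, montage):
        lf, parc = ms.generate_forward_model(19, montage, 19, identity=True)
        bad = np.eye(19)
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError):
            ms.generate_connected_sources(
                lf, parc, {0: bad}, np.zeros(100, int), 250.0, seed=0
            )

    def test_deterministic(self, montage):
        lf, parc = ms.generate_forward_model(30, montage, 5, seed=0)
        corr = _pairing_correlation(5, 0, 0.6)
        lab = np.zeros(1000, dtype=int)
        r1, _ = ms.generate_connected_sources(lf, parc, {0: corr}, lab, 250.0, snr=4, seed=2)
        r2, _ = ms.generate_connected_sources(lf, parc, {0: corr}, lab, 250.0, snr=4, seed=2)
        assert np.array_equal(r1.data, r2.data)


class TestCorrelationTargets:
    def test_equicorrelation_is_psd_and_unit_diagonal(self):
        corr = _equicorrelation(6, 0.6)
        assert np.allclose(np.diag(corr), 1)
        assert np.linalg.eigvalsh(corr).min() > -1e-12

    def test_pairing_targets_rotate_by_state(self):
        a = _pairing_correlation(6, 0, 0.7)
        b = _pairing_correlation(6, 1, 0.7)
        assert not np.array_equal(a, b)
        for corr in (a, b):
            assert np.linalg.eigvalsh(corr).min() > -1e-12
            assert (np.abs(np.triu(corr, 1)) > 0).sum() == 3


class TestCohort:
    def test_sizes_and_distinct_seeds(self):
        cfg = ms.SimulationConfig(
            seed=0, n_group_a=3, n_group_b=4, record_length=4.0
        )
        cohort = ms.generate_cohort(cfg)
        assert len(cohort.groups["A"]) == 3 and len(cohort.groups["B"]) == 4
        seeds = [s.seed for g in cohort.groups.values() for s in g]
        assert len(set(seeds)) == 7

    def test_bit_identical_rerun(self):
        cfg = ms.SimulationConfig(seed=5, n_group_a=2, n_group_b=2, record_length=3.0)
        c1 = ms.generate_cohort(cfg)
        c2 = ms.generate_cohort(cfg)
        for g in ("A", "B"):
            for s1, s2 in zip(c1.groups[g], c2.groups[g]):
                assert np.array_equal(s1.recording.data, s2.recording.data)

    def test_subjects_unchanged_when_cohort_grows(self):
        small = ms.generate_cohort(
            ms.SimulationConfig(seed=5, n_group_a=2, n_group_b=1, record_length=3.0)
        )
        large = ms.generate_cohort(
            ms.SimulationConfig(seed=5, n_group_a=3, n_group_b=1, record_length=3.0)
        )
        for s1, s2 in zip(small.groups["A"], large.groups["A"]):
            assert np.array_equal(s1.recording.data, s2.recording.data)

    def test_group_b_duration_multiplier_lands_in_truth(self):
        cfg = ms.SimulationConfig(
            seed=1,
            n_group_a=1,
            n_group_b=1,
            record_length=3.0,
            duration_multipliers=(1.2, 1.0, 1.0, 1.0),
        )
        cohort = ms.generate_cohort(cfg)
        assert cohort.groups["B"][0].truth.mean_durations[0] == pytest.approx(120.0)
        assert cohort.groups["A"][0].truth.mean_durations[0] == pytest.approx(100.0)

    def test_manifest_is_json_serialisable(self):
        import json

        cfg = ms.SimulationConfig(seed=0, n_group_a=1, n_group_b=1, record_length=2.0)
        manifest = ms.generate_cohort(cfg).manifest()
        json.dumps(manifest)
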