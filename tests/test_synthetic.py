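"""Synthetic BOLD generator: impulse statistics, HRF shape, forward model,
noise contracts and phantom construction."""

import numpy as np
import pytest

from zfrfc import (
    GaussianBlob,
    HRFModel,
    ImpulseTrain,
    NoiseSpec,
    PhantomComponent,
    PhantomSpec,
    TimeCourse,
    apply_noise,
    canonical_hrf,
    generate_impulse_train,
    generate_phantom,
    generate_subjects,
    stimulus_function,
    synthesize_bold,
)


class TestImpulseTrain:
    def test_bernoulli_mean_count(self):
        # E[count] = n*p = 150*0.07 = 10.5; Monte-Carlo mean within 3 SE
        n, p, reps = 150, 0.07, 2000
        counts = [len(generate_impulse_train(n, p, seed=s)) for s in range(reps)]
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(np.mean(counts) - n * p) < 3 * se

    def test_vanishing_probability_gives_empty_train(self):
        assert len(generate_impulse_train(100, 1e-12, seed=0)) == 0

    def test_fixed_seed_reproducible(self):
        a = generate_impulse_train(150, 0.07, seed=42)
        b = generate_impulse_train(150, 0.07, seed=42)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    @pytest.mark.parametrize("length,prob", [(0, 0.1), (100, 0.0), (100, 1.0), (100, -1)])
    def test_invalid_parameters_rejected(self, length, prob):
        with pytest.raises(ValueError):
            generate_impulse_train(length, prob)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ImpulseTrain(length=10, onsets=[3, 3])
        with pytest.raises(ValueError):
            ImpulseTrain(length=10, onsets=[5, 12])
        with pytest.raises(ValueError):
            ImpulseTrain(length=10, onsets=[5], amplitudes=[-1.0])


class TestCanonicalHRF:
    def test_peak_time_near_six_seconds(self):
        # dense sampling of the closed-form difference of gammas
        k = canonical_hrf(HRFModel(tr=0.1))
        t_peak = np.argmax(k) * 0.1
        assert 4.5 <= t_peak <= 6.0

    def test_unit_peak(self):
        for tr in (0.1, 1.0, 2.0):
            assert canonical_hrf(HRFModel(tr=tr)).max() == pytest.approx(1.0)

    def test_tail_below_five_percent_of_peak(self):
        k = canonical_hrf(HRFModel(tr=0.1))
        t = np.arange(len(k)) * 0.1
        assert np.all(np.abs(k[t > 25]) < 0.05)

    def test_kernel_length(self):
        assert len(canonical_hrf(HRFModel(tr=2.0, duration=32.0))) == 17

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            HRFModel(tr=-1)
        with pytest.raises(ValueError):
            HRFModel(peak_delay=0)
        with pytest.raises(ValueError):
            HRFModel(tr=2.0, duration=1.0)


class TestSynthesize:
    def test_single_impulse_reproduces_kernel(self, kernel_tr2):
        imp = ImpulseTrain(length=100, onsets=[0])
        tc = synthesize_bold(imp, kernel_tr2, tr=2.0)
        np.testing.assert_allclose(tc.values[: len(kernel_tr2)], kernel_tr2)
        np.testing.assert_allclose(tc.values[len(kernel_tr2) :], 0)

    def test_superposition_to_machine_precision(self, kernel_tr2):
        a = ImpulseTrain(length=120, onsets=[10], amplitudes=[2.0])
        b = ImpulseTrain(length=120, onsets=[40], amplitudes=[0.5])
        both = ImpulseTrain(length=120, onsets=[10, 40], amplitudes=[2.0, 0.5])
        lhs = synthesize_bold(both, kernel_tr2, tr=2.0).values
        rhs = (
            synthesize_bold(a, kernel_tr2, tr=2.0).values
            + synthesize_bold(b, kernel_tr2, tr=2.0).values
        )
        np.testing.assert_array_equal(lhs, rhs)

    def test_gaussian_noise_variance(self, kernel_tr2):
        imp = ImpulseTrain(length=400, onsets=[50, 150, 250])
        clean = synthesize_bold(imp, kernel_tr2, tr=2.0).values
        noisy = synthesize_bold(
            imp,
            kernel_tr2,
            NoiseSpec(kind="white_gaussian", sigma=0.1, seed=7),
            tr=2.0,
        ).values
        assert 0.007 <= np.var(noisy - clean) <= 0.013

    def test_gaussian_mean_preserved(self, kernel_tr2, rng):
        imp = ImpulseTrain(length=400, onsets=[100])
        clean = synthesize_bold(imp, kernel_tr2, tr=2.0).values
        noisy = synthesize_bold(
            imp, kernel_tr2, NoiseSpec(kind="white_gaussian", sigma=0.3), tr=2.0, rng=rng
        ).values
        n = clean.size
        assert abs(noisy.mean() - clean.mean()) < 3 * 0.3 / np.sqrt(n)

    def test_fixed_seed_bit_identical(self, kernel_tr2):
        imp = ImpulseTrain(length=200, onsets=[30, 90])
        spec = NoiseSpec(kind="white_gaussian", sigma=0.2, seed=11)
        a = synthesize_bold(imp, kernel_tr2, spec, tr=2.0).values
        b = synthesize_bold(imp, kernel_tr2, spec, tr=2.0).values
        np.testing.assert_array_equal(a, b)

    def test_empty_kernel_rejected(self):
        with pytest.raises(ValueError):
            synthesize_bold(ImpulseTrain(length=10, onsets=[2]), np.array([]))

    def test_rician_output_nonnegative(self, kernel_tr2, rng):
        imp = ImpulseTrain(length=200, onsets=[20, 80, 140])
        clean = synthesize_bold(imp, kernel_tr2, tr=2.0).values
        for cnr in (0.65, 1.0):
            noisy = apply_noise(clean, NoiseSpec(kind="rician", cnr=cnr), rng=rng)
            assert np.all(noisy >= 0)

    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(kind="white_gaussian", sigma=0.0)
        with pytest.raises(ValueError):
            NoiseSpec(kind="rician", cnr=-0.5)
        with pytest.raises(ValueError):
            NoiseSpec(kind="pink", sigma=1.0)


class TestStimulusFunction:
    def test_empty_stimuli_all_zero(self, kernel_tr2):
        tc = stimulus_function(ImpulseTrain(length=50, onsets=[]), kernel_tr2)
        np.testing.assert_array_equal(tc.values, 0)

    def test_single_stimulus_copies_kernel(self, kernel_tr2):
        tc = stimulus_function(ImpulseTrain(length=80, onsets=[20]), kernel_tr2)
        np.testing.assert_allclose(tc.values[20 : 20 + len(kernel_tr2)], kernel_tr2)

    def test_spaced_stimuli_give_one_peak_each(self, kernel_tr2):
        onsets = np.arange(5) * 25 + 5  # spacing > kernel length (17)
        tc = stimulus_function(ImpulseTrain(length=150, onsets=onsets), kernel_tr2)
        v = tc.values
        peaks = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > 0.5)) + 1
        assert len(peaks) == len(onsets)


class TestPhantom:
    @pytest.fixture()
    def small_spec(self):
        comps = (
            PhantomComponent(blob=GaussianBlob(center=(10.0, 10.0), sigma=4.0)),
            PhantomComponent(blob=GaussianBlob(center=(30.0, 30.0), sigma=4.0)),
        )
        return PhantomSpec(grid=(40, 40), n_timepoints=150, components=comps, noise=NoiseSpec(kind="none"))

    def test_in_blob_voxel_correlates_perfectly(self, small_spec):
        ph = generate_phantom(small_spec, seed=3)
        tc = ph.data[10, 10] - ph.spec.baseline
        comp = ph.component_timecourses[0].values
        r = np.corrcoef(tc, comp)[0, 1]
        assert r == pytest.approx(1.0)

    def test_far_voxel_is_baseline(self, small_spec):
        ph = generate_phantom(small_spec, seed=3)
        # a corner voxel ~40 voxels from both blob centres: weights ~exp(-50)
        np.testing.assert_allclose(ph.data[39, 0], ph.spec.baseline, atol=1e-8)

    def test_rician_phantom_nonnegative_and_reproducible(self):
        spec = PhantomSpec(grid=(20, 20), n_timepoints=150)
        a = generate_phantom(spec, seed=5)
        b = generate_phantom(spec, seed=5)
        assert np.all(a.data >= 0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_masks_and_trains_returned_per_component(self, small_spec):
        ph = generate_phantom(small_spec, seed=3)
        assert len(ph.masks) == len(ph.trains) == 2
        assert ph.masks[0][10, 10] and not ph.masks[0][30, 30]
        assert ph.label_map.max() == 2

    def test_empty_component_support_rejected(self):
        comp = PhantomComponent(weights=np.zeros((20, 20)), event_prob=0.07)
        spec = PhantomSpec(grid=(20, 20), n_timepoints=150, components=(comp,))
        with pytest.raises(ValueError):
            generate_phantom(spec, seed=0)

    def test_subject_jitter_moves_components(self):
        spec = PhantomSpec(grid=(40, 40), n_timepoints=150,
                           components=(PhantomComponent(blob=GaussianBlob(center=(20.0, 20.0), sigma=5.0)),))
        subs = generate_subjects(spec, 3, seed=9)
        centers = [np.mean(np.argwhere(s.masks[0]), axis=0) for s in subs]
        assert len({tuple(np.round(c, 1)) for c in centers}) > 1
        cnrs = [s.spec.noise.cnr for s in subs]
        assert all(0.65 <= c <= 1.0 for c in cnrs)
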