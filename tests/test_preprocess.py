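"""Preprocessing contracts: channel selection, zero-phase band-pass, ICA
source recovery, artifact flagging/removal and epoch extraction."""

import numpy as np
import pytest
from scipy import signal

from mi_csp import (
    ConfigurationError,
    EpochingError,
    EstimationError,
    Recording,
    SimConfig,
    amari_index,
    butter_bandpass,
    extract_epochs,
    fit_ica,
    flag_artifact_components,
    remove_components,
    select_channels,
    simulate_mi_recording,
)


def _tone(freq, fs=100.0, seconds=30.0, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    return Recording(np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)), fs=fs)


class TestChannelSelection:
    def test_all_is_identity(self, sim20):
        _, rec, _ = sim20
        out = select_channels(rec, "all")
        assert np.array_equal(out.data, rec.data)
        assert out.channel_labels == rec.channel_labels

    def test_explicit_list_preserves_original_order(self, sim20):
        _, rec, _ = sim20
        want = [rec.channel_labels[4], rec.channel_labels[1]]  # scrambled request
        out = select_channels(rec, "explicit", keep=want)
        assert out.channel_labels == [rec.channel_labels[1], rec.channel_labels[4]]
        assert out.n_channels == 2

    def test_drop_peripheral_reduces_by_annotated_count(self, sim20):
        _, rec, _ = sim20
        peripheral = rec.channel_labels[:3]
        out = select_channels(rec, "drop-peripheral", peripheral=peripheral)
        assert out.n_channels == rec.n_channels - 3

    def test_unknown_label_and_empty_result_raise(self, sim20):
        _, rec, _ = sim20
        with pytest.raises(ConfigurationError):
            select_channels(rec, "explicit", keep=["nope"])
        with pytest.raises(ConfigurationError):
            select_channels(rec, "drop-peripheral", peripheral=rec.channel_labels)


class TestBandpass:
    def test_dc_input_is_suppressed(self):
        rec = Recording(np.full((2, 2000), 5.0), fs=100.0)
        out = butter_bandpass(rec)
        interior = out.data[:, 200:-200]
        assert np.abs(interior).max() < 1e-6 * 5.0

    @pytest.mark.parametrize("freq", [11.0, 30.0])
    def test_tone_gain_matches_designed_frequency_response(self, freq):
        # oracle: |H(f)|^2 of the designed SOS (applied forward-backward)
        sos = signal.butter(4, [8, 15], btype="bandpass", fs=100.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=100.0)
        expected = np.abs(h[0]) ** 2
        out = butter_bandpass(_tone(freq))
        measured = np.abs(out.data[0, 500:-500]).max()
        assert measured == pytest.approx(expected, rel=0.02, abs=1e-4)
        if freq == 11.0:
            assert abs(measured - 1.0) < 0.05  # pass-band: within 5% of unity
        else:
            assert measured < 0.1  # stop-band

    def test_zero_phase_no_lag(self):
        # cross-correlation between an in-band tone and its filtered version
        # peaks at lag zero
        rec = _tone(11.0, n_ch=1)
        out = butter_bandpass(rec)
        x = rec.data[0, 500:-500]
        y = out.data[0, 500:-500]
        corr = signal.correlate(y, x, mode="full")
        assert np.argmax(corr) == len(x) - 1

    def test_band_outside_nyquist_raises(self, sim20):
        _, rec, _ = sim20
        with pytest.raises(ConfigurationError):
            butter_bandpass(rec, 8, 60)
        with pytest.raises(ConfigurationError):
            butter_bandpass(rec, 15, 8)


class TestIca:
    def test_recovers_laplace_mixture_amari_below_0_05(self):
        rng = np.random.default_rng(3)
        S = rng.laplace(0, 1, (3, 5000))
        A = rng.standard_normal((3, 3))
        model = fit_ica(Recording(A @ S, fs=100.0), seed=0)
        assert amari_index(model.unmixing, A) < 0.05
        assert model.n_iter > 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        S = rng.laplace(0, 1, (3, 3000))
        A = rng.standard_normal((3, 3))
        rec = Recording(A @ S, fs=100.0)
        m1 = fit_ica(rec, seed=4)
        m2 = fit_ica(rec, seed=4)
        assert np.array_equal(m1.unmixing, m2.unmixing)
        assert np.array_equal(m1.sources, m2.sources)

    def test_rank_deficient_input_raises(self):
        s = np.random.default_rng(0).laplace(0, 1, 1000)
        rec = Recording(np.vstack([s, s]), fs=100.0)  # rank 1
        with pytest.raises(EstimationError, match="rank"):
            fit_ica(rec, n_components=2, seed=0)

    def test_gaussian_sources_converge_with_unit_variance(self):
        # recovery is not expected (Gaussians are not identifiable), but the
        # fit must converge and honor the unit-variance source convention
        S = np.random.default_rng(103).standard_normal((3, 3000))
        A = np.random.default_rng(203).standard_normal((3, 3))
        model = fit_ica(Recording(A @ S, fs=100.0), seed=0)
        assert np.allclose(model.sources.var(axis=1), 1.0, atol=1e-8)

    def test_mixing_times_unmixing_is_identity_on_retained_subspace(self, sim20):
        _, rec, _ = sim20
        model = fit_ica(butter_bandpass(rec), seed=0)
        assert np.allclose(model.mixing @ model.unmixing, np.eye(rec.n_channels), atol=1e-6)


@pytest.fixture(scope="module")
def fitted(sim20):
    """ICA fitted on the raw (unfiltered) simulation, where the blink
    retains its full low-frequency energy."""
    _, rec, truth = sim20
    model = fit_ica(rec, seed=0)
    return rec, truth, model


class TestArtifactRejection:
    def _blink_component(self, truth, model):
        blink = truth.sources[truth.artifact_source_idx[0]]
        corr = [
            abs(np.corrcoef(s, blink)[0, 1]) for s in model.sources
        ]
        return int(np.argmax(corr))

    def test_planted_blink_flagged_and_only_it(self, fitted):
        rec, truth, model = fitted
        flagged = flag_artifact_components(model, rec, frontal_labels=["Fp1", "Fp2"])
        assert flagged == {self._blink_component(truth, model)}

    def test_no_artifacts_no_flags(self):
        config = SimConfig(n_channels=6, n_trials_per_class=10, artifact_rate=0.0, seed=9)
        rec, _ = simulate_mi_recording(config)
        model = fit_ica(rec, seed=0)
        flagged = flag_artifact_components(model, rec, frontal_labels=["Fp1", "Fp2"])
        assert flagged == set()

    def test_vacuous_thresholds_flag_nothing(self, fitted):
        rec, _, model = fitted
        assert flag_artifact_components(
            model, rec, frontal_labels=["Fp1"], kurtosis_thresh=np.inf, corr_thresh=1.0
        ) == set()

    def test_corr_criterion_without_frontal_channels_raises(self, fitted):
        rec, _, model = fitted
        with pytest.raises(ConfigurationError):
            flag_artifact_components(model, rec, frontal_labels=["XX"], corr_thresh=0.8)

    def test_removing_nothing_reproduces_input(self, fitted):
        rec, _, model = fitted
        out = remove_components(model, rec, set())
        assert np.allclose(out.data, rec.data, rtol=1e-8, atol=1e-8 * rec.data.std())

    def test_removing_everything_leaves_channel_means(self, fitted):
        rec, _, model = fitted
        out = remove_components(model, rec, set(range(model.n_components)))
        assert np.allclose(out.data, rec.data.mean(axis=1, keepdims=True))

    def test_blink_removal_cleans_frontal_channel_but_keeps_neural_sources(self, fitted):
        rec, truth, model = fitted
        flagged = flag_artifact_components(model, rec, frontal_labels=["Fp1", "Fp2"])
        clean = remove_components(model, rec, flagged)
        blink = truth.sources[truth.artifact_source_idx[0]]
        assert abs(np.corrcoef(clean.data[0], blink)[0, 1]) < 0.1
        for k in truth.disc_source_idx:  # neural content must survive
            s = truth.sources[k]
            before = max(abs(np.corrcoef(rec.data[i], s)[0, 1]) for i in range(rec.n_channels))
            after = max(abs(np.corrcoef(clean.data[i], s)[0, 1]) for i in range(rec.n_channels))
            assert after > before * 0.95

    def test_removal_is_an_idempotent_projector(self, fitted):
        rec, _, model = fitted
        once = remove_components(model, rec, {0, 2})
        model2 = type(model)(
            unmixing=model.unmixing,
            mixing=model.mixing,
            sources=model.unmixing @ (once.data - model.mean[:, None]),
            mean=model.mean,
            n_iter=model.n_iter,
            tol=model.tol,
        )
        twice = remove_components(model2, once, {0, 2})
        assert np.allclose(twice.data, once.data, atol=1e-8 * rec.data.std())

    def test_out_of_range_component_raises(self, fitted):
        rec, _, model = fitted
        with pytest.raises(IndexError):
            remove_components(model, rec, {model.n_components})


class TestEpoching:
    def test_default_window_yields_200_samples(self, sim20):
        _, rec, _ = sim20
        epochs = extract_epochs(rec, window=(0.5, 2.5))
        assert epochs.n_samples == 200
        assert epochs.n_trials == len(rec.markers)

    def test_full_window_yields_400_samples(self, sim20):
        _, rec, _ = sim20
        assert extract_epochs(rec, window=(0.0, 4.0)).n_samples == 400

    def test_window_sample_indices_are_half_open(self):
        data = np.arange(1000, dtype=float)[None, :]
        rec = Recording(data, fs=100.0, markers=[(100, 1), (500, 2)])
        epochs = extract_epochs(rec, window=(0.5, 2.5))
        assert epochs.data[0, 0, 0] == 150.0  # onset + 0.5 s
        assert epochs.data[0, 0, -1] == 349.0  # last sample before onset + 2.5 s

    def test_marker_at_recording_end_raises_naming_the_trial(self):
        rec = Recording(np.zeros((2, 500)), fs=100.0, markers=[(0, 1), (499, 2)])
        with pytest.raises(EpochingError, match="trial 1"):
            extract_epochs(rec, window=(0.5, 2.5))
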