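"""Feature backends, record-level combination, spectral baseline, surrogate."""

import itertools

import numpy as np
import pytest

from ieegsearch.errors import ContractError, ParameterError
from ieegsearch.featex import (
    SPECTRAL_BANDS,
    combine_record_features,
    extract_channel_features,
    load_backend,
    make_backend,
    record_features,
    save_backend,
    spectral_power_features,
)
from ieegsearch.records import FS, IEEGRecord
from ieegsearch.spectro import render_channel
from ieegsearch.synthio import make_event_waveform

from conftest import small_patient


@pytest.fixture(scope="module")
def backend():
    return make_backend("random_init", seed=3)


@pytest.fixture(scope="module")
def channel_image():
    return render_channel(make_event_waveform("baseline", None, 30, 1))


class TestBackends:
    def test_map_contract(self, backend, channel_image):
        fmap = extract_channel_features(channel_image, backend)
        assert fmap.shape == backend.map_shape
        assert fmap.ndim == 3  # C x H x W

    def test_deterministic_per_weights(self, backend, channel_image):
        a = extract_channel_features(channel_image, backend)
        b = extract_channel_features(channel_image, backend)
        np.testing.assert_array_equal(a, b)
        # same seed rebuilds the same backend
        again = make_backend("random_init", seed=3)
        c = extract_channel_features(channel_image, again)
        np.testing.assert_array_equal(a, c)

    def test_truncated_backend_shallower_and_larger(self, backend, channel_image):
        trunc = make_backend("random_init", seed=3, truncate_layers=1)
        fmap = extract_channel_features(channel_image, trunc)
        c_full, h_full, _ = backend.map_shape
        c_tr, h_tr, _ = fmap.shape
        assert c_tr < c_full and h_tr > h_full

    def test_wrong_image_shape_rejected(self, backend):
        with pytest.raises(ParameterError):
            extract_channel_features(np.zeros((100, 100, 3)), backend)

    def test_generic_pretrained_requires_weights(self):
        with pytest.raises(ParameterError):
            make_backend("generic_pretrained")

    def test_save_load_round_trip(self, backend, channel_image, tmp_path):
        path = tmp_path / "b.npz"
        save_backend(backend, path)
        loaded = load_backend(path)
        np.testing.assert_array_equal(
            extract_channel_features(channel_image, backend),
            extract_channel_features(channel_image, loaded),
        )


class TestCombineRecordFeatures:
    def test_reference_contract_length(self):
        """Four 2048 x 7 x 7 maps concatenate to a 401,408-long vector."""
        maps = [np.zeros((2048, 7, 7))] * 4
        assert combine_record_features(maps).size == 401_408

    def test_zero_block_for_missing_channel(self):
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal((8, 3, 3)) for _ in range(4)]
        maps[1] = None
        vec = combine_record_features(maps, {1})
        block = 8 * 3 * 3
        assert np.all(vec[block : 2 * block] == 0.0)
        np.testing.assert_array_equal(vec[:block], maps[0].ravel())
        np.testing.assert_array_equal(vec[2 * block : 3 * block], maps[2].ravel())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        maps = [rng.standard_normal((4, 2, 2)) for _ in range(4)]
        vec = combine_record_features(maps)
        order = (2, 0, 3, 1)
        pvec = combine_record_features([maps[i] for i in order])
        block = 16
        for dst, src in enumerate(order):
            np.testing.assert_array_equal(
                pvec[dst * block : (dst + 1) * block],
                vec[src * block : (src + 1) * block],
            )

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ContractError):
            combine_record_features([np.zeros((8, 3, 3)), np.zeros((4, 3, 3)),
                                     None, None], {2, 3})

    def test_zero_fill_conservation(self, backend):
        """Dropping a channel changes only that channel's block."""
        rec = small_patient("P", n=1)[0]
        full = record_features(rec, backend)
        dropped = rec.with_channels(
            [rec.channels[0], rec.channels[1], None, rec.channels[3]]
        )
        part = record_features(dropped, backend)
        block = backend.feature_length
        assert np.all(part[2 * block : 3 * block] == 0.0)
        mask = np.ones(part.size, dtype=bool)
        mask[2 * block : 3 * block] = False
        np.testing.assert_array_equal(part[mask], full[mask])


class TestSpectralPowerFeatures:
    def test_length_and_nonnegative(self):
        rec = small_patient("P", n=1)[0]
        vec = spectral_power_features(rec)
        assert vec.shape == (28,)
        assert np.all(vec >= 0.0)

    def test_sinusoid_band_dominance(self):
        """A 10 Hz sinusoid puts >=100x more power in 8-12 than 25-50 Hz."""
        t = np.arange(90 * FS) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = IEEGRecord("P", "r", [x, None, None, None], 90.0, 0.0, "scheduled")
        vec = spectral_power_features(rec)
        assert vec[2] >= 100 * vec[4]  # bands: index 2 = 8-12, 4 = 25-50

    def test_disjoint_band_additivity(self):
        rec = small_patient("P", n=1)[0]
        vec = spectral_power_features(rec)
        for ch in range(4):
            sub = vec[ch * 7 : ch * 7 + 6].sum()
            total = vec[ch * 7 + 6]
            assert sub == pytest.approx(total, rel=0.01)

    def test_missing_channel_zero_slots(self):
        rec = small_patient("P", n=1, missing=(2,))[0]
        vec = spectral_power_features(rec)
        assert np.all(vec[7:14] == 0.0)
        assert np.all(vec[:7] > 0.0)


class TestSurrogateClassifier:
    def test_holdout_accuracy(self, surrogate_backend):
        """Separable-by-construction classes: held-out accuracy >= 0.9."""
        _, accuracy = surrogate_backend
        assert accuracy >= 0.9

    def test_frozen_features_deterministic(self, surrogate_backend, channel_image):
        backend, _ = surrogate_backend
        a = extract_channel_features(channel_image, backend)
        b = extract_channel_features(channel_image, backend)
        np.testing.assert_array_equal(a, b)

    def test_within_class_distances_smaller(self, surrogate_backend):
        backend, _ = surrogate_backend
        seiz_imgs = [
            render_channel(
                make_event_waveform(
                    "seizure_hf_band",
                    {"band_hz": (55.0, 70.0), "ictal_duration_s": 15.0},
                    30, 5000 + i,
                )
            )
            for i in range(6)
        ]
        base_imgs = [
            render_channel(make_event_waveform("baseline", None, 30, 6000 + i))
            for i in range(6)
        ]
        fs = [extract_channel_features(im, backend).ravel() for im in seiz_imgs]
        fb = [extract_channel_features(im, backend).ravel() for im in base_imgs]
        d_within = np.mean(
            [np.linalg.norm(a - b) for a, b in itertools.combinations(fs, 2)]
        )
        d_between = np.mean([np.linalg.norm(a - b) for a in fs for b in fb])
        assert d_within < d_between

    def test_single_class_rejected(self):
        from ieegsearch.featex import SurrogateTrainConfig, train_surrogate_classifier

        imgs = [np.zeros((224, 224, 3))] * 4
        with pytest.raises(ParameterError):
            train_surrogate_classifier(imgs, [1, 1, 1, 1], SurrogateTrainConfig())
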