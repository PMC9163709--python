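"""Synthetic patient generator: determinism, labels, signal content, I/O."""

import numpy as np
import pytest
from scipy.signal import argrelmax, periodogram

from ieegsearch.errors import DataError, FormatError, ParameterError
from ieegsearch.records import FS, IEEGRecord
from ieegsearch.synthio import (
    MorphologyTemplate,
    SynthPatientSpec,
    make_event_waveform,
    make_patient,
    read_edf,
    read_fixture,
    write_edf,
    write_fixture,
)

from conftest import small_patient


def band_power(x, lo, hi):
    freqs, pxx = periodogram(x, fs=FS)
    return pxx[(freqs >= lo) & (freqs < hi)].sum()


class TestMakePatient:
    def test_counts_and_labels(self):
        records = small_patient("P", n=100, n_templates=3)
        assert len(records) == 300
        labels = {r.ground_truth_template for r in records}
        assert len(labels) == 3
        assert all(r.ground_truth_template is not None for r in records)

    def test_seeded_determinism_bit_identical(self):
        a = small_patient("P", seed=7, n=3)
        b = small_patient("P", seed=7, n=3)
        for ra, rb in zip(a, b):
            for ca, cb in zip(ra.channels, rb.channels):
                assert (ca is None) == (cb is None)
                if ca is not None:
                    np.testing.assert_array_equal(ca, cb)

    def test_different_seeds_differ(self):
        a = small_patient("P", seed=7, n=1)
        b = small_patient("P", seed=8, n=1)
        assert not np.array_equal(a[0].channels[0], b[0].channels[0])

    def test_seizure_band_power_dominates_baseline(self):
        """50-75 Hz periodogram power on an involved channel is >=10x baseline."""
        tpls = [
            MorphologyTemplate("base", "baseline"),
            MorphologyTemplate(
                "sz", "seizure_hf_band",
                {"band_hz": (60.0, 75.0),
                 "involved_channels": (True, False, False, True)},
            ),
        ]
        spec = SynthPatientSpec("P", tpls, records_per_template=3, seed=5)
        records = make_patient(spec)
        base = [r for r in records if r.ground_truth_template == "base"]
        seiz = [r for r in records if r.ground_truth_template == "sz"]
        p_seiz = np.mean([band_power(r.channels[0], 50, 75) for r in seiz])
        p_base = np.mean([band_power(r.channels[0], 50, 75) for r in base])
        assert p_seiz >= 10 * p_base
        # uninvolved channel 2 stays at baseline level
        p_ch2 = np.mean([band_power(r.channels[1], 50, 75) for r in seiz])
        assert p_ch2 < 10 * p_base

    def test_missing_channels_absent(self):
        records = small_patient("P", missing=(3,), n=2)
        assert all(r.channels[2] is None for r in records)
        assert all(r.channels[0] is not None for r in records)

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ParameterError):
            MorphologyTemplate("bad", "seizure_hf_band", {"band_hz": (60.0, 130.0)})

    def test_invalid_duration_rejected(self):
        with pytest.raises(ParameterError):
            SynthPatientSpec(
                "P", [MorphologyTemplate("t", "baseline")], record_duration_s=10
            )


class TestMakeEventWaveform:
    def test_sample_count(self):
        assert make_event_waveform("baseline", None, 90, 0).size == 22_500

    def test_stim_pulse_count_by_slew_oracle(self):
        """A pulse every 5 s over 90 s gives exactly 18 detectable onsets."""
        x = make_event_waveform("stim_artifact", {"pulse_period_s": 5.0}, 90, 7)
        d = np.abs(np.diff(x))
        onsets = np.flatnonzero(d > 500.0)
        groups = np.split(onsets, np.flatnonzero(np.diff(onsets) > FS // 2) + 1)
        assert len(groups) == 18

    def test_harmonic_stack_peaks(self):
        """f0=10 Hz with 3 harmonics: ictal-window peaks at 10/20/30/40 Hz."""
        x = make_event_waveform(
            "seizure_harmonics", {"f0_hz": 10.0, "n_harmonics": 3}, 90, 3
        )
        ictal = x[30 * FS : 60 * FS]
        freqs, pxx = periodogram(ictal, fs=FS)
        peaks = argrelmax(pxx, order=5)[0]
        top4 = freqs[peaks][np.argsort(pxx[peaks])[::-1][:4]]
        assert sorted(np.round(top4, 1)) == [10.0, 20.0, 30.0, 40.0]

    def test_saturation_clips_at_rails(self):
        x = make_event_waveform("saturation", {"saturation_limit_uv": 400.0}, 30, 1)
        assert x.max() <= 400.0 and x.min() >= -400.0
        assert np.mean(np.abs(x) >= 399.9) > 0.1  # rails actually reached

    def test_unknown_event_class_rejected(self):
        with pytest.raises(ParameterError):
            make_event_waveform("wiggles", None, 90, 0)


class TestLabelRecoverability:
    def test_spectral_nearest_centroid_recovers_templates(self):
        """Well-separated templates are >=90% recoverable from 28 features.

        Nearest-centroid in spectral-power feature space (trained on half
        of each template's records) recovers the planted labels, which
        guarantees downstream clustering has structure to find.
        """
        from ieegsearch.featex import spectral_power_features

        records = small_patient("P", n=20, n_templates=4, seed=11)
        feats = np.stack([np.log1p(spectral_power_features(r)) for r in records])
        labels = np.array([r.ground_truth_template for r in records])
        train = np.zeros(len(records), dtype=bool)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            train[idx[: len(idx) // 2]] = True
        cents = {
            lab: feats[train & (labels == lab)].mean(axis=0)
            for lab in np.unique(labels)
        }
        names = list(cents)
        pred = [
            names[int(np.argmin([np.linalg.norm(f - cents[c]) for c in names]))]
            for f in feats[~train]
        ]
        acc = np.mean(np.array(pred) == labels[~train])
        assert acc >= 0.9


class TestFixtureIO:
    def test_round_trip_lossless(self, tmp_path):
        records = small_patient("P", n=5, missing=(2,))
        path = tmp_path / "p.h5"
        write_fixture(records, path)
        back = read_fixture(path)
        assert len(back) == len(records)
        by_id = {r.record_id: r for r in back}
        for rec in records:
            got = by_id[rec.record_id]
            assert got.patient_id == rec.patient_id
            assert got.duration_s == rec.duration_s
            assert got.trigger_offset_s == rec.trigger_offset_s
            assert got.trigger_type == rec.trigger_type
            assert got.ground_truth_template == rec.ground_truth_template
            for ca, cb in zip(rec.channels, got.channels):
                assert (ca is None) == (cb is None)
                if ca is not None:
                    np.testing.assert_array_equal(ca, cb)

    def test_missing_field_raises_format_error(self, tmp_path):
        import h5py

        records = small_patient("P", n=1)
        path = tmp_path / "p.h5"
        write_fixture(records, path)
        with h5py.File(path, "a") as f:
            del f[records[0].record_id].attrs["trigger_offset_s"]
        with pytest.raises(FormatError) as exc:
            read_fixture(path)
        assert exc.value.field == "trigger_offset_s"


class TestEDF:
    def test_round_trip_preserves_samples_and_gap(self, tmp_path):
        rec = small_patient("Pat X", n=1, missing=(3,))[0]
        path = tmp_path / "r.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert back.duration_s == rec.duration_s
        assert back.channels[2] is None
        for i in (0, 1, 3):
            assert back.channels[i].size == rec.channels[i].size
            # 16-bit quantization: values agree to the digitization step
            step = (rec.channels[i].max() - rec.channels[i].min()) / 65535 + 2 / 65535
            assert np.max(np.abs(back.channels[i] - rec.channels[i])) < 4 * step + 0.1

    def test_mne_reads_our_edf(self, tmp_path):
        """Cross-check the in-package writer against an independent reader."""
        mne = pytest.importorskip("mne")

        rec = small_patient("PatY", n=1)[0]
        path = tmp_path / "r.edf"
        write_edf(rec, path)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()  # volts
        assert data.shape == (4, rec.n_samples)
        for i in range(4):
            r = np.corrcoef(data[i], rec.channels[i])[0, 1]
            assert r > 0.999
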