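"""EDF I/O, hypnogram parsing, stage mapping, resampling, and epoching."""

import numpy as np
import pytest

from sleepfusion.psg_io import (
    ChannelNotFoundError,
    EdfParseError,
    EpochSet,
    HypnogramAnnotation,
    HypnogramValidationError,
    Recording,
    SignalChannel,
    StageLabel,
    map_stage,
    read_edf,
    read_hypnogram,
    resample_channel,
    segment_epochs,
    write_edf,
    write_hypnogram,
)
from sleepfusion.synthetic_data import write_fixture_edf


def _recording(duration_s=90.0, rate=100.0, n_channels=4):
    rng = np.random.default_rng(0)
    channels = [
        SignalChannel(name, rate, rng.normal(scale=50.0, size=int(duration_s * rate)))
        for name in ["EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal", "EMG submental"][:n_channels]
    ]
    return Recording("test", channels)


class TestEdfRoundTrip:
    def test_four_channel_round_trip(self, tmp_path):
        rec = _recording(duration_s=10.0)
        path = write_edf(tmp_path / "sig.edf", rec.channels)
        back = read_edf(path)
        assert back.channel_names == rec.channel_names
        for orig, re_read in zip(rec.channels, back.channels):
            assert re_read.sampling_rate == orig.sampling_rate
            span = orig.samples.max() - orig.samples.min()
            assert np.max(np.abs(re_read.samples - orig.samples)) <= 1.01 * span / 65534

    def test_requested_channel_subset_and_order(self, tmp_path):
        path = write_edf(tmp_path / "sig.edf", _recording(10.0).channels)
        rec = read_edf(path, ["EOG horizontal", "EEG Fpz-Cz"])
        assert rec.channel_names == ["EOG horizontal", "EEG Fpz-Cz"]

    def test_missing_channel_is_named(self, tmp_path):
        path = write_edf(tmp_path / "sig.edf", _recording(10.0, n_channels=2).channels)
        with pytest.raises(ChannelNotFoundError, match="EMG submental"):
            read_edf(path, ["EMG submental"])

    def test_per_channel_native_rates_preserved(self, tmp_path):
        """EEG at 100 Hz and EMG at 1 Hz keep their rates through the file."""
        eeg = SignalChannel("EEG Fpz-Cz", 100.0, np.random.default_rng(1).normal(size=1000))
        emg = SignalChannel("EMG submental", 1.0, np.arange(10.0))
        path = write_edf(tmp_path / "mixed.edf", [eeg, emg])
        rec = read_edf(path)
        assert [c.sampling_rate for c in rec.channels] == [100.0, 1.0]
        assert len(rec.channel("EMG submental").samples) == 10

    def test_corrupt_file_error_names_the_file(self, tmp_path):
        bad = tmp_path / "corrupt.edf"
        bad.write_bytes(b"this is not an EDF file at all")
        with pytest.raises(EdfParseError, match="corrupt.edf"):
            read_edf(bad)

    def test_truncated_header_rejected(self, tmp_path):
        bad = tmp_path / "short.edf"
        bad.write_bytes(b"0".ljust(100))
        with pytest.raises(EdfParseError):
            read_edf(bad)


class TestHypnogram:
    def test_edfplus_round_trip_preserves_entries(self, tmp_path):
        anns = [
            HypnogramAnnotation(0.0, 30.0, "Sleep stage W"),
            HypnogramAnnotation(30.0, 60.0, "Sleep stage 2"),
            HypnogramAnnotation(90.0, 30.0, "Sleep stage R"),
        ]
        path = write_hypnogram(tmp_path / "hyp.edf", anns)
        back = read_hypnogram(path)
        assert len(back) == 3
        assert [a.raw_label for a in back] == [a.raw_label for a in anns]
        assert [a.onset_s for a in back] == [0.0, 30.0, 90.0]

    def test_plain_text_table(self, tmp_path):
        path = tmp_path / "hyp.tsv"
        path.write_text("# onset\tduration\tlabel\n0\t30\tSleep stage W\n30\t30\tSleep stage 1\n")
        back = read_hypnogram(path)
        assert len(back) == 2
        assert back[1].raw_label == "Sleep stage 1"

    def test_zero_duration_rejected(self):
        with pytest.raises(HypnogramValidationError):
            HypnogramAnnotation(0.0, 0.0, "Sleep stage W")

    def test_overlap_rejected(self, tmp_path):
        path = tmp_path / "hyp.tsv"
        path.write_text("0\t40\tSleep stage W\n30\t30\tSleep stage 1\n")
        with pytest.raises(HypnogramValidationError, match="overlap"):
            read_hypnogram(path)


class TestMapStage:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Sleep stage W", StageLabel.W),
            ("Sleep stage 1", StageLabel.S1),
            ("Sleep stage 2", StageLabel.S2),
            ("Sleep stage 3", StageLabel.S3),
            ("Sleep stage 4", StageLabel.S3),  # R&K stages 3+4 merge
            ("Sleep stage R", StageLabel.REM),
            ("Movement time", StageLabel.EXCLUDED),
            ("Sleep stage ?", StageLabel.EXCLUDED),
        ],
    )
    def test_dialect_mapping(self, raw, expected):
        assert map_stage(raw) is expected

    def test_unknown_label_lists_alias_table(self):
        with pytest.raises(KeyError, match="Sleep stage W"):
            map_stage("Stage N17")

    def test_exactly_five_retained_codes(self):
        codes = {int(v) for v in StageLabel if v is not StageLabel.EXCLUDED}
        assert codes == {0, 1, 2, 3, 4}


class TestResample:
    def test_zero_order_hold_upsampling(self):
        ch = SignalChannel("EMG submental", 1.0, np.arange(30.0))
        up = resample_channel(ch, 100.0)
        assert len(up.samples) == 3000
        assert np.array_equal(up.samples, np.repeat(np.arange(30.0), 100))

    def test_identity_when_rate_matches(self):
        ch = SignalChannel("EEG Fpz-Cz", 100.0, np.random.default_rng(0).normal(size=500))
        same = resample_channel(ch, 100.0)
        assert np.array_equal(same.samples, ch.samples)

    def test_block_mean_downsampling(self):
        x = np.random.default_rng(3).normal(size=3000)
        down = resample_channel(SignalChannel("EEG Fpz-Cz", 100.0, x), 1.0)
        assert len(down.samples) == 30
        expected = x.reshape(30, 100).mean(axis=1)
        assert np.allclose(down.samples, expected)

    def test_non_integer_ratio_rejected(self):
        ch = SignalChannel("EEG Fpz-Cz", 100.0, np.zeros(300))
        with pytest.raises(ValueError, match="integer"):
            resample_channel(ch, 33.0)


class TestSegmentEpochs:
    def test_three_annotations_three_epochs(self):
        rec = _recording(duration_s=90.0)
        anns = [
            HypnogramAnnotation(0.0, 30.0, "Sleep stage W"),
            HypnogramAnnotation(30.0, 30.0, "Sleep stage 2"),
            HypnogramAnnotation(60.0, 30.0, "Sleep stage R"),
        ]
        es = segment_epochs(rec, anns)
        assert es.signals.shape == (3, 3000, 4)
        assert list(es.labels) == [0, 2, 4]
        # sample fidelity: epoch k is exactly the k-th 30 s slice
        assert np.array_equal(es.signals[1, :, 0], rec.channels[0].samples[3000:6000])

    def test_movement_epochs_absent(self):
        rec = _recording(duration_s=90.0)
        anns = [
            HypnogramAnnotation(0.0, 30.0, "Sleep stage W"),
            HypnogramAnnotation(30.0, 30.0, "Movement time"),
            HypnogramAnnotation(60.0, 30.0, "Sleep stage 2"),
        ]
        es = segment_epochs(rec, anns)
        assert es.n_epochs == 2
        assert list(es.labels) == [0, 2]

    def test_long_annotation_tiles_into_epochs(self):
        rec = _recording(duration_s=120.0)
        es = segment_epochs(rec, [HypnogramAnnotation(0.0, 120.0, "Sleep stage 2")])
        assert es.n_epochs == 4
        assert set(es.labels) == {2}

    def test_trailing_partial_epoch_dropped(self):
        rec = _recording(duration_s=95.0)
        es = segment_epochs(rec, [HypnogramAnnotation(0.0, 95.0, "Sleep stage 3")])
        assert es.n_epochs == 3  # floor(95/30), 5 s tail discarded

    def test_rate_mismatch_rejected(self):
        channels = [
            SignalChannel("EEG Fpz-Cz", 100.0, np.zeros(3000)),
            SignalChannel("EMG submental", 1.0, np.zeros(30)),
        ]
        with pytest.raises(ValueError, match="sampling rate"):
            segment_epochs(
                Recording("r", channels), [HypnogramAnnotation(0.0, 30.0, "Sleep stage W")]
            )

    def test_empty_retained_set_rejected(self):
        rec = _recording(duration_s=30.0)
        with pytest.raises(ValueError, match="no retained"):
            segment_epochs(rec, [HypnogramAnnotation(0.0, 30.0, "Movement time")])

    def test_sample_conservation_bound(self):
        """n_epochs * epoch_samples never exceeds available samples."""
        rec = _recording(duration_s=100.0)
        es = segment_epochs(rec, [HypnogramAnnotation(0.0, 100.0, "Sleep stage 1")])
        assert es.n_epochs * es.epoch_samples <= len(rec.channels[0].samples)


class TestEpochSetContainer:
    def test_cache_round_trip(self, tmp_path, small_epochset):
        path = small_epochset.save(tmp_path / "cache")
        back = EpochSet.load(tmp_path / "cache")
        assert np.array_equal(back.signals, small_epochset.signals)
        assert np.array_equal(back.labels, small_epochset.labels)
        assert back.channel_names == small_epochset.channel_names

    def test_excluded_labels_never_stored(self):
        with pytest.raises(ValueError, match="0..4"):
            EpochSet(
                np.zeros((1, 3000, 1)), np.array([-1]), ["EEG Fpz-Cz"], 30.0, 100.0
            )


class TestFixtureRoundTrip:
    def test_full_pipeline_round_trip(self, tmp_path, small_epochset):
        """write -> read -> resample -> segment reproduces labels and samples."""
        sig, hyp = write_fixture_edf(
            small_epochset, tmp_path / "f-PSG.edf", tmp_path / "f-Hypnogram.edf"
        )
        rec = read_edf(sig)
        assert rec.channel("EMG submental").sampling_rate == 1.0
        rec = Recording(rec.record_id, [resample_channel(c, 100.0) for c in rec.channels])
        es = segment_epochs(rec, read_hypnogram(hyp))
        assert np.array_equal(es.labels, small_epochset.labels)
        for j, name in enumerate(small_epochset.channel_names):
            span = (
                small_epochset.signals[:, :, j].max()
                - small_epochset.signals[:, :, j].min()
            )
            err = np.max(np.abs(es.signals[:, :, j] - small_epochset.signals[:, :, j]))
            assert err <= 1.02 * span / 65534, name


class TestExternalReaderAgreement:
    def test_mne_reads_our_edf_identically(self, tmp_path, small_epochset):
        """Cross-check the in-repo EDF writer/reader against MNE's reader."""
        mne = pytest.importorskip("mne")
        sig, _ = write_fixture_edf(
            small_epochset, tmp_path / "x-PSG.edf", tmp_path / "x-Hypnogram.edf"
        )
        ours = read_edf(sig).channel("EEG Fpz-Cz").samples
        raw = mne.io.read_raw_edf(sig, verbose="error")
        theirs = raw.get_data(picks=["EEG Fpz-Cz"])[0] * 1e6  # volts -> uV
        assert np.max(np.abs(ours - theirs)) < 1e-9
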