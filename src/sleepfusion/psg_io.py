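"""Polysomnography I/O: EDF signals, EDF+/text hypnograms, stage mapping, epoching.

Sleep recordings arrive as EDF/EDF+ files holding several channels at
heterogeneous native rates (EEG/EOG at 100 Hz, submental EMG at 1 Hz) with a
companion hypnogram file annotating sleep stages on a 30 s grid in
Rechtschaffen-Kales (R&K) vocabulary. This module reads both, maps R&K labels
onto the five retained classes (W, S1, S2, S3, REM; stages 3 and 4 merged,
movement/unknown excluded), and cuts the recording into fixed-length labelled
epochs — the ``EpochSet`` tensor every downstream stage consumes.

The EDF reader/writer here is intentionally small: it handles the standard
16-bit EDF layout plus the "EDF Annotations" time-stamped annotation lists
(TALs) of EDF+, and it preserves each channel's native sampling rate, which a
single-rate Raw container cannot represent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SignalChannel",
    "Recording",
    "HypnogramAnnotation",
    "StageLabel",
    "EpochSet",
    "STAGE_ALIASES",
    "DEFAULT_EXCLUDED_FILES",
    "ChannelNotFoundError",
    "EdfParseError",
    "HypnogramValidationError",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "map_stage",
    "segment_epochs",
    "resample_channel",
]


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from the recording."""


class EdfParseError(ValueError):
    """The file is not a readable EDF/EDF+ file (names the offending path)."""


class HypnogramValidationError(ValueError):
    """Hypnogram annotations are overlapping, unordered, or degenerate."""


class StageLabel(IntEnum):
    """Five-class sleep stage codes; EXCLUDED marks dropped epochs.

    R&K stages 3 and 4 are merged into S3; movement time and unknown
    annotations map to EXCLUDED, which never appears inside an ``EpochSet``.
    """

    W = 0
    S1 = 1
    S2 = 2
    S3 = 3
    REM = 4
    EXCLUDED = -1


#: Sleep-EDF dialect stage strings -> class codes. Short single-character
#: forms are accepted as well so plain-text hypnogram tables stay terse.
STAGE_ALIASES: dict[str, StageLabel] = {
    "Sleep stage W": StageLabel.W,
    "Sleep stage 1": StageLabel.S1,
    "Sleep stage 2": StageLabel.S2,
    "Sleep stage 3": StageLabel.S3,
    "Sleep stage 4": StageLabel.S3,
    "Sleep stage R": StageLabel.REM,
    "Sleep stage ?": StageLabel.EXCLUDED,
    "Movement time": StageLabel.EXCLUDED,
    "W": StageLabel.W,
    "1": StageLabel.S1,
    "2": StageLabel.S2,
    "3": StageLabel.S3,
    "4": StageLabel.S3,
    "R": StageLabel.REM,
    "?": StageLabel.EXCLUDED,
    "M": StageLabel.EXCLUDED,
}

#: Recording/hypnogram pair known to be unreadable in the public Sleep-EDF
#: expanded release; skipped by the pipeline orchestration by default.
DEFAULT_EXCLUDED_FILES: tuple[str, ...] = (
    "SC4362F0-PSG.edf",
    "SC4362FC-Hypnogram.edf",
)


@dataclass
class SignalChannel:
    """One channel of a PSG recording at its native sampling rate."""

    name: str
    sampling_rate: float
    samples: np.ndarray
    unit: str = "uV"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class Recording:
    """A multi-channel PSG recording; channels may differ in sampling rate."""

    record_id: str
    channels: list[SignalChannel]

    @property
    def duration_s(self) -> float:
        return max((c.duration_s for c in self.channels), default=0.0)

    def channel(self, name: str) -> SignalChannel:
        for c in self.channels:
            if c.name == name:
                return c
        raise ChannelNotFoundError(
            f"channel {name!r} not in recording {self.record_id!r}; "
            f"available: {[c.name for c in self.channels]}"
        )

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]


@dataclass(frozen=True)
class HypnogramAnnotation:
    """One stage annotation: onset and duration in seconds, raw R&K label."""

    onset_s: float
    duration_s: float
    raw_label: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise HypnogramValidationError(f"negative onset {self.onset_s}")
        if self.duration_s <= 0:
            raise HypnogramValidationError(
                f"annotation at {self.onset_s}s has non-positive duration {self.duration_s}"
            )


@dataclass
class EpochSet:
    """Segmented, labelled epochs: the currency between pipeline stages.

    ``signals`` has shape (n_epochs, epoch_samples, n_channels) with
    epoch_samples = epoch_len_s * sampling_rate; ``labels`` holds the
    five-class codes 0..4 (EXCLUDED epochs are dropped before construction).
    """

    signals: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    epoch_len_s: float = 30.0
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError(f"signals must be 3-D, got shape {self.signals.shape}")
        n, s, c = self.signals.shape
        if len(self.labels) != n:
            raise ValueError(f"{n} epochs but {len(self.labels)} labels")
        if c != len(self.channel_names):
            raise ValueError(f"{c} signal channels but {len(self.channel_names)} names")
        expected = int(round(self.epoch_len_s * self.sampling_rate))
        if s != expected:
            raise ValueError(
                f"epoch_samples {s} != epoch_len_s*rate = {expected}"
            )
        if len(self.labels) and not np.all((self.labels >= 0) & (self.labels <= 4)):
            raise ValueError("labels must lie in 0..4 (EXCLUDED epochs must be dropped)")

    @property
    def n_epochs(self) -> int:
        return self.signals.shape[0]

    @property
    def epoch_samples(self) -> int:
        return self.signals.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in epoch set; available: {self.channel_names}"
            ) from None

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = [self.channel_index(n) for n in names]
        return EpochSet(
            self.signals[:, :, idx],
            self.labels.copy(),
            list(names),
            self.epoch_len_s,
            self.sampling_rate,
        )

    def subset(self, indices: np.ndarray) -> "EpochSet":
        indices = np.asarray(indices)
        return EpochSet(
            self.signals[indices],
            self.labels[indices],
            list(self.channel_names),
            self.epoch_len_s,
            self.sampling_rate,
        )

    # --- cached binary container -------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Write signals+labels to ``<path>.npz`` with a JSON metadata sidecar."""
        path = Path(path)
        npz = path.with_suffix(".npz")
        np.savez(npz, signals=self.signals, labels=self.labels)
        meta = {
            "channel_names": self.channel_names,
            "epoch_len_s": self.epoch_len_s,
            "sampling_rate": self.sampling_rate,
            "n_epochs": int(self.n_epochs),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return npz

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            signals, labels = data["signals"], data["labels"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            signals,
            labels,
            meta["channel_names"],
            meta["epoch_len_s"],
            meta["sampling_rate"],
        )


# =============================================================================
# EDF reading / writing
# =============================================================================

_ANNOTATION_LABEL = "EDF Annotations"


def _ascii(field_bytes: bytes) -> str:
    return field_bytes.decode("ascii", errors="replace").strip()


def _read_header(fh, path: Path) -> dict:
    fixed = fh.read(256)
    if len(fixed) < 256:
        raise EdfParseError(f"{path}: truncated EDF header ({len(fixed)} bytes)")
    version = _ascii(fixed[0:8])
    if version != "0":
        raise EdfParseError(f"{path}: not an EDF file (version field {version!r})")
    try:
        n_records = int(_ascii(fixed[236:244]))
        record_dur = float(_ascii(fixed[244:252]))
        ns = int(_ascii(fixed[252:256]))
    except ValueError as exc:
        raise EdfParseError(f"{path}: malformed EDF header: {exc}") from exc
    if ns <= 0:
        raise EdfParseError(f"{path}: header declares {ns} signals")
    per_sig = fh.read(256 * ns)
    if len(per_sig) < 256 * ns:
        raise EdfParseError(f"{path}: truncated signal headers")

    def fields(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            _ascii(per_sig[base + i * width : base + (i + 1) * width]) for i in range(ns)
        ]

    labels = fields(0, 16)
    # layout: label(16) transducer(80) dim(8) pmin(8) pmax(8) dmin(8) dmax(8)
    #         prefilter(80) nsamples(8) reserved(32)  -- each block ns-contiguous
    dims = [_ascii(per_sig[96 * ns + i * 8 : 96 * ns + (i + 1) * 8]) for i in range(ns)]
    pmin = [float(x) for x in (_ascii(per_sig[104 * ns + i * 8 : 104 * ns + (i + 1) * 8]) for i in range(ns))]
    pmax = [float(x) for x in (_ascii(per_sig[112 * ns + i * 8 : 112 * ns + (i + 1) * 8]) for i in range(ns))]
    dmin = [int(float(x)) for x in (_ascii(per_sig[120 * ns + i * 8 : 120 * ns + (i + 1) * 8]) for i in range(ns))]
    dmax = [int(float(x)) for x in (_ascii(per_sig[128 * ns + i * 8 : 128 * ns + (i + 1) * 8]) for i in range(ns))]
    nsamp = [int(_ascii(per_sig[216 * ns + i * 8 : 216 * ns + (i + 1) * 8])) for i in range(ns)]
    return {
        "n_records": n_records,
        "record_dur": record_dur,
        "ns": ns,
        "labels": labels,
        "dims": dims,
        "pmin": pmin,
        "pmax": pmax,
        "dmin": dmin,
        "dmax": dmax,
        "nsamp": nsamp,
    }


def read_edf(path: str | Path, wanted_channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Each channel keeps its native sampling rate (samples-per-record divided by
    record duration); no resampling or rate unification is performed.

    Parameters
    ----------
    path
        EDF or EDF+ file.
    wanted_channels
        Channel labels to extract, in the order requested. ``None`` reads all
        ordinary signal channels (annotation channels are always skipped).

    Raises
    ------
    ChannelNotFoundError
        If a requested label is missing.
    EdfParseError
        If the file is not parseable EDF (the message names the file,
        mirroring the practice of excluding corrupt recordings explicitly).
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            hdr = _read_header(fh, path)
            raw = fh.read()
    except OSError as exc:
        raise EdfParseError(f"{path}: unreadable ({exc})") from exc

    ns, nsamp = hdr["ns"], hdr["nsamp"]
    rec_len = sum(nsamp)  # int16 samples per data record
    n_records = hdr["n_records"]
    if n_records < 0:  # unknown record count: infer from file size
        n_records = len(raw) // (2 * rec_len)
    if len(raw) < 2 * rec_len * n_records:
        raise EdfParseError(f"{path}: data section truncated")
    data = np.frombuffer(raw[: 2 * rec_len * n_records], dtype="<i2").reshape(
        n_records, rec_len
    )

    channels: list[SignalChannel] = []
    col = np.cumsum([0] + nsamp)
    for i in range(ns):
        if hdr["labels"][i] == _ANNOTATION_LABEL:
            continue
        dig = data[:, col[i] : col[i + 1]].ravel().astype(np.float64)
        dmin, dmax = hdr["dmin"][i], hdr["dmax"][i]
        pmin, pmax = hdr["pmin"][i], hdr["pmax"][i]
        scale = (pmax - pmin) / (dmax - dmin) if dmax != dmin else 1.0
        phys = (dig - dmin) * scale + pmin
        rate = nsamp[i] / hdr["record_dur"]
        channels.append(
            SignalChannel(hdr["labels"][i], rate, phys, unit=hdr["dims"][i])
        )

    rec = Recording(path.stem, channels)
    if wanted_channels is not None:
        rec = Recording(rec.record_id, [rec.channel(n) for n in wanted_channels])
    return rec


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _float8(value: float) -> str:
    """Shortest decimal form of value fitting the 8-char EDF header field."""
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def write_edf(
    path: str | Path,
    channels: Sequence[SignalChannel],
    record_dur: float = 1.0,
    physical_range: tuple[float, float] | None = None,
) -> Path:
    """Write channels to a 16-bit EDF file.

    Every channel must cover the same duration, which must be an integer
    multiple of ``record_dur`` and of each channel's sample period. Physical
    scaling defaults to each channel's observed extrema (slightly padded), so
    round-trip error is bounded by the 16-bit quantization step of that range.
    """
    path = Path(path)
    channels = list(channels)
    if not channels:
        raise ValueError("no channels to write")
    duration = channels[0].duration_s
    for c in channels:
        if abs(c.duration_s - duration) > 1e-9:
            raise ValueError("all channels must cover the same duration")
    n_records = int(round(duration / record_dur))
    if abs(n_records * record_dur - duration) > 1e-9 or n_records <= 0:
        raise ValueError(
            f"duration {duration}s is not a positive multiple of record_dur {record_dur}s"
        )

    nsamp, pmins, pmaxs, digitized = [], [], [], []
    for c in channels:
        per_rec = c.sampling_rate * record_dur
        if abs(per_rec - round(per_rec)) > 1e-9:
            raise ValueError(
                f"channel {c.name!r}: rate {c.sampling_rate} Hz does not yield an "
                f"integer sample count per {record_dur}s record"
            )
        nsamp.append(int(round(per_rec)))
        if physical_range is not None:
            pmin, pmax = physical_range
        else:
            lo, hi = float(np.min(c.samples)), float(np.max(c.samples))
            span = max(hi - lo, 1e-6)
            pmin, pmax = lo - 0.005 * span, hi + 0.005 * span
        # digitize against the values as actually stored in the 8-char
        # header fields, so reader-side rescaling is exact
        pmin = float(_float8(pmin))
        pmax = float(_float8(pmax))
        pmins.append(pmin)
        pmaxs.append(pmax)
        dig = np.round((c.samples - pmin) / (pmax - pmin) * 65534.0 - 32767.0)
        digitized.append(np.clip(dig, -32767, 32767).astype("<i2"))

    ns = len(channels)
    header = b"".join(
        [
            _fmt(0, 8),
            _fmt("X X X X", 80),
            _fmt("Startdate 01-JAN-2000 X X X", 80),
            _fmt("01.01.00", 8),
            _fmt("00.00.00", 8),
            _fmt(256 * (ns + 1), 8),
            _fmt("", 44),
            _fmt(n_records, 8),
            _fmt(record_dur if record_dur != int(record_dur) else int(record_dur), 8),
            _fmt(ns, 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(_fmt(c.name, 16) for c in channels),
            b"".join(_fmt("", 80) for _ in channels),
            b"".join(_fmt(c.unit, 8) for c in channels),
            b"".join(_fmt(_float8(p), 8) for p in pmins),
            b"".join(_fmt(_float8(p), 8) for p in pmaxs),
            b"".join(_fmt(-32767, 8) for _ in channels),
            b"".join(_fmt(32767, 8) for _ in channels),
            b"".join(_fmt("", 80) for _ in channels),
            b"".join(_fmt(n, 8) for n in nsamp),
            b"".join(_fmt("", 32) for _ in channels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            for i, dig in enumerate(digitized):
                fh.write(dig[r * nsamp[i] : (r + 1) * nsamp[i]].tobytes())
    return path


# =============================================================================
# Hypnograms
# =============================================================================


def _validate_annotations(anns: list[HypnogramAnnotation]) -> list[HypnogramAnnotation]:
    for prev, cur in zip(anns, anns[1:]):
        if cur.onset_s < prev.onset_s:
            raise HypnogramValidationError(
                f"annotations out of order at onset {cur.onset_s}s"
            )
        if cur.onset_s < prev.onset_s + prev.duration_s - 1e-9:
            raise HypnogramValidationError(
                f"annotation at {cur.onset_s}s overlaps previous "
                f"({prev.onset_s}s + {prev.duration_s}s)"
            )
    return anns


def _parse_tals(payload: bytes) -> list[HypnogramAnnotation]:
    anns: list[HypnogramAnnotation] = []
    for tal in payload.split(b"\x00"):
        if not tal:
            continue
        head, *texts = tal.split(b"\x14")
        head = head.decode("ascii", errors="replace")
        if "\x15" in head:
            onset_str, dur_str = head.split("\x15", 1)
        else:
            onset_str, dur_str = head, ""
        texts = [t.decode("utf-8", errors="replace") for t in texts if t]
        if not texts:
            continue  # timekeeping TAL
        onset = float(onset_str)
        dur = float(dur_str) if dur_str else 0.0
        for text in texts:
            anns.append(HypnogramAnnotation(onset, dur, text))
    return anns


def read_hypnogram(path: str | Path) -> list[HypnogramAnnotation]:
    """Read stage annotations from an EDF+ annotation file or a text table.

    EDF+ files are recognized by their header; anything else is parsed as a
    whitespace/comma-separated ``onset_s  duration_s  label`` table (lines
    starting with ``#`` ignored). Annotations are returned time-ordered and
    validated as non-overlapping.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head.strip() == b"0":  # EDF header
        with open(path, "rb") as fh:
            hdr = _read_header(fh, path)
            raw = fh.read()
        nsamp = hdr["nsamp"]
        rec_len = sum(nsamp)
        n_records = hdr["n_records"]
        if n_records < 0:
            n_records = len(raw) // (2 * rec_len)
        anns: list[HypnogramAnnotation] = []
        col = np.cumsum([0] + nsamp)
        for r in range(n_records):
            rec = raw[2 * rec_len * r : 2 * rec_len * (r + 1)]
            for i in range(hdr["ns"]):
                if hdr["labels"][i] != _ANNOTATION_LABEL:
                    continue
                anns.extend(_parse_tals(rec[2 * col[i] : 2 * col[i + 1]]))
        anns.sort(key=lambda a: a.onset_s)
        return _validate_annotations(anns)

    anns = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").split("\t") if p] if "\t" in line or "," in line else line.split(None, 2)
        if len(parts) < 3:
            raise HypnogramValidationError(f"{path}: malformed hypnogram line {line!r}")
        anns.append(HypnogramAnnotation(float(parts[0]), float(parts[1]), parts[2].strip()))
    anns.sort(key=lambda a: a.onset_s)
    return _validate_annotations(anns)


def write_hypnogram(
    path: str | Path, annotations: Sequence[HypnogramAnnotation]
) -> Path:
    """Write annotations as an EDF+ file with a single annotation channel."""
    path = Path(path)
    anns = _validate_annotations(sorted(annotations, key=lambda a: a.onset_s))
    total = max((a.onset_s + a.duration_s for a in anns), default=1.0)
    record_dur = max(total, 1.0)
    tals = b"+0\x14\x14\x00"  # timekeeping TAL for the single record
    for a in anns:
        onset = f"{a.onset_s:g}"
        if not onset.startswith("-"):
            onset = "+" + onset
        tals += f"{onset}\x15{a.duration_s:g}\x14{a.raw_label}\x14\x00".encode("utf-8")
    if len(tals) % 2:
        tals += b"\x00"
    nsamp = len(tals) // 2

    header = b"".join(
        [
            _fmt(0, 8),
            _fmt("X X X X", 80),
            _fmt("Startdate 01-JAN-2000 X X X", 80),
            _fmt("01.01.00", 8),
            _fmt("00.00.00", 8),
            _fmt(256 * 2, 8),
            _fmt("EDF+C", 44),
            _fmt(1, 8),
            _fmt(f"{record_dur:g}", 8),
            _fmt(1, 4),
        ]
    )
    sig_hdr = b"".join(
        [
            _fmt(_ANNOTATION_LABEL, 16),
            _fmt("", 80),
            _fmt("", 8),
            _fmt(-1, 8),
            _fmt(1, 8),
            _fmt(-32768, 8),
            _fmt(32767, 8),
            _fmt("", 80),
            _fmt(nsamp, 8),
            _fmt("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        fh.write(tals)
    return path


# =============================================================================
# Stage mapping and epoch segmentation
# =============================================================================


def map_stage(
    raw_label: str, aliases: dict[str, StageLabel] | None = None
) -> StageLabel:
    """Map an R&K stage string to the five-class code.

    W->0, stage 1->1, stage 2->2, stages 3 and 4->3 (merged slow-wave class),
    REM->4; movement time and unknown map to ``StageLabel.EXCLUDED``.

    Raises ``KeyError`` listing the alias table for unrecognized labels.
    """
    table = STAGE_ALIASES if aliases is None else aliases
    label = raw_label.strip()
    if label not in table:
        raise KeyError(
            f"unrecognized stage label {raw_label!r}; known labels: {sorted(table)}"
        )
    return table[label]


def resample_channel(channel: SignalChannel, target_rate: float) -> SignalChannel:
    """Resample by an integer factor: zero-order hold up, block mean down.

    Upsampling repeats each sample ``target/current`` times (zero-order hold),
    the natural reading of a slowly-sampled tonic signal such as 1 Hz EMG
    envelope; downsampling averages non-overlapping blocks. Non-integer rate
    ratios are rejected.
    """
    cur = channel.sampling_rate
    if abs(target_rate - cur) < 1e-12:
        return SignalChannel(channel.name, cur, channel.samples.copy(), channel.unit)
    if target_rate > cur:
        ratio = target_rate / cur
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"upsampling ratio {ratio} is not an integer ({cur} -> {target_rate} Hz)"
            )
        out = np.repeat(channel.samples, int(round(ratio)))
    else:
        ratio = cur / target_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"downsampling ratio {ratio} is not an integer ({cur} -> {target_rate} Hz)"
            )
        k = int(round(ratio))
        n = (len(channel.samples) // k) * k
        out = channel.samples[:n].reshape(-1, k).mean(axis=1)
    return SignalChannel(channel.name, target_rate, out, channel.unit)


def segment_epochs(
    recording: Recording,
    annotations: Sequence[HypnogramAnnotation],
    epoch_len_s: float = 30.0,
    aliases: dict[str, StageLabel] | None = None,
) -> EpochSet:
    """Cut a recording into fixed-length labelled epochs.

    Epoch windows are half-open ``[onset, onset + epoch_len_s)`` anchored at
    each annotation's onset; an annotation spanning k full epoch lengths is
    tiled into k consecutive epochs sharing its label. Epochs whose label maps
    to EXCLUDED, and trailing partial epochs (of an annotation or of the
    recording), are dropped.

    All channels must already share one sampling rate (see
    :func:`resample_channel`); a rate mismatch raises ``ValueError``, as does
    an empty retained set.
    """
    rates = {c.sampling_rate for c in recording.channels}
    if len(rates) != 1:
        raise ValueError(
            f"channels must share a sampling rate before segmentation; got {sorted(rates)}"
        )
    rate = rates.pop()
    samples_per_epoch = epoch_len_s * rate
    if abs(samples_per_epoch - round(samples_per_epoch)) > 1e-9:
        raise ValueError(
            f"epoch_len_s {epoch_len_s} * rate {rate} is not an integer sample count"
        )
    samples_per_epoch = int(round(samples_per_epoch))
    n_total = min(len(c.samples) for c in recording.channels)

    windows: list[tuple[int, int]] = []  # (start sample, label code)
    for ann in _validate_annotations(sorted(annotations, key=lambda a: a.onset_s)):
        code = map_stage(ann.raw_label, aliases)
        n_epochs_here = int(np.floor(ann.duration_s / epoch_len_s + 1e-9))
        if code is StageLabel.EXCLUDED:
            continue
        for k in range(n_epochs_here):
            start = (ann.onset_s + k * epoch_len_s) * rate
            if abs(start - round(start)) > 1e-6:
                raise ValueError(
                    f"annotation onset {ann.onset_s}s does not align to the sample grid"
                )
            start = int(round(start))
            if start + samples_per_epoch > n_total:
                break  # trailing partial epoch: drop
            windows.append((start, int(code)))

    if not windows:
        raise ValueError("no retained epochs after label mapping and windowing")

    n_ch = len(recording.channels)
    signals = np.empty((len(windows), samples_per_epoch, n_ch))
    labels = np.empty(len(windows), dtype=np.int64)
    for e, (start, code) in enumerate(windows):
        labels[e] = code
        for j, ch in enumerate(recording.channels):
            signals[e, :, j] = ch.samples[start : start + samples_per_epoch]
    return EpochSet(signals, labels, recording.channel_names, epoch_len_s, rate)
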