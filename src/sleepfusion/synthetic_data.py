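"""Synthetic PSG epochs with stage-dependent spectral structure.

Every pipeline stage is testable without downloading real recordings: this
module draws labelled 30 s, 100 Hz, four-channel epochs whose spectral
content caricatures the classical stage descriptions — wake rich in alpha
(8-13 Hz) and beta with high muscle tone and frequent eye movements; S1 with
attenuated alpha and emerging theta; S2 with sleep spindles (12-14 Hz
bursts) and K-complexes over a theta background; S3 dominated by
high-amplitude delta (0.5-4 Hz); REM with saw-tooth waves, large slow eye
deflections, and minimal muscle tone. Submental EMG is synthesized at 1 Hz
(a tonic activity envelope) and zero-order-held to the common rate,
mirroring how it is stored in the source recordings and exercising the
resampling path.

All amplitudes and noise levels are invented fixture numbers, not
measurements: they are chosen so that at "easy" separability the five
classes are distinguishable by spectral energy alone, which is what makes
scaled-down end-to-end training tests meaningful. None of this approaches
physiologically realistic EEG simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .psg_io import (
    EpochSet,
    HypnogramAnnotation,
    SignalChannel,
    StageLabel,
    resample_channel,
    write_edf,
    write_hypnogram,
)

__all__ = [
    "BandComponent",
    "ChannelRecipe",
    "StageSignalSpec",
    "SyntheticConfig",
    "CHANNEL_NAMES",
    "CODE_TO_DIALECT",
    "SLEEP_EDF20_TRAIN_COUNTS",
    "default_stage_specs",
    "generate_epochset",
    "write_fixture_edf",
]

CHANNEL_NAMES = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG horizontal", "EMG submental")

#: Stage code -> Sleep-EDF dialect annotation string (S3 written as the
#: R&K "Sleep stage 3"; the reader merges stages 3 and 4 anyway).
CODE_TO_DIALECT = {
    0: "Sleep stage W",
    1: "Sleep stage 1",
    2: "Sleep stage 2",
    3: "Sleep stage 3",
    4: "Sleep stage R",
}

#: Published per-stage training-epoch counts of the smaller public corpus,
#: usable as imbalance ratios for class-skew emulation.
SLEEP_EDF20_TRAIN_COUNTS = {0: 7042, 1: 2384, 2: 15129, 3: 4848, 4: 6559}

_NYQUIST = 50.0  # Hz at the 100 Hz common rate


@dataclass(frozen=True)
class BandComponent:
    """One sinusoidal component: frequency drawn uniformly in [low, high] Hz."""

    low: float
    high: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low <= self.high:
            raise ValueError(f"invalid band [{self.low}, {self.high}]")
        if self.high >= _NYQUIST:
            raise ValueError(f"band edge {self.high} Hz exceeds Nyquist ({_NYQUIST} Hz)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ChannelRecipe:
    """Per-channel generative recipe: bands plus transient events.

    Rates are expected event counts per 30 s epoch. ``tone_level`` is the
    mean of the 1 Hz tonic envelope used for the EMG channel.
    """

    bands: tuple[BandComponent, ...] = ()
    spindle_rate: float = 0.0  # 12-14 Hz bursts, ~1 s Gaussian envelope
    spindle_amplitude: float = 0.0
    kcomplex_rate: float = 0.0  # large biphasic transients
    kcomplex_amplitude: float = 0.0
    sawtooth_amplitude: float = 0.0  # 2-3 Hz saw-tooth train
    deflection_rate: float = 0.0  # slow EOG deflections
    deflection_amplitude: float = 0.0
    tone_level: float = 0.0


@dataclass(frozen=True)
class StageSignalSpec:
    """Recipes for all channels of one sleep stage, plus additive noise."""

    channels: Mapping[str, ChannelRecipe]
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic draw.

    ``epochs_per_class`` is either one count for all five stages or a
    per-code mapping (e.g. scaled published imbalance ratios). ``hard``
    separability multiplies every noise standard deviation by 6.
    """

    epochs_per_class: int | Mapping[int, int] = 100
    channels: tuple[str, ...] = CHANNEL_NAMES
    sampling_rate: float = 100.0
    epoch_len_s: float = 30.0
    seed: int = 0
    separability: str = "easy"

    def __post_init__(self) -> None:
        n = self.sampling_rate * self.epoch_len_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * epoch_len_s must be integral")
        if self.separability not in ("easy", "hard"):
            raise ValueError(f"separability must be easy|hard, got {self.separability!r}")

    def class_counts(self) -> dict[int, int]:
        if isinstance(self.epochs_per_class, Mapping):
            counts = {c: int(self.epochs_per_class.get(c, 0)) for c in range(5)}
        else:
            counts = {c: int(self.epochs_per_class) for c in range(5)}
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be non-negative")
        return counts

    @property
    def noise_scale(self) -> float:
        return 1.0 if self.separability == "easy" else 6.0


def default_stage_specs() -> dict[StageLabel, StageSignalSpec]:
    """The five stage recipes (amplitudes in uV; invented fixture values)."""
    specs: dict[StageLabel, StageSignalSpec] = {
        StageLabel.W: StageSignalSpec(
            channels={
                "EEG Fpz-Cz": ChannelRecipe(
                    bands=(BandComponent(8.0, 13.0, 40.0), BandComponent(18.0, 30.0, 15.0))
                ),
                "EEG Pz-Oz": ChannelRecipe(
                    bands=(BandComponent(8.0, 13.0, 45.0), BandComponent(18.0, 30.0, 12.0))
                ),
                "EOG horizontal": ChannelRecipe(
                    bands=(BandComponent(0.5, 2.0, 10.0),),
                    deflection_rate=6.0,
                    deflection_amplitude=80.0,
                ),
                "EMG submental": ChannelRecipe(tone_level=30.0),
            },
            noise_sd=5.0,
        ),
        StageLabel.S1: StageSignalSpec(
            channels={
                "EEG Fpz-Cz": ChannelRecipe(
                    bands=(BandComponent(4.0, 7.0, 30.0), BandComponent(8.0, 13.0, 8.0))
                ),
                "EEG Pz-Oz": ChannelRecipe(
                    bands=(BandComponent(4.0, 7.0, 28.0), BandComponent(8.0, 13.0, 8.0))
                ),
                "EOG horizontal": ChannelRecipe(
                    bands=(BandComponent(0.3, 1.0, 15.0),),
                    deflection_rate=1.0,
                    deflection_amplitude=30.0,
                ),
                "EMG submental": ChannelRecipe(tone_level=15.0),
            },
            noise_sd=5.0,
        ),
        StageLabel.S2: StageSignalSpec(
            channels={
                "EEG Fpz-Cz": ChannelRecipe(
                    bands=(BandComponent(4.0, 7.0, 25.0),),
                    spindle_rate=3.0,
                    spindle_amplitude=45.0,
                    kcomplex_rate=1.5,
                    kcomplex_amplitude=100.0,
                ),
                "EEG Pz-Oz": ChannelRecipe(
                    bands=(BandComponent(4.0, 7.0, 22.0),),
                    spindle_rate=2.0,
                    spindle_amplitude=35.0,
                    kcomplex_rate=1.0,
                    kcomplex_amplitude=80.0,
                ),
                "EOG horizontal": ChannelRecipe(bands=(BandComponent(0.3, 1.0, 10.0),)),
                "EMG submental": ChannelRecipe(tone_level=10.0),
            },
            noise_sd=5.0,
        ),
        StageLabel.S3: StageSignalSpec(
            channels={
                "EEG Fpz-Cz": ChannelRecipe(bands=(BandComponent(0.75, 3.5, 150.0),)),
                "EEG Pz-Oz": ChannelRecipe(bands=(BandComponent(0.75, 3.5, 130.0),)),
                "EOG horizontal": ChannelRecipe(bands=(BandComponent(0.5, 2.0, 25.0),)),
                "EMG submental": ChannelRecipe(tone_level=8.0),
            },
            noise_sd=5.0,
        ),
        StageLabel.REM: StageSignalSpec(
            channels={
                "EEG Fpz-Cz": ChannelRecipe(
                    bands=(BandComponent(4.0, 8.0, 18.0),), sawtooth_amplitude=40.0
                ),
                "EEG Pz-Oz": ChannelRecipe(
                    bands=(BandComponent(4.0, 8.0, 16.0),), sawtooth_amplitude=35.0
                ),
                "EOG horizontal": ChannelRecipe(
                    bands=(BandComponent(0.3, 1.5, 20.0),),
                    deflection_rate=8.0,
                    deflection_amplitude=120.0,
                ),
                "EMG submental": ChannelRecipe(tone_level=2.0),
            },
            noise_sd=5.0,
        ),
    }
    return specs


# =============================================================================
# Waveform primitives
# =============================================================================


def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _synth_channel(
    recipe: ChannelRecipe,
    t: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One 100 Hz channel epoch from a recipe (sinusoids + events + noise)."""
    epoch_len = t[-1] + (t[1] - t[0]) if len(t) > 1 else 1.0
    x = np.zeros_like(t)
    for band in recipe.bands:
        f = rng.uniform(band.low, band.high)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += band.amplitude * np.sin(2.0 * np.pi * f * t + phase)
    lo, hi = 0.1 * epoch_len, 0.9 * epoch_len  # keep events off the edges
    n_spindles = rng.poisson(recipe.spindle_rate) if recipe.spindle_rate > 0 else 0
    for _ in range(n_spindles):
        center = rng.uniform(lo, hi)
        f = rng.uniform(12.0, 14.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += (
            recipe.spindle_amplitude
            * _gaussian_bump(t, center, 0.25)
            * np.sin(2.0 * np.pi * f * t + phase)
        )
    n_kc = rng.poisson(recipe.kcomplex_rate) if recipe.kcomplex_rate > 0 else 0
    for _ in range(n_kc):
        center = rng.uniform(lo, hi)
        # biphasic: sharp negative lobe then slower positive rebound
        x += recipe.kcomplex_amplitude * (
            -_gaussian_bump(t, center, 0.1) + 0.7 * _gaussian_bump(t, center + 0.35, 0.2)
        )
    if recipe.sawtooth_amplitude > 0:
        from scipy.signal import sawtooth

        f = rng.uniform(2.0, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += recipe.sawtooth_amplitude * sawtooth(2.0 * np.pi * f * t + phase)
    n_defl = rng.poisson(recipe.deflection_rate) if recipe.deflection_rate > 0 else 0
    for _ in range(n_defl):
        center = rng.uniform(lo, hi)
        sign = rng.choice([-1.0, 1.0])
        x += sign * recipe.deflection_amplitude * _gaussian_bump(t, center, 0.3)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=t.shape)
    return x


def _synth_emg_1hz(
    recipe: ChannelRecipe, epoch_len_s: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """1 Hz tonic EMG envelope: positive activity level around tone_level."""
    n = int(round(epoch_len_s))
    return np.abs(rng.normal(recipe.tone_level, max(noise_sd, 0.4 * recipe.tone_level + 1e-9), size=n))


# =============================================================================
# Epoch-set generation
# =============================================================================


def generate_epochset(
    config: SyntheticConfig = SyntheticConfig(),
    specs: Mapping[StageLabel, StageSignalSpec] | None = None,
) -> EpochSet:
    """Draw a seeded, labelled epoch set with exact per-class counts.

    Each epoch is the sum of its stage recipe's sinusoids, transient events,
    and Gaussian noise, per channel. The EMG channel is generated at 1 Hz and
    zero-order-held to the common rate so its stored and in-memory forms are
    mutually exact. Labels are emitted in class-block order (W block first);
    downstream splitting shuffles, so no randomization is applied here.
    """
    specs = default_stage_specs() if specs is None else specs
    counts = config.class_counts()
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("zero total epochs requested")
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.sampling_rate * config.epoch_len_s))
    t = np.arange(n_samples) / config.sampling_rate
    upsample = int(round(config.sampling_rate))  # 1 Hz -> common rate factor

    signals = np.empty((n_total, n_samples, len(config.channels)))
    labels = np.empty(n_total, dtype=np.int64)
    e = 0
    for code in range(5):
        spec = specs[StageLabel(code)]
        noise_sd = spec.noise_sd * config.noise_scale
        for _ in range(counts[code]):
            labels[e] = code
            for j, name in enumerate(config.channels):
                recipe = spec.channels[name]
                if name.startswith("EMG"):
                    env = _synth_emg_1hz(recipe, config.epoch_len_s, noise_sd, rng)
                    signals[e, :, j] = np.repeat(env, upsample)[:n_samples]
                else:
                    signals[e, :, j] = _synth_channel(recipe, t, noise_sd, rng)
            e += 1
    return EpochSet(
        signals, labels, list(config.channels), config.epoch_len_s, config.sampling_rate
    )


# =============================================================================
# EDF fixture round-trip
# =============================================================================


def write_fixture_edf(
    epochs: EpochSet,
    signal_path: str | Path,
    hypnogram_path: str | Path,
) -> tuple[Path, Path]:
    """Write an epoch set as an EDF signal file plus an EDF+ hypnogram.

    Epochs are laid end-to-end in time; each contributes one annotation of
    ``epoch_len_s`` duration with its Sleep-EDF dialect stage string. EMG
    channels are stored at 1 Hz (recovered exactly by block-mean from the
    zero-order-held samples), all other channels at the common rate, so the
    read -> resample -> segment round trip reproduces labels exactly and
    samples within the 16-bit quantization of each channel's physical range.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot write an empty epoch set")
    channels: list[SignalChannel] = []
    for j, name in enumerate(epochs.channel_names):
        flat = epochs.signals[:, :, j].reshape(-1)
        if name.startswith("EMG"):
            ch = resample_channel(
                SignalChannel(name, epochs.sampling_rate, flat), 1.0
            )
        else:
            ch = SignalChannel(name, epochs.sampling_rate, flat)
        channels.append(ch)
    signal_path = write_edf(Path(signal_path), channels, record_dur=1.0)
    annotations = [
        HypnogramAnnotation(
            onset_s=i * epochs.epoch_len_s,
            duration_s=epochs.epoch_len_s,
            raw_label=CODE_TO_DIALECT[int(code)],
        )
        for i, code in enumerate(epochs.labels)
    ]
    hypnogram_path = write_hypnogram(Path(hypnogram_path), annotations)
    return signal_path, hypnogram_path
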