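"""Deterministic synthetic EEG generator.

Emulates the class-conditional amplitude structure of the five-class
brain-activity dataset: seizure traces swing within +/-2000 with sparse
high-amplitude spike bursts, tumor-area traces mostly stay within +/-500
with rare excursions, and the three remaining classes live inside the
+300/-400 envelope.  Amplitude envelopes for the three low-amplitude
classes overlap while their oscillation bands are disjoint, so single
time samples carry mostly amplitude information and temporal models can
additionally read frequency — the property that makes the classes
separable in the same qualitative way as the real recordings.

Everything is a pure function of (config, label, stream id): one master
seed, per-recording substreams keyed by (label code, stream id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    CHUNKS_PER_RECORDING,
    RECORDING_LENGTH,
    EEGRecording,
    ClassLabel,
    SegmentDataset,
    chunk_recording,
    class_labels,
)

#: nominal sampling rate of the dialect (Hz)
SAMPLING_RATE = 178.0


@dataclass(frozen=True)
class ClassEnvelope:
    """Amplitude and spectral description of one class."""

    #: hard bound on |amplitude| after synthesis (clip guard)
    bound_hi: float
    bound_lo: float  # negative
    #: oscillation target peak amplitude range (fraction of signal before noise)
    amp_range: tuple[float, float]
    #: frequency band the sinusoids are drawn from (Hz)
    band: tuple[float, float]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults are the study conditions."""

    master_seed: int = 0
    #: sinusoids per trace drawn uniformly from this inclusive range
    n_components: tuple[int, int] = (2, 4)
    #: additive Gaussian noise scale as a fraction of the class amplitude;
    #: real EEG rhythms ride on strong broadband background activity, so the
    #: default places the noise floor at half the oscillation amplitude
    noise_scale: float = 0.5
    #: mean spike bursts per seizure recording (at least one is forced)
    seizure_burst_rate: float = 3.0
    #: probability that a tumor recording carries excursion bursts
    tumor_excursion_rate: float = 0.3
    envelopes: dict[int, ClassEnvelope] = field(
        default_factory=lambda: {
            1: ClassEnvelope(2000.0, -2000.0, (500.0, 800.0), (2.0, 8.0)),
            2: ClassEnvelope(500.0, -500.0, (350.0, 480.0), (4.0, 10.0)),
            3: ClassEnvelope(300.0, -400.0, (140.0, 260.0), (8.0, 13.0)),
            4: ClassEnvelope(300.0, -400.0, (150.0, 280.0), (1.0, 5.0)),
            5: ClassEnvelope(300.0, -400.0, (130.0, 250.0), (14.0, 30.0)),
        }
    )
    #: seizure spike-burst peak amplitude range
    burst_amp_range: tuple[float, float] = (1200.0, 1950.0)
    #: tumor excursion peak amplitude range (rare departures beyond +/-500)
    excursion_amp_range: tuple[float, float] = (650.0, 1100.0)

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")
        for env in self.envelopes.values():
            if env.bound_hi <= 0 or env.bound_lo >= 0:
                raise ValueError("envelope bounds must bracket zero")


def _burst(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """A single Hann-windowed spike burst placed at a random position."""
    width = int(rng.integers(20, 60))
    start = int(rng.integers(0, n - width))
    window = np.hanning(width)
    freq = rng.uniform(3.0, 7.0)
    t = np.arange(width) / SAMPLING_RATE
    phase = rng.uniform(0, 2 * np.pi)
    out = np.zeros(n)
    out[start : start + width] = amp * window * np.sin(2 * np.pi * freq * t + phase)
    return out


def generate_recording(
    label: ClassLabel, config: SynthConfig, stream_id: int
) -> EEGRecording:
    """Synthesize one 4,097-sample recording for the given class.

    Identical (master seed, label, stream id) always yields a bit-identical
    trace.
    """
    env = config.envelopes[label.code]
    rng = np.random.default_rng([config.master_seed, label.code, int(stream_id)])
    n = RECORDING_LENGTH
    t = np.arange(n) / SAMPLING_RATE

    n_comp = int(rng.integers(config.n_components[0], config.n_components[1] + 1))
    sig = np.zeros(n)
    for _ in range(n_comp):
        f = rng.uniform(*env.band)
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.4, 1.0)
        sig += weight * np.sin(2 * np.pi * f * t + phase)
    target = rng.uniform(*env.amp_range)
    peak = np.max(np.abs(sig))
    if peak > 0:
        sig *= target / peak

    sig += rng.normal(scale=config.noise_scale * target, size=n)

    if label.code == 1:
        n_bursts = max(1, int(rng.poisson(config.seizure_burst_rate)))
        for _ in range(n_bursts):
            sig += _burst(rng, n, rng.uniform(*config.burst_amp_range))
    elif label.code == 2 and rng.uniform() < config.tumor_excursion_rate:
        for _ in range(int(rng.integers(1, 3))):
            sig += _burst(rng, n, rng.uniform(*config.excursion_amp_range))

    np.clip(sig, env.bound_lo, env.bound_hi, out=sig)
    return EEGRecording(
        subject_id=f"synth-{label.code}-{stream_id}", amplitudes=sig, label=label
    )


def generate_balanced_dataset(n_per_class: int, config: SynthConfig) -> SegmentDataset:
    """A balanced dataset of ``23 * n_per_class`` segments per class.

    Each class contributes ``n_per_class`` recordings (stream ids
    ``0..n_per_class-1``), chunked into 23 segments each; the pooled
    segments are shuffled with a seed-derived permutation.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    segments = []
    for label in class_labels():
        for stream_id in range(n_per_class):
            rec = generate_recording(label, config, stream_id)
            segments.extend(chunk_recording(rec))
    ds = SegmentDataset.from_segments(segments)
    if len(ds) == 0:
        return ds
    perm = np.random.default_rng([config.master_seed, 777]).permutation(len(ds))
    return ds.subset(perm)
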