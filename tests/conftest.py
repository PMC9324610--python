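"""Shared fixtures: tiny deterministic datasets and reduced model configs.

Everything is generated programmatically and seeded; nothing is read from
disk. Unit tests use miniature networks (8/16/8 filters, few epochs); the
acceptance suite uses the reduced benchmark core (32/64/32, 20 epochs).
"""

from __future__ import annotations

import numpy as np
import pytest

from perhar import (
    ActivityRecording,
    FCNConfig,
    Segment,
    SegmentSet,
    TripletSamplerConfig,
    make_benchmark_fixture,
    segment_recordings,
)


def make_segment(
    window,
    label=0,
    subject="S00",
    source="rec0",
    start=0,
    rate_hz=50.0,
) -> Segment:
    window = np.atleast_2d(np.asarray(window, dtype=float))
    return Segment(
        subject_id=subject,
        label=label,
        window=window,
        rate_hz=rate_hz,
        source_id=source,
        interval=(start, start + window.shape[1]),
    )


def sine_recording(
    freqs, n_channels=2, n_samples=1000, rate_hz=50.0, subject="S00", label=0, seed=0,
    noise_sd=0.05, recording_id=None,
) -> ActivityRecording:
    """Multichannel sum-of-sines recording with a single label."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate_hz
    channels = np.zeros((n_channels, n_samples))
    for f in np.atleast_1d(freqs):
        phases = rng.uniform(0, 2 * np.pi, n_channels)
        channels += np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
    channels += rng.normal(0, noise_sd, channels.shape)
    return ActivityRecording(
        subject_id=subject,
        channels=channels,
        labels=np.full(n_samples, label),
        rate_hz=rate_hz,
        recording_id=recording_id or f"{subject}_L{label}",
    )


@pytest.fixture
def tiny_two_class_segments() -> SegmentSet:
    """Two subjects x two classes with disjoint frequency content; ~56 segments."""
    recs = []
    for s, subject in enumerate(["S00", "S01"]):
        for label, freq in [(0, 1.0), (1, 4.0)]:
            recs.append(
                sine_recording(
                    [freq], n_channels=2, n_samples=800, subject=subject,
                    label=label, seed=10 * s + label,
                )
            )
    return segment_recordings(recs, window_seconds=2.0, overlap=0.5)


@pytest.fixture
def tiny_fcn_config() -> FCNConfig:
    return FCNConfig(
        n_channels=2, conv_filters=(8, 16, 8), embedding_dim=8,
        n_classes=2, epochs=5, batch_size=32, seed=0,
    )


# four segments forming the minimal triplet universe: one subject,
# classes {A, B}, two non-overlapping segments each
@pytest.fixture
def toy_triplet_segments() -> SegmentSet:
    rng = np.random.default_rng(0)
    segs = []
    for i, (label, start) in enumerate([("A", 0), ("A", 100), ("B", 200), ("B", 300)]):
        segs.append(
            make_segment(rng.normal(size=(2, 50)), label=label, subject="S00",
                         source="rec0", start=start)
        )
    return SegmentSet(segs)


def random_segment_set(rng: np.random.Generator) -> SegmentSet:
    """Random small segment set for sampler property checks."""
    n_subjects = int(rng.integers(1, 4))
    n_classes = int(rng.integers(2, 4))
    segs = []
    for s in range(n_subjects):
        n_seg = int(rng.integers(3, 9))
        for i in range(n_seg):
            label = int(rng.integers(0, n_classes))
            source = f"S{s}_r{int(rng.integers(0, 2))}"
            start = int(rng.integers(0, 200))
            segs.append(
                make_segment(rng.normal(size=(1, 20)), label=label,
                             subject=f"S{s}", source=source, start=start)
            )
    return SegmentSet(segs)
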