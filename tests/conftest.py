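"""Shared fixtures: the seeded synthetic benchmark and objects derived from it.

The expensive pieces (benchmark generation, CRNN training) are session-scoped
so the end-to-end identification checks and the unit tests reuse one trained
pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

import ecgident as eid

BENCH_SEED = 0
N_SUBJECTS = 10
BEATS_PER_SUBJECT = 60
FS = 500.0


@pytest.fixture(scope="session")
def benchmark() -> eid.BeatMatrix:
    """10 subjects x 60 beats at 500 Hz with moderate noise (fixed seed)."""
    return eid.make_benchmark(
        n_subjects=N_SUBJECTS,
        beats_per_subject=BEATS_PER_SUBJECT,
        fs=FS,
        noise=eid.NoiseSpec(seed=BENCH_SEED),
        seed=BENCH_SEED,
    )


@pytest.fixture(scope="session")
def split(benchmark):
    """Stratified 80/20 split with integer-coded labels."""
    train, test = eid.split_train_test(benchmark, 0.2, seed=BENCH_SEED)
    classes = sorted(set(benchmark.labels))
    index = {c: i for i, c in enumerate(classes)}
    y_train = np.asarray([index[l] for l in train.labels])
    y_test = np.asarray([index[l] for l in test.labels])
    return train, test, y_train, y_test, classes


@pytest.fixture(scope="session")
def trained_net(split):
    """CRNN trained on the benchmark training split with the default protocol."""
    train, _test, y_train, _y_test, classes = split
    net = eid.build_crnn(
        eid.CRNNConfig(seq_len=train.beats.shape[1], n_classes=len(classes), seed=BENCH_SEED)
    )
    net, history = eid.train_crnn(net, train.beats, y_train, eid.TrainSpec(seed=BENCH_SEED))
    return net, history


@pytest.fixture(scope="session")
def feature_sets(split, trained_net):
    """DWT, deep and fused feature blocks for train and test splits."""
    train, test, y_train, y_test, _classes = split
    net, _history = trained_net
    dwt_train = eid.dwt_feature_matrix(train, "coif5")
    dwt_test = eid.dwt_feature_matrix(test, "coif5")
    deep_train = eid.extract_deep_features(net, train.beats)
    deep_test = eid.extract_deep_features(net, test.beats)
    return {
        "dwt": (dwt_train, dwt_test),
        "deep": (deep_train, deep_test),
        "fused": (
            eid.fuse_features(dwt_train, deep_train, train.labels).matrix,
            eid.fuse_features(dwt_test, deep_test, test.labels).matrix,
        ),
    }


def make_template(
    bpm: float = 60.0,
    rr_jitter_ms: float = 5.0,
    subject_id: str = "T000",
    r_amp: float = 1.2,
) -> eid.SubjectTemplate:
    """A fixed mid-range PQRST template with a controllable heart rate."""
    return eid.SubjectTemplate(
        subject_id=subject_id,
        p=eid.WaveParams(0.12, -170.0, 20.0),
        q=eid.WaveParams(-0.1, -30.0, 7.0),
        r=eid.WaveParams(r_amp, 0.0, 10.0),
        s=eid.WaveParams(-0.2, 35.0, 10.0),
        t=eid.WaveParams(0.25, 250.0, 40.0),
        rr_mean_ms=60_000.0 / bpm,
        rr_jitter_ms=rr_jitter_ms,
    )
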