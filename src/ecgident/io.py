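"""Readers/writers and the end-to-end pipeline runner.

Formats
-------
* single-column signal text: one sample per line, one-line header ``fs=<Hz>``
* delimited beat/feature matrices: CSV with a trailing ``label`` column
* WFDB-compatible records: plain-text header (record name, channels, fs,
  samples-per-channel; per-channel format/gain/baseline/units) next to a
  16-bit little-endian signal file.  Covers format 16, which is what the
  package writes and reads.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crnn as crnn_mod
from . import dwt as dwt_mod
from .errors import InvalidConfigError, InvalidInputError
from .evaluate import MetricsReport, confusion_matrix, per_class_metrics, split_train_test
from .fusion import ClassifierSpec, fuse_features, train_classifier
from .preprocess import FilterSpec, RawRecord, preprocess_record
from .segmentation import BeatMatrix, concat_consecutive, detect_rpeaks, extract_beats
from .synth import NoiseSpec, make_benchmark

__all__ = [
    "RunConfig",
    "read_signal_text",
    "write_signal_text",
    "read_beat_matrix",
    "write_beat_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
    "read_wfdb_record",
    "write_wfdb_record",
    "write_metrics_report",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# plain-text signal and matrix formats
# ---------------------------------------------------------------------------


def write_signal_text(path, samples, fs: float) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fs={fs}\n")
        for v in np.asarray(samples, dtype=float):
            fh.write(f"{v:.9g}\n")


def read_signal_text(path, subject_id: str = "") -> RawRecord:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise InvalidInputError(f"{path}: expected 'fs=<Hz>' header, got {header!r}")
        fs = float(header[3:])
        samples = np.array([float(line) for line in fh if line.strip()])
    return RawRecord(samples=samples, fs=fs, subject_id=subject_id, source=str(path))


def write_beat_matrix(path, beats: BeatMatrix) -> None:
    n_cols = beats.beats.shape[1]
    df = pd.DataFrame(beats.beats, columns=[f"s{i}" for i in range(n_cols)])
    df["label"] = beats.labels
    if beats.record_ids is not None:
        df["record"] = beats.record_ids
    df.to_csv(path, index=False)


def read_beat_matrix(path) -> BeatMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'label' column")
    record_ids = df.pop("record").to_numpy(dtype=object) if "record" in df.columns else None
    labels = df.pop("label").to_numpy(dtype=object)
    mat = df.to_numpy(dtype=float)
    from .segmentation import BEAT_LEN

    if mat.shape[1] % BEAT_LEN != 0:
        raise InvalidInputError(f"{path}: row length {mat.shape[1]} is not a multiple of {BEAT_LEN}")
    return BeatMatrix(beats=mat, labels=labels, k=mat.shape[1] // BEAT_LEN, record_ids=record_ids)


def write_feature_matrix(path, features: np.ndarray, labels) -> None:
    features = np.atleast_2d(np.asarray(features, dtype=float))
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'label' column")
    labels = df.pop("label").to_numpy(dtype=object)
    return df.to_numpy(dtype=float), labels


# ---------------------------------------------------------------------------
# WFDB-compatible records (format 16)
# ---------------------------------------------------------------------------


def write_wfdb_record(basepath, record: RawRecord, gain: float = 200.0, baseline: int = 0) -> None:
    """Write ``<base>.hea`` + ``<base>.dat`` (format 16, single channel)."""
    base = Path(basepath)
    name = base.name
    x = np.asarray(record.samples, dtype=float)
    digital = np.clip(np.round(x * gain + baseline), -32768, 32767).astype("<i2")
    digital.tofile(base.with_suffix(".dat"))
    with base.with_suffix(".hea").open("w") as fh:
        fh.write(f"{name} 1 {record.fs:g} {x.size}\n")
        fh.write(f"{name}.dat 16 {gain:g}({baseline})/mV 16 0 {digital[0]} 0 0 ECG\n")


def read_wfdb_record(basepath, channel: int = 0, subject_id: str = "") -> RawRecord:
    """Read a WFDB record (format 16) and return physical-unit samples."""
    base = Path(basepath)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise InvalidInputError(f"missing header file: {hea}")
    lines = [l.strip() for l in hea.read_text().splitlines() if l.strip() and not l.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    if not 0 <= channel < n_sig:
        raise InvalidInputError(
            f"channel {channel} out of range; record has channels 0..{n_sig - 1}"
        )
    sig_lines = lines[1: 1 + n_sig]
    specs = []
    for line in sig_lines:
        parts = line.split()
        fname, fmt = parts[0], parts[1]
        if fmt.split("x")[0] != "16":
            raise InvalidInputError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain_s, base_s = gain_str.split("(")
            gain = float(gain_s)
            baseline = int(base_s.rstrip(")"))
        else:
            gain = float(gain_str)
            baseline = 0
        if gain == 0:
            gain = 200.0
        specs.append((fname, gain, baseline))
    dat = hea.parent / specs[channel][0]
    if not dat.exists():
        raise InvalidInputError(f"missing signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        # format 16 is sample-interleaved across channels
        raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)[:, channel]
    if n_samp:
        raw = raw[:n_samp]
    _, gain, baseline = specs[channel]
    return RawRecord(
        samples=(raw.astype(float) - baseline) / gain,
        fs=fs,
        subject_id=subject_id,
        source=str(base),
    )


# ---------------------------------------------------------------------------
# metrics report + pipeline runner
# ---------------------------------------------------------------------------


def write_metrics_report(path, report: MetricsReport) -> None:
    rows = []
    for c in range(len(report.recall)):
        rows.append(
            {
                "class": c,
                "specificity": report.specificity[c],
                "recall": report.recall[c],
                "precision": report.precision[c],
                "f1": report.f1[c],
                "support": report.support[c],
            }
        )
    rows.append(
        {
            "class": "macro",
            "specificity": report.macro_specificity,
            "recall": report.macro_recall,
            "precision": report.macro_precision,
            "f1": report.macro_f1,
            "support": int(report.support.sum()),
        }
    )
    rows.append({"class": "accuracy", "specificity": "", "recall": "", "precision": "",
                 "f1": report.accuracy, "support": int(report.support.sum())})
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run on the synthetic benchmark."""

    n_subjects: int = 10
    beats_per_subject: int = 60
    fs: float = 500.0
    k: int = 1
    wavelet: str = "coif5"
    test_frac: float = 0.2
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    n_trees: int = 100
    seed: int = 0
    noise_baseline_amp: float = 0.15
    noise_powerline_amp: float = 0.05
    noise_white_sigma: float = 0.02
    out_dir: str | None = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def run_pipeline(config: RunConfig) -> tuple[MetricsReport, dict]:
    """preprocess -> segment -> (DWT || CRNN) -> fuse -> classify -> evaluate.

    Returns the metrics report and an artifact dictionary (stage timings, row
    counts, per-route accuracies, trained objects).  All randomness derives
    from ``config.seed``.
    """
    artifacts: dict = {"config": asdict(config), "timings": {}, "counts": {}}

    def stage(name):
        artifacts["timings"][name] = time.perf_counter()

    def stage_done(name):
        artifacts["timings"][name] = time.perf_counter() - artifacts["timings"][name]

    stage("benchmark")
    noise = NoiseSpec(
        baseline_amp=config.noise_baseline_amp,
        powerline_amp=config.noise_powerline_amp,
        white_sigma=config.noise_white_sigma,
        seed=config.seed,
    )
    bench = make_benchmark(
        n_subjects=config.n_subjects,
        beats_per_subject=config.beats_per_subject,
        fs=config.fs,
        noise=noise,
        seed=config.seed,
    )
    if config.k > 1:
        bench = concat_consecutive(bench, config.k)
    stage_done("benchmark")
    artifacts["counts"]["beats"] = bench.n_beats

    classes = sorted(set(bench.labels))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[c] for c in bench.labels])

    train, test = split_train_test(bench, config.test_frac, seed=config.seed)
    y_train = np.asarray([class_index[c] for c in train.labels])
    y_test = np.asarray([class_index[c] for c in test.labels])
    artifacts["counts"]["train"] = train.n_beats
    artifacts["counts"]["test"] = test.n_beats

    stage("dwt")
    dwt_train = dwt_mod.dwt_feature_matrix(train, config.wavelet)
    dwt_test = dwt_mod.dwt_feature_matrix(test, config.wavelet)
    stage_done("dwt")

    stage("crnn")
    net = crnn_mod.build_crnn(
        crnn_mod.CRNNConfig(seq_len=train.beats.shape[1], n_classes=len(classes), seed=config.seed)
    )
    spec = crnn_mod.TrainSpec(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    net, history = crnn_mod.train_crnn(net, train.beats, y_train, spec)
    deep_train = crnn_mod.extract_deep_features(net, train.beats)
    deep_test = crnn_mod.extract_deep_features(net, test.beats)
    stage_done("crnn")

    stage("classify")
    fused_train = fuse_features(dwt_train, deep_train, train.labels,
                                provenance={"wavelet": config.wavelet, "crnn_seed": config.seed})
    fused_test = fuse_features(dwt_test, deep_test, test.labels)
    clf_spec = ClassifierSpec(n_trees=config.n_trees, random_state=config.seed)
    clf = train_classifier(fused_train.matrix, y_train, clf_spec)
    y_pred = clf.predict(fused_test.matrix)
    stage_done("classify")

    cm = confusion_matrix(y_test, y_pred, len(classes))
    report = per_class_metrics(cm)

    artifacts.update(
        {
            "classes": classes,
            "history": history,
            "network": net,
            "classifier": clf,
            "confusion_matrix": cm,
            "train_labels": y_train,
            "test_labels": y_test,
            "fused_train": fused_train,
            "fused_test": fused_test,
            "dwt_train": dwt_train,
            "dwt_test": dwt_test,
            "deep_train": deep_train,
            "deep_test": deep_test,
        }
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "config.json").open("w") as fh:
            json.dump(asdict(config), fh, indent=1, sort_keys=True)
        write_metrics_report(out / "report.csv", report)
        with (out / "manifest.json").open("w") as fh:
            json.dump(
                {
                    "classes": [str(c) for c in classes],
                    "counts": artifacts["counts"],
                    "timings": artifacts["timings"],
                    "accuracy": report.accuracy,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    return report, artifacts
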