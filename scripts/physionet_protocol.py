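#!/usr/bin/env python
"""Optional: run the identification protocol on real PhysioNet-style records.

This is NOT part of the self-contained test suite — it requires locally
downloaded WFDB records (plain header + format-16 signal files, e.g. the
ECG-ID corpus; other signal formats are not supported by the bundled
reader).  Expected layout: one subdirectory per subject containing that
subject's records.

    python scripts/physionet_protocol.py --data <dir> --epochs 100 --seed 0

Protocol: preprocess each record at native sampling rate, Pan-Tompkins
segmentation into 94-sample beats, per-beat stratified 80/20 split, coif5
DWT (256) + trained CRNN (128) feature fusion, 100-tree random forest, and
a per-subject metrics report.  Published reference accuracies for this
protocol on ECG-ID / MIT-BIH Arrhythmia / MIT-BIH NSR / all three combined
are 80.64 / 98.81 / 99.62 / 98.24 percent; they are comparison values, not
targets this script asserts.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

import ecgident as eid
from ecgident.fusion import ClassifierSpec


def collect_beats(data_dir: Path, channel: int) -> eid.BeatMatrix:
    rows, labels, records = [], [], []
    for subject_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        for hea in sorted(subject_dir.glob("*.hea")):
            rec = eid.read_wfdb_record(hea.with_suffix(""), channel=channel,
                                       subject_id=subject_dir.name)
            clean = eid.preprocess_record(rec)
            peaks = eid.detect_rpeaks(clean)
            beats = eid.extract_beats(clean, peaks, record_id=str(hea))
            if beats.n_beats:
                rows.append(beats.beats)
                labels.append(np.full(beats.n_beats, subject_dir.name, dtype=object))
                records.append(np.full(beats.n_beats, str(hea), dtype=object))
    if not rows:
        raise SystemExit(f"no readable records under {data_dir}")
    return eid.BeatMatrix(
        beats=np.vstack(rows), labels=np.concatenate(labels),
        record_ids=np.concatenate(records),
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True)
    parser.add_argument("--channel", type=int, default=0)
    parser.add_argument("--wavelet", default="coif5")
    parser.add_argument("--epochs", type=int, default=100)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("physionet_report.csv"))
    args = parser.parse_args()

    bench = collect_beats(args.data, args.channel)
    classes = sorted(set(bench.labels))
    index = {c: i for i, c in enumerate(classes)}
    train, test = eid.split_train_test(bench, 0.2, seed=args.seed)
    y_train = np.asarray([index[l] for l in train.labels])
    y_test = np.asarray([index[l] for l in test.labels])
    print(f"{len(classes)} subjects, {train.n_beats} train / {test.n_beats} test beats")

    dwt_train = eid.dwt_feature_matrix(train, args.wavelet)
    dwt_test = eid.dwt_feature_matrix(test, args.wavelet)
    net = eid.build_crnn(eid.CRNNConfig(seq_len=94, n_classes=len(classes), seed=args.seed))
    net, _ = eid.train_crnn(net, train.beats, y_train,
                            eid.TrainSpec(epochs=args.epochs, seed=args.seed))
    fused_train = eid.fuse_features(dwt_train, eid.extract_deep_features(net, train.beats))
    fused_test = eid.fuse_features(dwt_test, eid.extract_deep_features(net, test.beats))

    clf = eid.train_classifier(fused_train.matrix, y_train, ClassifierSpec(random_state=args.seed))
    y_pred = clf.predict(fused_test.matrix)
    report = eid.per_class_metrics(eid.confusion_matrix(y_test, y_pred, len(classes)))
    eid.write_metrics_report(args.out, report)
    print(report.summary())


if __name__ == "__main__":
    main()
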