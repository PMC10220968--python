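"""R-peak detection (Pan-Tompkins) and fixed-length QRS beat extraction.

Each identified heartbeat is cut into a 94-sample window with the R-peak at
within-row offset 45 (45 samples before, 49 after, half-open on the right).
Consecutive beats of a subject can be concatenated into rows of 94*k samples
for multi-beat identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, InvalidInputError
from .preprocess import CleanSignal

__all__ = [
    "PanTompkinsConfig",
    "RPeakList",
    "BeatMatrix",
    "detect_rpeaks",
    "extract_beats",
    "concat_consecutive",
]

#: samples before / after the R-peak in a single-beat window
PRE_SAMPLES = 45
POST_SAMPLES = 49
BEAT_LEN = PRE_SAMPLES + POST_SAMPLES  # 94


@dataclass
class PanTompkinsConfig:
    """Internal constants of the QRS detector (classic defaults).

    Band-pass passband, integration window, refractory period, threshold
    update factors and the T-wave discrimination window follow the original
    algorithm; all are overridable.
    """

    band: tuple[float, float] = (5.0, 15.0)
    band_order: int = 2
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    twave_window_s: float = 0.360
    signal_update: float = 0.125
    noise_update: float = 0.25
    searchback_factor: float = 1.66
    refine_window_s: float = 0.050


@dataclass
class RPeakList:
    """Strictly increasing R-peak sample indices at sampling rate ``fs``."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise InvalidInputError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class BeatMatrix:
    """n beats x (94*k) aligned QRS segments with per-row subject labels.

    ``record_ids`` (optional) tag the source recording of each row so that
    multi-beat concatenation never crosses a record boundary.
    """

    beats: np.ndarray
    labels: np.ndarray
    k: int = 1
    peak_offset: int = PRE_SAMPLES
    record_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.beats.shape[0] != self.labels.shape[0]:
            raise InvalidInputError("labels must align with beat rows")
        if self.beats.size and self.beats.shape[1] != BEAT_LEN * self.k:
            raise InvalidInputError(
                f"rows must have {BEAT_LEN}*k={BEAT_LEN * self.k} samples, got {self.beats.shape[1]}"
            )
        if self.beats.size and not np.all(np.isfinite(self.beats)):
            raise InvalidInputError("beat matrix contains non-finite values")
        if self.record_ids is not None:
            self.record_ids = np.asarray(self.record_ids)
            if self.record_ids.shape[0] != self.beats.shape[0]:
                raise InvalidInputError("record_ids must align with beat rows")

    @property
    def n_beats(self) -> int:
        return int(self.beats.shape[0])


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks(clean: CleanSignal, config: PanTompkinsConfig | None = None) -> RPeakList:
    """Pan-Tompkins QRS detection on a preprocessed signal.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, dual adaptive thresholds with search-back, and
    final refinement of every detection to the local maximum of the clean
    signal within +/-50 ms.

    Returns an empty :class:`RPeakList` when nothing crosses threshold.
    """
    cfg = config or PanTompkinsConfig()
    x = np.asarray(clean.samples, dtype=float)
    fs = clean.fs
    if x.size < 2 * fs:
        raise InvalidInputError("need at least 2 s of signal for QRS detection")

    sos = sps.butter(cfg.band_order, cfg.band, btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)

    # five-point derivative (centered, zero-delay form)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    squared = deriv * deriv
    mwi = _moving_window_integral(squared, max(1, int(round(cfg.integration_window_s * fs))))

    refractory = int(round(cfg.refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=max(1, refractory))
    if cand.size == 0:
        return RPeakList(indices=np.array([], dtype=int), fs=fs)

    head = mwi[: int(2 * fs)]
    spki = 0.25 * head.max()
    npki = 0.5 * float(head.mean())
    if spki <= 0:
        return RPeakList(indices=np.array([], dtype=int), fs=fs)

    twave_win = int(round(cfg.twave_window_s * fs))
    peaks: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        idx = int(cand[i])
        amp = mwi[idx]
        is_qrs = amp > threshold()
        if is_qrs and peaks and idx - peaks[-1] <= twave_win:
            # T-wave discrimination: reject if the leading slope is less than
            # half of the previous QRS slope
            w = max(1, refractory // 2)
            cur = np.max(np.abs(deriv[max(0, idx - w): idx + 1]))
            prev = np.max(np.abs(deriv[max(0, peaks[-1] - w): peaks[-1] + 1]))
            if cur < 0.5 * prev:
                is_qrs = False
        if is_qrs:
            if peaks and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                gap = idx - peaks[-1]
                if gap > cfg.searchback_factor * rr_avg:
                    # search-back: accept the strongest skipped candidate over half threshold
                    missed = cand[(cand > peaks[-1] + refractory) & (cand < idx - refractory)]
                    if missed.size:
                        best = int(missed[np.argmax(mwi[missed])])
                        if mwi[best] > 0.5 * threshold():
                            rr_history.append(best - peaks[-1])
                            peaks.append(best)
                            spki = 0.25 * mwi[best] + 0.75 * spki
            if peaks:
                rr_history.append(idx - peaks[-1])
            peaks.append(idx)
            spki = cfg.signal_update * amp + (1 - cfg.signal_update) * spki
        else:
            npki = cfg.noise_update * amp + (1 - cfg.noise_update) * npki
        i += 1

    if not peaks:
        return RPeakList(indices=np.array([], dtype=int), fs=fs)

    # refine to the local maximum of the clean signal within +/- refine_window
    half = max(1, int(round(cfg.refine_window_s * fs)))
    refined = []
    for p in peaks:
        lo = max(0, p - half)
        hi = min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # enforce the refractory period after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
        elif x[p] > x[keep[-1]]:
            keep[-1] = int(p)
    return RPeakList(indices=np.asarray(keep, dtype=int), fs=fs)


def extract_beats(
    clean: CleanSignal,
    peaks: RPeakList,
    pre: int = PRE_SAMPLES,
    post: int = POST_SAMPLES,
    record_id: str | None = None,
) -> BeatMatrix:
    """Slice a fixed window ``[Rp - pre, Rp + post)`` around every R-peak.

    Peaks whose window would cross the signal boundary are dropped; row order
    follows peak order.
    """
    if pre < 0 or post < 0:
        raise InvalidConfigError("pre and post must be non-negative")
    x = np.asarray(clean.samples, dtype=float)
    rows = []
    kept_peaks = []
    for p in peaks.indices:
        lo, hi = p - pre, p + post
        if lo < 0 or hi > x.size:
            continue
        rows.append(x[lo:hi])
        kept_peaks.append(p)
    n = len(rows)
    beats = np.asarray(rows, dtype=float) if n else np.empty((0, pre + post))
    labels = np.full(n, clean.subject_id, dtype=object)
    rec = None
    if record_id is not None:
        rec = np.full(n, record_id, dtype=object)
    k = (pre + post) // BEAT_LEN if (pre + post) % BEAT_LEN == 0 else 1
    return BeatMatrix(beats=beats, labels=labels, k=max(1, k), peak_offset=pre, record_ids=rec)


def concat_consecutive(beats: BeatMatrix, k: int) -> BeatMatrix:
    """Join non-overlapping groups of ``k`` consecutive same-subject beats.

    Rows must be single-beat and in temporal order within each (subject,
    record) group; the trailing remainder of fewer than ``k`` beats is
    dropped.  ``k = 1`` is the identity.
    """
    if not 1 <= k <= 4:
        raise InvalidConfigError(f"k must be in 1..4, got {k}")
    if beats.k != 1:
        raise InvalidInputError("concat_consecutive expects single-QRS rows")
    if k == 1:
        return beats

    if beats.record_ids is not None:
        keys = [f"{l}\x00{r}" for l, r in zip(beats.labels, beats.record_ids)]
    else:
        keys = [str(l) for l in beats.labels]
    keys = np.asarray(keys, dtype=object)

    out_rows, out_labels, out_rec = [], [], []
    seen = []
    for key in keys:
        if key not in seen:
            seen.append(key)
    for key in seen:
        idx = np.flatnonzero(keys == key)
        for g in range(len(idx) // k):
            sel = idx[g * k:(g + 1) * k]
            out_rows.append(np.concatenate([beats.beats[j] for j in sel]))
            out_labels.append(beats.labels[sel[0]])
            if beats.record_ids is not None:
                out_rec.append(beats.record_ids[sel[0]])
    n = len(out_rows)
    mat = np.asarray(out_rows) if n else np.empty((0, BEAT_LEN * k))
    rec = np.asarray(out_rec, dtype=object) if out_rec else None
    return BeatMatrix(
        beats=mat,
        labels=np.asarray(out_labels, dtype=object) if n else np.empty(0, dtype=object),
        k=k,
        record_ids=rec,
    )
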