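"""Level-4 discrete wavelet decomposition of QRS beats and the fixed
256-length coefficient feature vector.

A beat is decomposed into five subbands [cA4, cD4, cD3, cD2, cD1] with the
chosen family's analysis filters and symmetric boundary extension; the
concatenated coefficients are right-zero-padded (or right-truncated) to the
fixed classifier width of 256, so every family and every beat length meets
the same fusion interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import InvalidConfigError, InvalidInputError
from .segmentation import BeatMatrix

__all__ = [
    "FAMILIES",
    "FEATURE_LEN",
    "WaveletFamily",
    "DWTCoefficients",
    "wavelet_decompose",
    "dwt_feature_vector",
    "dwt_feature_matrix",
    "reconstruct",
    "band_lengths",
]

FAMILIES = ("haar", "db2", "bior6.8", "sym5", "coif5")
FEATURE_LEN = 256
LEVEL = 4
BAND_NAMES = ("cA4", "cD4", "cD3", "cD2", "cD1")


@dataclass(frozen=True)
class WaveletFamily:
    """A supported wavelet family with its analysis/synthesis filter banks.

    On construction the orthogonal families are validated against the
    two-scale (double-shift orthogonality) relation, so the module cannot
    silently run with a corrupted filter table.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in FAMILIES:
            raise InvalidConfigError(
                f"unsupported wavelet family {self.name!r}; choose from {FAMILIES}"
            )
        if self.orthogonal:
            h = np.asarray(self.wavelet.dec_lo)
            # sum h[n] h[n-2m] = delta(m); unit energy at m=0
            for m in range(1, len(h) // 2):
                if abs(np.dot(h[2 * m:], h[:len(h) - 2 * m])) > 1e-10:
                    raise InvalidConfigError(f"{self.name}: filter fails two-scale relation")
            if abs(np.dot(h, h) - 1.0) > 1e-10:
                raise InvalidConfigError(f"{self.name}: analysis filter is not unit-norm")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.name)

    @property
    def orthogonal(self) -> bool:
        return bool(self.wavelet.orthogonal)

    @property
    def filter_length(self) -> int:
        return int(self.wavelet.dec_len)


@dataclass
class DWTCoefficients:
    """Subbands of a level-4 decomposition, ordered [cA4, cD4, cD3, cD2, cD1]."""

    bands: list[np.ndarray]
    family: WaveletFamily
    boundary_mode: str
    original_length: int

    def __post_init__(self) -> None:
        if len(self.bands) != LEVEL + 1:
            raise InvalidInputError(f"expected {LEVEL + 1} subbands, got {len(self.bands)}")
        self.bands = [np.asarray(b, dtype=float) for b in self.bands]


def band_lengths(n: int, filter_length: int, level: int = LEVEL) -> list[int]:
    """Subband lengths under symmetric extension: l <- floor((l + L - 1) / 2),
    returned in [cA, cD_level, ..., cD1] order."""
    lengths = []
    cur = n
    for _ in range(level):
        cur = (cur + filter_length - 1) // 2
        lengths.append(cur)
    return [lengths[-1]] + lengths[::-1]


def wavelet_decompose(
    beat,
    family: WaveletFamily | str = "coif5",
    level: int = LEVEL,
    mode: str = "symmetric",
) -> DWTCoefficients:
    """Cascade analysis filter bank with dyadic downsampling."""
    if isinstance(family, str):
        family = WaveletFamily(family)
    x = np.asarray(beat, dtype=float).ravel()
    if x.size < 2 ** level:
        raise InvalidInputError(
            f"beat of length {x.size} too short for a level-{level} decomposition"
        )
    with warnings.catch_warnings():
        # level 4 on a 94-sample beat deliberately exceeds pywt's
        # boundary-effect-free depth; the coefficients are still exact
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, family.wavelet, mode=mode, level=level)
    return DWTCoefficients(
        bands=list(coeffs), family=family, boundary_mode=mode, original_length=x.size
    )


def reconstruct(coeffs: DWTCoefficients) -> np.ndarray:
    """Inverse cascade; reproduces the analyzed beat to floating-point accuracy."""
    expected = band_lengths(
        coeffs.original_length, coeffs.family.filter_length, len(coeffs.bands) - 1
    )
    if coeffs.boundary_mode == "symmetric":
        got = [b.size for b in coeffs.bands]
        if got != expected:
            raise InvalidInputError(f"inconsistent band lengths {got}, expected {expected}")
    y = pywt.waverec(coeffs.bands, coeffs.family.wavelet, mode=coeffs.boundary_mode)
    return y[: coeffs.original_length]


def dwt_feature_vector(beat, family: WaveletFamily | str = "coif5") -> np.ndarray:
    """Fixed 256-length feature vector: concatenated level-4 coefficients,
    right-zero-padded or right-truncated."""
    coeffs = wavelet_decompose(beat, family)
    flat = np.concatenate(coeffs.bands)
    out = np.zeros(FEATURE_LEN)
    n = min(flat.size, FEATURE_LEN)
    out[:n] = flat[:n]
    return out


def dwt_feature_matrix(beats: BeatMatrix, family: WaveletFamily | str = "coif5") -> np.ndarray:
    """Apply :func:`dwt_feature_vector` to every row of a beat matrix."""
    if isinstance(family, str):
        family = WaveletFamily(family)
    return np.vstack([dwt_feature_vector(row, family) for row in beats.beats]) \
        if beats.n_beats else np.empty((0, FEATURE_LEN))
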