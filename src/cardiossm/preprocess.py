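"""The classical ECG denoising pipeline the classifier is designed to not need.

Three stages, applied lead-wise and length-preserving:

1. 4th-order Butterworth bandpass, 0.5-40 Hz;
2. wavelet denoising ('db4', decomposition level 8, universal soft threshold
   with a median-absolute-deviation noise estimate from the finest detail
   level);
3. 6th-order Butterworth high-pass at 0.1 Hz (residual baseline wander).

All IIR stages are applied forward-backward (zero phase) so fiducial timing
such as PR intervals is preserved.  The pipeline exists so raw-vs-denoised
comparisons can be run; its dispensability for the classifier is the point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

from .ecg_io import ECGRecord

__all__ = [
    "DenoiseConfig",
    "bandpass",
    "wavelet_denoise",
    "baseline_highpass",
    "denoise_pipeline",
]


@dataclass
class DenoiseConfig:
    bandpass_low: float = 0.5       # Hz
    bandpass_high: float = 40.0     # Hz
    bandpass_order: int = 4
    wavelet_name: str = "db4"
    wavelet_level: int = 8
    highpass_cutoff: float = 0.1    # Hz
    highpass_order: int = 6
    #: run the 0.1 Hz high-pass after (True) or before (False) the wavelet step
    highpass_last: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.bandpass_high >= nyq or self.highpass_cutoff >= nyq:
            raise ValueError(
                f"cutoff at or above Nyquist ({nyq:g} Hz) for fs={sampling_rate:g}"
            )
        if self.bandpass_order < 1 or self.highpass_order < 1 or self.wavelet_level < 1:
            raise ValueError("filter orders and wavelet level must be >= 1")


def _padlen(record: ECGRecord, corner_hz: float) -> int:
    """Forward-backward filtering needs edge padding on the scale of the
    slowest corner's settling time, far beyond scipy's default."""
    return min(record.n_samples - 1, int(3.0 * record.sampling_rate / corner_hz))


def bandpass(record: ECGRecord, config: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Zero-phase Butterworth bandpass of every lead."""
    config.validate(record.sampling_rate)
    sos = butter(
        config.bandpass_order,
        [config.bandpass_low, config.bandpass_high],
        btype="bandpass",
        fs=record.sampling_rate,
        output="sos",
    )
    out = sosfiltfilt(sos, record.signal, axis=1,
                      padlen=_padlen(record, config.bandpass_low))
    return record.replace(signal=out)


def wavelet_denoise(record: ECGRecord, config: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Multilevel wavelet shrinkage per lead.

    Detail coefficients at every level are soft-thresholded with the
    universal threshold sigma * sqrt(2 ln n); sigma is estimated as
    MAD(finest detail) / 0.6745.
    """
    config.validate(record.sampling_rate)
    n = record.n_samples
    min_len = 2 ** config.wavelet_level
    if n < min_len:
        raise ValueError(
            f"signal length {n} too short for decomposition level "
            f"{config.wavelet_level}; need at least {min_len} samples"
        )
    out = np.empty_like(record.signal)
    for i in range(record.n_leads):
        coeffs = pywt.wavedec(record.signal[i], config.wavelet_name,
                              level=config.wavelet_level)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        if thr > 0:
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
            ]
        out[i] = pywt.waverec(coeffs, config.wavelet_name)[:n]
    return record.replace(signal=out)


def baseline_highpass(record: ECGRecord, config: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Zero-phase high-pass removing baseline wander below the cutoff."""
    config.validate(record.sampling_rate)
    sos = butter(
        config.highpass_order,
        config.highpass_cutoff,
        btype="highpass",
        fs=record.sampling_rate,
        output="sos",
    )
    out = sosfiltfilt(sos, record.signal, axis=1,
                      padlen=_padlen(record, config.highpass_cutoff))
    return record.replace(signal=out)


def denoise_pipeline(record: ECGRecord, config: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Full pre-processing arm: bandpass -> wavelet -> baseline high-pass."""
    out = bandpass(record, config)
    if config.highpass_last:
        out = wavelet_denoise(out, config)
        out = baseline_highpass(out, config)
    else:
        out = baseline_highpass(out, config)
        out = wavelet_denoise(out, config)
    return out
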