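"""Post-ICA time-series processing: trim, detrend, despike, bandpass.

The stages run in that fixed order, per component, per subject. All
parameters live in :class:`PreprocessConfig`; each stage is also
exposed as a standalone function so the composition contract can be
tested directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import ComponentTimeSeries

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters with the pipeline's standard defaults.

    Scans are standardized to ``target_frames`` frames by dropping
    ``n_drop_leading`` initial volumes (scanner equilibration) and any
    excess from the end. Despiking compresses outlying excursions with a
    tanh soft clip between ``despike_c1`` and ``despike_c2`` robust SDs
    around a running-median baseline. The bandpass is a zero-phase
    Butterworth restricted to the 0.01-0.1 Hz resting-state band.
    """

    n_drop_leading: int = 5
    target_frames: int = 155
    despike_c1: float = 2.5
    despike_c2: float = 4.0
    despike_window: int = 9
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    filter_order: int = 5
    filter_design: str = "butter"  # or "fft"
    zscore_components: bool = True
    do_trim: bool = True
    do_detrend: bool = True
    do_despike: bool = True
    do_bandpass: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise PreprocessError("require 0 < band_low_hz < band_high_hz")
        if not (self.despike_c2 > self.despike_c1 > 0):
            raise PreprocessError("require despike_c2 > despike_c1 > 0")
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise PreprocessError("despike_window must be odd and >= 3")
        if self.filter_design not in ("butter", "fft"):
            raise PreprocessError("filter_design must be 'butter' or 'fft'")


def trim_scan(
    ts: ComponentTimeSeries, n_drop_leading: int = 5, target_frames: int = 155
) -> ComponentTimeSeries:
    """Drop leading volumes, then cut the tail to ``target_frames`` frames."""
    needed = n_drop_leading + target_frames
    if ts.n_frames < needed:
        raise PreprocessError(
            f"{ts.subject_id}: scan has {ts.n_frames} frames but trimming "
            f"requires at least {needed} ({n_drop_leading} dropped + "
            f"{target_frames} kept)"
        )
    return ts.with_data(ts.data[n_drop_leading : n_drop_leading + target_frames])


def detrend_linear(ts: ComponentTimeSeries) -> ComponentTimeSeries:
    """Remove each component's least-squares line (slope and intercept)."""
    if ts.n_frames < 3:
        raise PreprocessError("need at least 3 frames to detrend")
    return ts.with_data(signal.detrend(ts.data, axis=0, type="linear"))


def despike(
    ts: ComponentTimeSeries,
    c1: float = 2.5,
    c2: float = 4.0,
    window: int = 9,
) -> ComponentTimeSeries:
    """Compress spikes with a tanh soft clip around a running-median baseline.

    Residuals from a centered running median (window shrinking at the
    edges) are standardized by 1.4826x the median absolute residual.
    Standardized residuals ``s`` with ``|s| <= c1`` pass unchanged;
    larger ones are mapped to
    ``sign(s) * (c1 + (c2 - c1) * tanh((|s| - c1) / (c2 - c1)))``,
    so every output residual stays strictly below ``c2`` in magnitude.
    Components whose median absolute residual is zero (e.g. constant
    series) are returned unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise PreprocessError("window must be odd and >= 3")
    if not (c2 > c1 > 0):
        raise PreprocessError("require c2 > c1 > 0")
    data = ts.data
    baseline = (
        pd.DataFrame(data)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    resid = data - baseline
    sigma = 1.4826 * np.median(np.abs(resid), axis=0)
    out = data.copy()
    ok = sigma > 0
    if np.any(ok):
        s = resid[:, ok] / sigma[ok]
        a = np.abs(s)
        clipped = np.where(
            a > c1, np.sign(s) * (c1 + (c2 - c1) * np.tanh((a - c1) / (c2 - c1))), s
        )
        out[:, ok] = baseline[:, ok] + sigma[ok] * clipped
    return ts.with_data(out)


def bandpass(
    ts: ComponentTimeSeries,
    band_low_hz: float = 0.01,
    band_high_hz: float = 0.1,
    filter_order: int = 5,
    design: str = "butter",
) -> ComponentTimeSeries:
    """Zero-phase bandpass; ``design='fft'`` selects an ideal FFT mask instead."""
    fs = 1.0 / ts.tr_seconds
    nyq = fs / 2.0
    if not (0 < band_low_hz < band_high_hz < nyq):
        raise PreprocessError(
            f"band ({band_low_hz}, {band_high_hz}) Hz infeasible for "
            f"TR = {ts.tr_seconds} s (Nyquist {nyq:.4g} Hz)"
        )
    if design == "fft":
        freqs = np.fft.rfftfreq(ts.n_frames, d=ts.tr_seconds)
        spec = np.fft.rfft(ts.data, axis=0)
        spec[(freqs < band_low_hz) | (freqs > band_high_hz)] = 0
        return ts.with_data(np.fft.irfft(spec, n=ts.n_frames, axis=0))
    if ts.n_frames < 3 * filter_order:
        raise PreprocessError("series too short for the requested filter order")
    sos = signal.butter(
        filter_order, [band_low_hz, band_high_hz], btype="band", fs=fs, output="sos"
    )
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=0))


def zscore(ts: ComponentTimeSeries) -> ComponentTimeSeries:
    """Z-score each component across frames; constant components map to zero."""
    mu = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return ts.with_data((ts.data - mu) / sd_safe)


def run_postica_pipeline(
    ts: ComponentTimeSeries, config: PreprocessConfig | None = None
) -> ComponentTimeSeries:
    """Apply trim -> detrend -> despike -> bandpass (then optional z-score)."""
    config = PreprocessConfig() if config is None else config
    out = ts
    if config.do_trim:
        out = trim_scan(out, config.n_drop_leading, config.target_frames)
        logger.debug("%s: trimmed to %d frames", ts.subject_id, out.n_frames)
    if config.do_detrend:
        out = detrend_linear(out)
        logger.debug("%s: linear detrend", ts.subject_id)
    if config.do_despike:
        out = despike(out, config.despike_c1, config.despike_c2, config.despike_window)
        logger.debug("%s: despike (c1=%g, c2=%g)", ts.subject_id,
                     config.despike_c1, config.despike_c2)
    if config.do_bandpass:
        out = bandpass(out, config.band_low_hz, config.band_high_hz,
                       config.filter_order, config.filter_design)
        logger.debug("%s: bandpass %g-%g Hz", ts.subject_id,
                     config.band_low_hz, config.band_high_hz)
    if config.zscore_components:
        out = zscore(out)
    return out
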