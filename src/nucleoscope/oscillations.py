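"""Depth-resolved FFT analysis of cell-area oscillations.

Per-cell, per-layer area signals are aligned to each cell's own nuclear
midplane (depth offset 0 µm; positive offsets apical, negative basal),
detrended, Fourier-transformed, and the amplitude spectra averaged per
depth-offset bin into an oscillation map.  The dampening statistic is the
percent drop in amplitude at a frequency of interest (0.008 Hz by
default) between a basal reference offset (−4 µm) and the midplane.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps


def detrend(y: np.ndarray, method: str = "linear", *, window: int | None = None) -> np.ndarray:
    """Remove the trend of a signal (zero-mean output).

    ``"linear"``: least-squares line removal; ``"mean"``: mean removal;
    ``"movavg"``: subtract a centred moving average of ``window`` samples.
    """
    y = np.asarray(y, dtype=float)
    if method == "linear":
        return sps.detrend(y, type="linear")
    if method == "mean":
        return y - y.mean()
    if method == "movavg":
        if not window or window < 1:
            raise ValueError("movavg detrending needs a positive window")
        pad = np.pad(y, (window // 2, window - 1 - window // 2), mode="edge")
        ma = np.convolve(pad, np.ones(window) / window, mode="valid")
        return y - ma
    raise ValueError(f"unknown detrending method {method!r}")


def amplitude_spectrum(y: np.ndarray, dt: float, *, window: str | None = None) -> pd.DataFrame:
    """One-sided FFT amplitude spectrum of a uniformly sampled signal.

    Amplitudes are scaled so a pure sinusoid of amplitude A shows A at its
    frequency bin (2|Y|/N, with DC and Nyquist unscaled).  No taper is
    applied by default; ``window="hann"`` is available.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if window == "hann":
        y = y * np.hanning(n)
    yf = np.fft.rfft(y)
    amp = np.abs(yf) / n
    amp[1:] *= 2.0
    if n % 2 == 0 and len(amp) > 1:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=dt)
    return pd.DataFrame({"freq_hz": freqs, "amplitude": amp})


def fft_amplitude_map(
    signals: pd.DataFrame,
    frame_interval: float,
    *,
    min_duration_s: float = 180.0,
    offset_bin_um: float = 1.0,
    detrend_method: str = "linear",
    average: str = "spectra",
) -> pd.DataFrame:
    """Oscillation map: mean FFT amplitude per (depth offset, frequency).

    ``signals`` needs columns track, frame, offset_um, area_um2 (one area
    signal per cell per layer; the offset is the layer's depth relative to
    that cell's nuclear midplane, re-binned to ``offset_bin_um``).  Signals
    shorter than ``min_duration_s`` are excluded; the rest are truncated to
    the shortest common length so all spectra share one frequency grid.
    ``average="spectra"`` averages amplitude spectra across cells per depth
    bin (default); ``average="cells"`` averages the signals first.

    Returns a DataFrame indexed by depth-offset bin (µm) with one column
    per frequency (Hz); per-bin aggregation counts are in
    ``attrs["counts"]``.
    """
    req = {"track", "frame", "offset_um", "area_um2"}
    if not req <= set(signals.columns):
        raise ValueError(f"signals table needs columns {sorted(req)}")
    min_len = int(np.ceil(min_duration_s / frame_interval))
    groups = []
    for (track, obin), g in signals.groupby(
        ["track", (signals["offset_um"] / offset_bin_um).round() * offset_bin_um]
    ):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if len(frames) < min_len:
            continue
        if not np.all(np.diff(frames) == 1):
            raise ValueError("non-uniform sampling: frames of one signal must be consecutive")
        groups.append((obin, g["area_um2"].to_numpy(dtype=float)))
    if not groups:
        return pd.DataFrame()
    n = min(len(y) for _, y in groups)
    freqs = np.fft.rfftfreq(n, d=frame_interval)
    by_offset: dict[float, list] = {}
    for obin, y in groups:
        by_offset.setdefault(float(obin), []).append(y[:n])
    rows, counts = {}, {}
    for obin, ys in sorted(by_offset.items()):
        if average == "cells":
            mean_sig = np.mean([detrend(y, detrend_method) for y in ys], axis=0)
            amp = amplitude_spectrum(mean_sig, frame_interval)["amplitude"].to_numpy()
        else:
            specs = [
                amplitude_spectrum(detrend(y, detrend_method), frame_interval)["amplitude"].to_numpy()
                for y in ys
            ]
            amp = np.mean(specs, axis=0)
        rows[obin] = amp
        counts[obin] = len(ys)
    out = pd.DataFrame(rows, index=freqs).T
    out.index.name = "offset_um"
    out.columns.name = "freq_hz"
    out.attrs["counts"] = counts
    out.attrs["detrend"] = detrend_method
    return out


def dampening_percent(
    osc_map: pd.DataFrame,
    f0: float = 0.008,
    depth_a: float = 0.0,
    depth_b: float = -4.0,
) -> float:
    """Percent amplitude decrease at ``depth_a`` relative to ``depth_b``.

    100·(amp(b, f0) − amp(a, f0)) / amp(b, f0) with a = nuclear midplane
    (0 µm) and b = 4 µm basal by default: positive when oscillations are
    dampened at the midplane compared with basal regions.  NaN (flagged)
    when the reference amplitude is 0.
    """
    if not len(osc_map):
        raise ValueError("empty oscillation map")
    offs = osc_map.index.to_numpy(dtype=float)
    freqs = osc_map.columns.to_numpy(dtype=float)
    ia = int(np.argmin(np.abs(offs - depth_a)))
    ib = int(np.argmin(np.abs(offs - depth_b)))
    jf = int(np.argmin(np.abs(freqs - f0)))
    amp_a = float(osc_map.iloc[ia, jf])
    amp_b = float(osc_map.iloc[ib, jf])
    if amp_b == 0:
        return float("nan")
    return 100.0 * (amp_b - amp_a) / amp_b
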