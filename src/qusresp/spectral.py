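"""Per-window spectral analysis: MBF/SS/SI line fits, Gaussian form-factor
scatterer-size and acoustic-concentration estimates, scatterer-spacing
estimation, and depth-resolved attenuation estimation.

Windows are 2 x 2 mm RF blocks slid over a region of interest.  Each
window's power spectrum is the average of per-line mean-removed,
Hann-tapered periodograms, normalized by a reference power spectral
density (the analytic pulse spectrum by default; a measured reference can
be substituted) and expressed in dB.  The analysis band is the reference
-6 dB band intersected with [1 MHz, 0.8 x Nyquist].

All estimators are deterministic given a frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from .rf_io import RFFrame, ROISet
from .rf_simulator import GAUSS_FF_COEF, Pulse

__all__ = [
    "Window", "WindowGrid", "NormalizedSpectrum", "SpectralFit",
    "ScattererEstimate", "SASEstimate", "ACEEstimate",
    "tile_windows", "normalized_spectrum", "average_spectrum",
    "fit_spectral_params", "fit_form_factor", "estimate_sas",
    "estimate_ace", "compensate_attenuation",
]


@dataclass(frozen=True)
class Window:
    """One RF analysis window (sample-grid spans and centre depth)."""

    ax_start: int
    lat_start: int
    ax_len: int
    lat_len: int
    depth_cm: float


@dataclass
class WindowGrid:
    windows: List[Window]
    window_size_mm: float
    overlap_fraction: float
    ax_step: int
    lat_step: int

    def __len__(self) -> int:
        return len(self.windows)


def tile_windows(roi, frame: RFFrame, window_mm: float = 2.0,
                 overlap: float = 0.94, inclusion_threshold: float = 0.9,
                 which: str = "core") -> WindowGrid:
    """Sliding-window grid restricted to an ROI mask.

    Axial window length is ``round(window_mm * 2 * fs / c)`` samples
    (about 104 at the 40 MHz / 1540 m/s defaults), lateral length
    ``round(window_mm / line_pitch)`` lines; the step per axis is
    ``max(1, round((1 - overlap) * length))``.  Windows whose footprint is
    at least ``inclusion_threshold`` inside the mask are kept.
    """
    if isinstance(roi, ROISet):
        mask = roi.core_mask if which == "core" else roi.margin_mask
    else:
        mask = np.asarray(roi, dtype=bool)
    if mask.shape != frame.samples.shape:
        raise ValueError("ROI mask must be aligned to the frame grid")

    ax_len = int(round(window_mm * 1e-3 * 2.0 * frame.fs / frame.sound_speed))
    lat_len = max(1, int(round(window_mm * 1e-3 / frame.line_pitch)))
    ax_step = max(1, int(round((1.0 - overlap) * ax_len)))
    lat_step = max(1, int(round((1.0 - overlap) * lat_len)))

    grid = WindowGrid([], window_mm, overlap, ax_step, lat_step)
    n_ax, n_lat = mask.shape
    if ax_len > n_ax or lat_len > n_lat or not mask.any():
        warnings.warn("ROI smaller than one analysis window; empty grid",
                      stacklevel=2)
        return grid

    # Integral image for O(1) coverage queries.
    ii = np.zeros((n_ax + 1, n_lat + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    footprint = ax_len * lat_len
    for i0 in range(0, n_ax - ax_len + 1, ax_step):
        i1 = i0 + ax_len
        for j0 in range(0, n_lat - lat_len + 1, lat_step):
            j1 = j0 + lat_len
            covered = ii[i1, j1] - ii[i0, j1] - ii[i1, j0] + ii[i0, j0]
            if covered >= inclusion_threshold * footprint:
                depth_cm = ((i0 + ax_len / 2.0) * frame.axial_pitch) * 100.0
                grid.windows.append(Window(i0, j0, ax_len, lat_len, depth_cm))
    if not grid.windows:
        warnings.warn("no window met the ROI inclusion threshold",
                      stacklevel=2)
    return grid


@dataclass
class NormalizedSpectrum:
    """Reference-normalized window power spectrum on the analysis band.

    ``taper_len`` / ``nfft`` record the periodogram geometry so that
    estimators can model the taper-induced spectral coherence.
    """

    freqs_mhz: np.ndarray
    power_db: np.ndarray
    band_mhz: Tuple[float, float]
    centre_frequency_mhz: float
    window_depth_cm: float
    taper_len: Optional[int] = None
    nfft: Optional[int] = None

    def __post_init__(self):
        lo, hi = self.band_mhz
        if not lo < self.centre_frequency_mhz < hi:
            raise ValueError("centre frequency must lie inside the band")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("power must be finite on the band")


def _raw_periodogram(block: np.ndarray, nfft: int) -> np.ndarray:
    """Average of per-line mean-removed, Hann-tapered periodograms."""
    taper = hann(block.shape[0], sym=False)
    x = (block - block.mean(axis=0, keepdims=True)) * taper[:, None]
    return np.mean(np.abs(rfft(x, nfft, axis=0)) ** 2, axis=1)


def _band_and_ref(reference: Pulse, frame: RFFrame, nfft: int):
    freqs = rfftfreq(nfft, 1.0 / frame.fs)
    b_lo, b_hi = reference.band
    lo = max(b_lo, 1e6)
    hi = min(b_hi, 0.8 * frame.fs / 2.0)
    if hi <= lo:
        raise ValueError("empty analysis band")
    sel = (freqs >= lo) & (freqs <= hi)
    ref_psd = reference.analytic_psd(freqs[sel])
    if np.any(ref_psd <= 0):
        raise ValueError("reference PSD must be positive on the band")
    return freqs, sel, ref_psd, (lo, hi)


def normalized_spectrum(window: Window, frame: RFFrame, reference: Pulse,
                        nfft: int = 1024) -> NormalizedSpectrum:
    """Normalized power spectrum of one window, in dB re reference."""
    block = frame.samples[window.ax_start:window.ax_start + window.ax_len,
                          window.lat_start:window.lat_start + window.lat_len]
    if block.shape[1] < 2:
        warnings.warn("window holds a single line; using its periodogram "
                      "alone", stacklevel=2)
    nfft = max(nfft, next_fast_len(window.ax_len))
    power = _raw_periodogram(block, nfft)
    freqs, sel, ref_psd, (lo, hi) = _band_and_ref(reference, frame, nfft)
    ratio = np.maximum(power[sel], np.finfo(float).tiny) / ref_psd
    return NormalizedSpectrum(
        freqs_mhz=freqs[sel] * 1e-6,
        power_db=10.0 * np.log10(ratio),
        band_mhz=(lo * 1e-6, hi * 1e-6),
        centre_frequency_mhz=frame.centre_frequency * 1e-6,
        window_depth_cm=window.depth_cm,
        taper_len=window.ax_len, nfft=nfft)


def average_spectrum(windows: Sequence[Window], frame: RFFrame,
                     reference: Pulse, nfft: int = 1024) -> NormalizedSpectrum:
    """Linear-power average of many window spectra (one frame).

    Averaging before the nonlinear parameter fits suppresses speckle
    variance; used by the recovery harnesses and frame-level estimates.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    nfft = max(nfft, next_fast_len(windows[0].ax_len))
    acc = None
    for w in windows:
        block = frame.samples[w.ax_start:w.ax_start + w.ax_len,
                              w.lat_start:w.lat_start + w.lat_len]
        p = _raw_periodogram(block, nfft)
        acc = p if acc is None else acc + p
    power = acc / len(windows)
    freqs, sel, ref_psd, (lo, hi) = _band_and_ref(reference, frame, nfft)
    ratio = np.maximum(power[sel], np.finfo(float).tiny) / ref_psd
    depth = float(np.mean([w.depth_cm for w in windows]))
    return NormalizedSpectrum(
        freqs_mhz=freqs[sel] * 1e-6,
        power_db=10.0 * np.log10(ratio),
        band_mhz=(lo * 1e-6, hi * 1e-6),
        centre_frequency_mhz=frame.centre_frequency * 1e-6,
        window_depth_cm=depth,
        taper_len=windows[0].ax_len, nfft=nfft)


# ---------------------------------------------------------------------------
# Line fit: midband fit / spectral slope / 0-MHz intercept

@dataclass
class SpectralFit:
    mbf: float      # dB at the centre frequency
    ss: float       # dB/MHz
    si: float       # dB at 0 MHz
    r2: float


def fit_spectral_params(spec: NormalizedSpectrum) -> SpectralFit:
    """Ordinary least squares of power (dB) against frequency (MHz).

    SS is the slope, SI the 0-MHz intercept, and MBF the fitted value at
    the centre frequency, so ``mbf == ss * f_c + si`` holds exactly.
    """
    f, y = spec.freqs_mhz, spec.power_db
    if len(f) < 5:
        raise ValueError("need at least 5 frequency bins on the band")
    if f.max() - f.min() <= 0:
        raise ValueError("degenerate analysis band")
    ss, si = np.polyfit(f, y, 1)
    resid = y - (ss * f + si)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / tss) if tss > 0 else 1.0
    return SpectralFit(mbf=float(ss * spec.centre_frequency_mhz + si),
                       ss=float(ss), si=float(si), r2=r2)


# ---------------------------------------------------------------------------
# Gaussian form-factor fit: scatterer diameter and acoustic concentration

@dataclass
class ScattererEstimate:
    asd: float            # um
    aac: float            # dB (10*log10 of concentration, arbitrary ref)
    fit_residual: float
    clipped: bool = False


def fit_form_factor(spec: NormalizedSpectrum, sound_speed: float = 1540.0,
                    search_range_um: Tuple[float, float] = (10.0, 500.0),
                    rayleigh_prefactor: bool = False) -> ScattererEstimate:
    """Fit the Gaussian form-factor backscatter model to a window spectrum.

    Model (linear power): ``S(f) = C * exp(-0.827 * k^2 * (asd/2)^2)`` with
    ``k = 2*pi*f/c``; with ``rayleigh_prefactor`` the classical ``f^4``
    Rayleigh term multiplies the model (the frame simulator offers the
    matching convention).  The fit linearizes by regressing ``ln S``
    (minus ``4 ln f`` if applicable) on ``k^2``, then polishes ``asd`` by
    bounded golden-section search (1 um tolerance) on the linear-power
    residual.  A non-negative slope carries no size information: ``asd``
    is set to the lower search bound and flagged.
    """
    f_hz = spec.freqs_mhz * 1e6
    k2 = (2.0 * math.pi * f_hz / sound_speed) ** 2
    S = 10.0 ** (spec.power_db / 10.0)
    y = np.log(S)
    if rayleigh_prefactor:
        y = y - 4.0 * np.log(f_hz)
    slope, intercept = np.polyfit(k2, y, 1)
    lo, hi = search_range_um

    def model_gain(asd_um: float) -> np.ndarray:
        g = np.exp(-GAUSS_FF_COEF * k2 * (asd_um * 1e-6 / 2.0) ** 2)
        if rayleigh_prefactor:
            g = g * f_hz ** 4
        return g

    def sse_and_c(asd_um: float):
        g = model_gain(asd_um)
        c = float(np.dot(S, g) / np.dot(g, g))
        return float(np.sum((S - c * g) ** 2)), c

    if slope >= 0.0:
        sse, c = sse_and_c(lo)
        return ScattererEstimate(asd=lo, aac=10.0 * math.log10(max(c, 1e-300)),
                                 fit_residual=sse, clipped=True)

    asd0 = 2.0 * math.sqrt(-slope / GAUSS_FF_COEF) * 1e6
    clipped = not (lo <= asd0 <= hi)
    asd0 = min(max(asd0, lo), hi)
    res = minimize_scalar(lambda a: sse_and_c(a)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1.0})
    asd = float(res.x) if res.fun <= sse_and_c(asd0)[0] else asd0
    sse, c = sse_and_c(asd)
    return ScattererEstimate(asd=asd, aac=10.0 * math.log10(max(c, 1e-300)),
                             fit_residual=sse, clipped=clipped)


# ---------------------------------------------------------------------------
# Scatterer spacing from spectral ripple

@dataclass
class SASEstimate:
    sas: float               # um
    peak_prominence: float
    present: bool = True


def _taper_coherence(taper_len: int, nfft: int, n_lags: int) -> np.ndarray:
    """Expected speckle autocorrelation of a Hann-tapered periodogram.

    For a diffuse (smooth-spectrum) process the periodogram values at
    frequency separation ``l`` bins are correlated with coefficient
    ``|A(l)|^2`` where ``A`` is the normalized DFT of the squared taper;
    subtracting this known curve removes the spurious low-lag structure
    that pure speckle imprints on the spectral autocorrelation.
    """
    w2 = hann(taper_len, sym=False) ** 2
    A = np.fft.rfft(w2, nfft)
    coh = np.abs(A / A[0]) ** 2
    out = np.zeros(n_lags)
    m = min(n_lags, len(coh) - 1)
    out[:m] = coh[1:m + 1]
    return out


def estimate_sas(spec: NormalizedSpectrum, sound_speed: float = 1540.0,
                 sas_range_um: Tuple[float, float] = (250.0, 2500.0),
                 prominence_threshold: float = 0.40) -> SASEstimate:
    """Dominant quasi-regular scatterer spacing from spectral ripple.

    Regular spacing ``d`` imprints a ripple of period ``df = c / (2 d)``
    on the power spectrum.  The estimator autocorrelates the linearly
    detrended linear-power spectrum over the band, subtracts the
    analytically known taper-coherence curve (the autocorrelation pure
    speckle would produce), and takes the lag of the highest positive
    local maximum — preferring a subharmonic lag when one carries at
    least half the peak value, which suppresses harmonic picking —
    refined by parabolic interpolation; ``sas = c / (2 df)``.  Lags are
    searched only where they map into ``sas_range_um``.  Without a peak
    above ``prominence_threshold`` (in units of the spectral variance)
    the band-limited default is returned with an absent flag.
    """
    f = spec.freqs_mhz
    if f.max() - f.min() < 2.0:
        raise ValueError("analysis band must span at least 2 MHz")
    S = 10.0 ** (spec.power_db / 10.0)
    trend = np.polyval(np.polyfit(f, S, 1), f)
    s0 = S - trend
    denom = float(np.dot(s0, s0))
    df = float(f[1] - f[0])
    c_um = sound_speed  # c[m/s] / (2 * df[MHz]) is directly in um
    lag_lo = max(2, int(math.ceil(c_um / (2.0 * sas_range_um[1]) / df)))
    lag_hi = min(len(s0) - 2,
                 int(math.floor(c_um / (2.0 * sas_range_um[0]) / df)))
    default = SASEstimate(
        sas=float(np.clip(c_um / (2.0 * (f.max() - f.min())),
                          *sas_range_um)),
        peak_prominence=0.0, present=False)
    if denom <= 0 or lag_hi <= lag_lo:
        return default
    lags = np.arange(1, len(s0))
    r = np.array([np.dot(s0[:-l], s0[l:]) for l in lags]) / denom
    if spec.taper_len is not None and spec.nfft is not None:
        r = r - _taper_coherence(spec.taper_len, spec.nfft, len(r))
    in_range = (lags >= lag_lo) & (lags <= lag_hi)
    peaks, _ = find_peaks(r)
    peaks = [p for p in peaks if in_range[p] and r[p] > 0]
    if not peaks:
        return default
    best = max(peaks, key=lambda p: r[p])
    prom = float(r[best])
    # prefer the fundamental when the winner is its second harmonic
    for p in peaks:
        if abs(lags[p] - lags[best] / 2.0) <= 1.5 and r[p] >= 0.5 * prom:
            best, prom = p, float(r[p])
            break
    if prom < prominence_threshold:
        default.peak_prominence = prom
        return default
    # parabolic sub-bin refinement around the peak
    l0 = lags[best]
    if 0 < best < len(r) - 1:
        y0, y1, y2 = r[best - 1], r[best], r[best + 1]
        denom2 = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
        l0 = l0 + float(np.clip(shift, -0.5, 0.5))
    delta_f = l0 * df                       # MHz
    sas = c_um / (2.0 * delta_f)            # um
    if not sas_range_um[0] <= sas <= sas_range_um[1]:
        default.peak_prominence = prom
        return default
    return SASEstimate(sas=float(sas), peak_prominence=prom, present=True)


# ---------------------------------------------------------------------------
# Attenuation coefficient estimate (spectral difference across depth)

@dataclass
class ACEEstimate:
    ace: float               # dB/cm/MHz
    n_depth_windows: int


def estimate_ace(spectra: Sequence[NormalizedSpectrum],
                 min_depth_span_cm: float = 1.0) -> ACEEstimate:
    """Attenuation from depth-dependent spectral decay.

    For each band frequency the normalized power (dB) is regressed against
    window depth (cm) giving a decay rate ``s(f)`` in dB/cm; the slope of
    ``s(f)`` against frequency (MHz) equals ``-2 * ace`` (round-trip).
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 windows across depth")
    depths = np.array([s.window_depth_cm for s in spectra])
    if depths.max() - depths.min() < min_depth_span_cm:
        raise ValueError(
            f"depth span {depths.max() - depths.min():.2f} cm is below the "
            f"required {min_depth_span_cm:g} cm")
    f = spectra[0].freqs_mhz
    for s in spectra[1:]:
        if not np.allclose(s.freqs_mhz, f):
            raise ValueError("spectra must share one frequency grid")
    P = np.stack([s.power_db for s in spectra])       # (n_depth, n_freq)
    design = np.column_stack([depths, np.ones_like(depths)])
    coefs, *_ = np.linalg.lstsq(design, P, rcond=None)
    s_f = coefs[0]                                    # dB/cm per frequency
    slope, _ = np.polyfit(f, s_f, 1)                  # dB/cm/MHz
    return ACEEstimate(ace=float(-slope / 2.0), n_depth_windows=len(spectra))


def compensate_attenuation(spec: NormalizedSpectrum, ace: float,
                           reference_depth_cm: float) -> NormalizedSpectrum:
    """First-order round-trip attenuation compensation of one spectrum.

    Adds ``2 * ace * f * (z - z_ref)`` dB so that spectra at different
    depths are comparable; off by default in the pipeline (the flag is a
    configuration choice).
    """
    dz = spec.window_depth_cm - reference_depth_cm
    corr = 2.0 * ace * spec.freqs_mhz * dz
    return NormalizedSpectrum(
        freqs_mhz=spec.freqs_mhz.copy(),
        power_db=spec.power_db + corr,
        band_mhz=spec.band_mhz,
        centre_frequency_mhz=spec.centre_frequency_mhz,
        window_depth_cm=spec.window_depth_cm)
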