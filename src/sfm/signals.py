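"""Band-limited analytic signals and phase-coupling FC metrics.

Real time series (empirical source reconstructions or simulated signals) are
bandpass filtered, Hilbert transformed into the analytic representation
A_m(t) = r_m(t) exp(i phi_m(t)), and pairwise cross-spectra
s_mn(t) = A_m(t) conj(A_n(t)) are formed. From these, six functional
connectivity metrics are computed, differing in how they weight amplitude
versus phase and whether they discard zero-phase-lag (instantaneous)
coupling, which in sensor-space EEG is contaminated by volume conduction:

- COH: magnitude of the time-averaged cross-spectrum normalized by the two
  auto-spectra (standard coherence; amplitude- and phase-sensitive).
- COH_instant: magnitude of the time average of the *instantaneously*
  normalized cross-spectrum. This is the coherence formula as often written
  with the normalization inside the average; it reduces algebraically to the
  PLV and is provided to document that degeneracy.
- PLV: phase locking value, |<exp(i(phi_m - phi_n))>_t|; amplitude-blind.
- ICOH: absolute imaginary part of the complex coherency; discards the real
  part, in which zero-lag volume-conduction artifacts live exclusively.
- PLI: phase lag index, |<sgn(Im s_mn(t))>_t|; fully robust to zero-lag
  mixing, amplitude-blind.
- WPLI: weighted PLI, |<Im s_mn>_t| / <|Im s_mn|>_t; like PLI but more
  robust to noise under weak synchronization.
- LPC: lagged phase coherence, Im(C)^2 / (1 - Re(C)^2) for complex
  coherency C; the zero-lag contribution is partialled out via a quotient
  of residual variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

METRICS = ("coh", "coh_instant", "plv", "icoh", "pli", "wpli", "lpc")

#: metrics whose diagonal is identically 1 (the rest have zero diagonal)
_UNIT_DIAG = {"coh", "coh_instant", "plv"}


@dataclass
class AnalyticSignalSet:
    """Per-region analytic amplitude r_m(t) and phase phi_m(t)."""

    amplitude: np.ndarray  # (N, T), >= 0
    phase: np.ndarray  # (N, T), rad
    sample_rate: float
    band_center: float
    bandwidth: float

    def __post_init__(self):
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have identical shape")
        if self.amplitude.shape[0] < 2:
            raise ValueError("need at least two channels")

    @property
    def analytic(self) -> np.ndarray:
        """Complex analytic signals A = r exp(i phi)."""
        return self.amplitude * np.exp(1j * self.phase)


def bandpass_sos(sample_rate: float, band_center: float, bandwidth: float):
    lo = band_center - bandwidth / 2.0
    hi = band_center + bandwidth / 2.0
    nyq = sample_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(
            f"band {lo:g}-{hi:g} Hz must lie strictly inside (0, {nyq:g}) Hz"
        )
    return butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def to_analytic(
    x: np.ndarray,
    sample_rate: float,
    band_center: float = 8.0,
    bandwidth: float = 4.0,
) -> AnalyticSignalSet:
    """Zero-phase bandpass then Hilbert transform of N x T real signals.

    The filter is an order-4 Butterworth bandpass applied forward and
    backward (zero phase distortion). One effective filter length of samples
    is trimmed from each edge to drop the filter and Hilbert transients.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sos = bandpass_sos(sample_rate, band_center, bandwidth)
    filtered = sosfiltfilt(sos, x, axis=-1)
    analytic = hilbert(filtered, axis=-1)

    trim = int(np.ceil(4.0 * sample_rate / bandwidth))  # effective filter length
    t_kept = x.shape[-1] - 2 * trim
    min_t = int(np.ceil(2.0 * sample_rate / bandwidth))
    if t_kept < min_t:
        raise ValueError(
            f"only {t_kept} samples remain after edge trimming; "
            f"need at least {min_t} (2 x sample_rate / bandwidth)"
        )
    analytic = analytic[:, trim:-trim]
    return AnalyticSignalSet(
        amplitude=np.abs(analytic),
        phase=np.angle(analytic),
        sample_rate=sample_rate,
        band_center=band_center,
        bandwidth=bandwidth,
    )


def _mean_spectra(A: np.ndarray):
    """Time-averaged cross-spectra <s_mn>_t and auto-spectra <s_mm>_t."""
    T = A.shape[1]
    cross = (A @ A.conj().T) / T
    auto = np.real(np.diag(cross)).copy()
    return cross, auto


def compute_fc_metric(aset: AnalyticSignalSet, metric: str = "coh") -> np.ndarray:
    """Compute one phase-coupling FC metric as an N x N matrix in [0, 1].

    COH, COH_instant and PLV have unit diagonal; ICOH, PLI, WPLI and LPC
    have zero diagonal (a channel has no lag with itself). Channels with
    identically zero amplitude are flagged and their rows/columns set to NaN.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")

    A = aset.analytic
    n, T = A.shape
    dead = np.max(aset.amplitude, axis=1) == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-amplitude channel(s); their FC entries are NaN"
        )

    if metric in ("coh", "icoh", "lpc"):
        cross, auto = _mean_spectra(A)
        denom = np.sqrt(np.outer(auto, auto))
        with np.errstate(invalid="ignore", divide="ignore"):
            C = cross / denom  # complex coherency
        if metric == "coh":
            out = np.abs(C)
        elif metric == "icoh":
            out = np.abs(np.imag(C))
        else:  # lpc
            re2 = np.real(C) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.imag(C) ** 2 / (1.0 - re2)
            out[np.isclose(re2, 1.0)] = 0.0
            out = np.clip(out, 0.0, 1.0)
    elif metric in ("plv", "coh_instant"):
        # Eq for COH with the normalization inside the time average reduces
        # to |<exp(i dphi)>|, identical to the PLV.
        with np.errstate(invalid="ignore", divide="ignore"):
            U = np.exp(1j * aset.phase)
        out = np.abs(U @ U.conj().T) / T
    else:  # pli / wpli: need the per-sample imaginary cross-spectrum
        out = np.zeros((n, n))
        for m in range(n - 1):
            s = A[m] * A.conj()[m + 1 :]  # (n-m-1, T)
            im = s.imag
            # sgn(0) = 0; rounding noise in Im(s) of numerically real
            # cross-spectra counts as zero
            im = np.where(np.abs(im) > 1e-12 * np.abs(s), im, 0.0)
            if metric == "pli":
                row = np.abs(np.mean(np.sign(im), axis=1))
            else:
                num = np.abs(np.mean(im, axis=1))
                den = np.mean(np.abs(im), axis=1)
                row = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
            out[m, m + 1 :] = row
        out = out + out.T

    out = np.clip(0.5 * (out + out.T), 0.0, 1.0)
    np.fill_diagonal(out, 1.0 if metric in _UNIT_DIAG else 0.0)
    if np.any(dead):
        out[dead, :] = np.nan
        out[:, dead] = np.nan
    return out


def fc_from_sar(correlation: np.ndarray) -> np.ndarray:
    """Model FC from the SAR correlation matrix.

    The SAR model is static, so its correlation matrix passes through
    unchanged as the predicted FC; absolute values map it onto the [0, 1]
    scale of the phase-coupling metrics.
    """
    return np.abs(np.asarray(correlation, dtype=float))
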