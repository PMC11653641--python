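"""Classical inverse solutions used as comparison methods.

Three estimators share the lead field and produce :class:`SourceEstimate`
objects comparable with the network output:

* sLORETA -- the minimum-norm solution standardized by the diagonal of its
  resolution matrix; zero localization error for noiseless point sources.
* LCMV -- a unit-gain minimum-variance beamformer on the diagonally loaded
  data covariance.
* FDI -- frequency-domain imaging: sLORETA applied to the real and
  imaginary Fourier topographies at the dominant ictal frequency, combined
  as the complex magnitude.

For the time-domain methods the ictal convention is to average the
per-time-point maps at the peaks of the dominant oscillation, which raises
the effective SNR of the spatial map.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator

from .head_model import LeadField
from .network import SourceEstimate

__all__ = [
    "SLORETA",
    "LCMVBeamformer",
    "FrequencyDomainImager",
    "sloreta_map",
    "lcmv_map",
    "fdi_map",
    "detect_oscillation_peaks",
    "peak_averaged_map",
    "max_energy_channel",
]


def _auto_lambda(L: np.ndarray, snr_amplitude: float = 3.0) -> float:
    """Default Tikhonov parameter: sensor-space power over assumed SNR^2."""
    return float(np.trace(L @ L.T) / (L.shape[0] * snr_amplitude**2))


class SLORETA(BaseEstimator):
    """Standardized low-resolution electromagnetic tomography.

    Parameters
    ----------
    leadfield : LeadField
    lam : float or "auto"
        Tikhonov regularization of the sensor-space Gram matrix; "auto"
        scales with the lead-field power and an assumed amplitude SNR.
    snr_amplitude : float
        Assumed amplitude SNR for the automatic rule.
    """

    def __init__(self, leadfield: LeadField, lam="auto", snr_amplitude=3.0):
        self.leadfield = leadfield
        self.lam = lam
        self.snr_amplitude = snr_amplitude

    def fit(self, X=None, y=None):
        L = self.leadfield.matrix
        lam = _auto_lambda(L, self.snr_amplitude) if self.lam == "auto" else float(self.lam)
        gram = L @ L.T + lam * np.eye(L.shape[0])
        kernel = L.T @ np.linalg.pinv(gram, hermitian=True)
        resolution = np.einsum("ij,ji->i", kernel, L)
        if np.any(resolution <= 0):
            raise np.linalg.LinAlgError(
                "singular regularized Gram matrix: nonpositive resolution diagonal"
            )
        self.lambda_ = lam
        self.kernel_ = kernel
        self.norm_ = 1.0 / np.sqrt(resolution)
        return self

    def transform(self, sensors: np.ndarray) -> np.ndarray:
        """Standardized source amplitudes (regions x time)."""
        if not hasattr(self, "kernel_"):
            self.fit()
        return self.norm_[:, None] * (self.kernel_ @ np.atleast_2d(sensors))

    predict = transform


class LCMVBeamformer(BaseEstimator):
    """Unit-gain linearly constrained minimum-variance beamformer.

    ``fit(X)`` estimates the sensor covariance from the data window (at
    least ``n_channels`` samples recommended) and diagonally loads it by a
    fraction of its mean eigenvalue before inversion.
    """

    def __init__(self, leadfield: LeadField, loading=0.05):
        self.leadfield = leadfield
        self.loading = loading

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        cov = X @ X.T / X.shape[1]
        mean_eig = np.trace(cov) / cov.shape[0]
        if self.loading == 0 and np.linalg.matrix_rank(cov) < cov.shape[0]:
            raise np.linalg.LinAlgError(
                "rank-deficient covariance; use diagonal loading"
            )
        cov_loaded = cov + self.loading * mean_eig * np.eye(cov.shape[0])
        cinv = np.linalg.pinv(cov_loaded, hermitian=True)
        L = self.leadfield.matrix
        CiL = cinv @ L
        denom = np.einsum("ij,ij->j", L, CiL)
        self.weights_ = CiL / denom  # channels x regions, w_i^T l_i = 1
        self.cov_ = cov
        self.power_ = np.einsum(
            "ij,jk,ik->i", self.weights_.T, cov, self.weights_.T
        )
        return self

    def transform(self, sensors: np.ndarray) -> np.ndarray:
        return self.weights_.T @ np.atleast_2d(sensors)

    predict = transform


class FrequencyDomainImager(BaseEstimator):
    """sLORETA on the complex Fourier topography at one frequency."""

    def __init__(self, leadfield: LeadField, lam="auto", snr_amplitude=3.0):
        self.leadfield = leadfield
        self.lam = lam
        self.snr_amplitude = snr_amplitude

    def fit(self, X=None, y=None):
        self.sloreta_ = SLORETA(self.leadfield, self.lam, self.snr_amplitude).fit()
        return self

    def map(self, sensors: np.ndarray, frequency: float, sample_rate: float):
        """Complex per-region coefficients at the Fourier bin nearest
        ``frequency``; the spatial map is their magnitude."""
        if not hasattr(self, "sloreta_"):
            self.fit()
        sensors = np.atleast_2d(np.asarray(sensors, float))
        if frequency > sample_rate / 2:
            raise ValueError("frequency above Nyquist")
        spec = np.fft.rfft(sensors, axis=1)
        freqs = np.fft.rfftfreq(sensors.shape[1], d=1.0 / sample_rate)
        k = int(np.argmin(np.abs(freqs - frequency)))
        s_re = self.sloreta_.transform(spec[:, k].real[:, None])[:, 0]
        s_im = self.sloreta_.transform(spec[:, k].imag[:, None])[:, 0]
        return s_re + 1j * s_im, float(freqs[k])


def sloreta_map(sensors, lf: LeadField, lam="auto") -> SourceEstimate:
    wave = SLORETA(lf, lam).fit().transform(sensors)
    return SourceEstimate(wave, provenance={"method": "sloreta"})


def lcmv_map(sensors, lf: LeadField, loading=0.05) -> SourceEstimate:
    est = LCMVBeamformer(lf, loading).fit(sensors)
    out = SourceEstimate(est.transform(sensors), provenance={"method": "lcmv"})
    return out


def fdi_map(sensors, lf: LeadField, major_frequency: float,
            sample_rate: float, lam="auto") -> SourceEstimate:
    """Frequency-domain image combined as the complex magnitude per region.

    The returned waveforms are the rank-one sinusoidal reconstruction at
    the selected bin (real part driving cos, imaginary part sin); the
    energy map is the squared magnitude, so peak locations depend only on
    the magnitude, not the phase.
    """
    sensors = np.atleast_2d(np.asarray(sensors, float))
    n = sensors.shape[1]
    if n < 2 * sample_rate / max(major_frequency, 1e-12):
        raise ValueError("segment shorter than two cycles of the major frequency")
    imager = FrequencyDomainImager(lf, lam).fit()
    coeff, f_used = imager.map(sensors, major_frequency, sample_rate)
    t = np.arange(n) / sample_rate
    wave = (coeff.real[:, None] * np.cos(2 * np.pi * f_used * t)
            + coeff.imag[:, None] * np.sin(2 * np.pi * f_used * t))
    est = SourceEstimate(
        wave, energy_map=np.abs(coeff) ** 2,
        provenance={"method": "fdi", "frequency": f_used},
    )
    return est


def max_energy_channel(sensors: np.ndarray) -> int:
    """Channel with the maximum sum of squared values."""
    return int(np.argmax(np.sum(np.asarray(sensors, float) ** 2, axis=1)))


def detect_oscillation_peaks(trace: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict interior local maxima above ``threshold`` x the global maximum.

    Intended for the narrowband-filtered channel with the maximum energy;
    an empty result is allowed (e.g. for monotone input).
    """
    trace = np.asarray(trace, float)
    peaks, _ = sp_signal.find_peaks(trace)
    if peaks.size == 0:
        return peaks
    return peaks[trace[peaks] > threshold * trace.max()]


def peak_averaged_map(maps: np.ndarray, peak_indices) -> np.ndarray:
    """Mean of the absolute per-time-point maps at the oscillation peaks.

    Absolute values avoid cancellation between peaks of alternating
    polarity.  ``maps`` is regions x time.
    """
    peak_indices = np.asarray(peak_indices, int)
    if peak_indices.size == 0:
        raise ValueError("peak set is empty")
    return np.mean(np.abs(np.asarray(maps, float)[:, peak_indices]), axis=1)
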