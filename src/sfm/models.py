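"""Network models of functional connectivity: SAR and delayed Kuramoto.

Two generative models map a structural connectivity matrix S onto predicted
functional connectivity.

The spatial autoregressive (SAR) model treats each region's activity as a
linear combination of all other regions plus independent Gaussian noise,

    y = k S y + sigma nu,

whose equilibrium solution y = sigma (I - kS)^-1 nu has covariance
sigma^2 Q Q^T with Q = (I - kS)^-1. The pairwise correlation matrix derived
from that covariance is the model FC; it is static (no temporal dynamics)
and available in closed form, which makes exhaustive parameter grids cheap.

The Kuramoto model couples phase oscillators through the sine of their phase
differences with conduction delays, combining a fixed per-node delay d with
a distance-dependent term D_ij / v (fiber distance over transmission
velocity):

    dphi_j/dt = 2 pi omega - k sum_{i != j} S_ij sin(phi_j(t) - phi_i(t - d - D_ij/v)).

It is integrated with the Euler method at 0.1 ms steps; the resulting phase
trajectories are turned into unit-amplitude signals cos(phi) and passed
through the same bandpass/analytic-signal/coherence path as empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome
from .geometry import ROIGeometry


class UnstableCouplingError(ValueError):
    """Raised when the spectral radius of k*S reaches 1 (SAR has no equilibrium)."""


@dataclass
class SARParams:
    """SAR model parameters: global coupling scale k and noise scale sigma."""

    k: float = 0.65
    sigma: float = 1.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SARResult:
    """Closed-form SAR solution: Q = (I - kS)^-1, covariance and correlation."""

    Q: np.ndarray
    covariance: np.ndarray
    correlation: np.ndarray


def sar_spectral_radius(S: np.ndarray, k: float) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(k * np.asarray(S, dtype=float)))))


def sar_correlation(sc: StructuralConnectome | np.ndarray, params: SARParams) -> SARResult:
    """Solve the SAR model analytically on S.

    Returns Q = (I - kS)^-1, Cov = sigma^2 Q Q^T (the noise covariance is
    sigma^2 I for uncorrelated Gaussian noise), and the correlation matrix
    Corr_ij = Cov_ij / sqrt(Cov_ii Cov_jj), which normalizes away the
    per-node variance and is independent of sigma.
    """
    S = sc.S if isinstance(sc, StructuralConnectome) else np.asarray(sc, dtype=float)
    n = S.shape[0]
    rho = sar_spectral_radius(S, params.k)
    if rho >= 1.0:
        raise UnstableCouplingError(
            f"spectral radius of k*S is {rho:.4f} >= 1: SAR equilibrium does not exist"
        )
    Q = np.linalg.solve(np.eye(n) - params.k * S, np.eye(n))
    cov = params.sigma**2 * (Q @ Q.T)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return SARResult(Q=Q, covariance=cov, correlation=corr)


@dataclass
class KuramotoParams:
    """Delayed-Kuramoto parameters.

    omega is the common intrinsic frequency in Hz (default 8 Hz, the center
    of the analyzed alpha band); d a fixed delay in ms; v the transmission
    velocity in m/s converting fiber distance (mm) into a connection-specific
    delay D_ij/v in ms; dt the Euler step in ms; duration/burn_in in s;
    noise_sd an optional phase-noise standard deviation per sqrt(step), in
    rad (default 0: the model itself is deterministic).
    """

    k: float = 700.0
    omega: float = 8.0
    d: float = 1.25
    v: float = 1.7
    dt: float = 0.1
    duration: float = 30.0
    burn_in: float = 5.0
    sample_rate: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.burn_in:
            raise ValueError("duration must exceed burn_in")
        if not (self.v > 0):  # also rejects nan; np.inf allowed (zero delay)
            raise ValueError("v must be positive")


@dataclass
class PhaseTrajectories:
    """Phase time courses phi_j(t) after burn-in, at sample_rate Hz."""

    phases: np.ndarray  # (N, T)
    sample_rate: float


def simulate_kuramoto(
    sc: StructuralConnectome | np.ndarray,
    geometry: ROIGeometry,
    params: KuramotoParams,
) -> PhaseTrajectories:
    """Euler-integrate the delay-coupled Kuramoto model on S.

    Initial phases are uniform on [0, 2pi) from the seed. Delays
    d + D_ij / v are rounded to the nearest integer multiple of dt. Phases
    earlier than t = 0 are back-extrapolated along the intrinsic drift as
    phi_i(0) - 2 pi omega * |t|. Burn-in is discarded and the trajectory is
    downsampled to ``sample_rate``.
    """
    S = sc.S if isinstance(sc, StructuralConnectome) else np.asarray(sc, dtype=float)
    n = S.shape[0]
    p = params
    dt_s = p.dt * 1e-3

    # delays in ms -> integer steps; D (mm) / v (m/s) = ms
    if np.isinf(p.v):
        delay_ms = np.full((n, n), p.d, dtype=float)
    else:
        delay_ms = p.d + geometry.fiber_dist / p.v
    delay_steps = np.rint(delay_ms / p.dt).astype(np.int64)
    np.fill_diagonal(delay_steps, 0)

    n_steps = int(round(p.duration / dt_s))
    if delay_steps.max() >= n_steps:
        raise ValueError("maximum delay exceeds the simulated duration (history buffer)")

    rng = np.random.default_rng(p.seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=n)

    phases = np.empty((n_steps + 1, n), dtype=float)
    phases[0] = phi0
    drift = 2.0 * np.pi * p.omega

    src = np.arange(n)[:, np.newaxis]  # row i: source oscillator of S_ij
    coupled = p.k != 0 and np.any(S != 0)
    noisy = p.noise_sd > 0

    for t in range(n_steps):
        phi = phases[t]
        if coupled:
            idx = t - delay_steps  # (n, n): delayed time index of source i for target j
            past = np.where(
                idx >= 0,
                phases[np.maximum(idx, 0), src],
                phi0[:, np.newaxis] + drift * (idx * dt_s),
            )
            coupling = np.einsum("ij,ij->j", S, np.sin(phi[np.newaxis, :] - past))
        else:
            coupling = 0.0
        dphi = dt_s * (drift - p.k * coupling)
        if noisy:
            dphi = dphi + p.noise_sd * np.sqrt(dt_s) * rng.standard_normal(n)
        phases[t + 1] = phi + dphi
        if not np.all(np.isfinite(phases[t + 1])):
            raise FloatingPointError(
                f"Kuramoto integration diverged at t = {(t + 1) * dt_s:.4f} s"
            )

    start = int(round(p.burn_in / dt_s))
    stride = max(1, int(round(1.0 / (p.sample_rate * dt_s))))
    fs = 1.0 / (stride * dt_s)
    n_keep = int(round((p.duration - p.burn_in) * fs))
    kept = phases[start::stride][:n_keep].T  # (N, T)
    return PhaseTrajectories(phases=kept, sample_rate=fs)


def phases_to_signals(traj: PhaseTrajectories) -> np.ndarray:
    """Unit-amplitude real signals x_j(t) = cos(phi_j(t)).

    These feed the same bandpass + analytic-signal + coherence path used for
    empirical recordings; with unit amplitudes every phase-coupling metric is
    amplitude-insensitive by construction.
    """
    return np.cos(traj.phases)


KURAMOTO_REFERENCE = dict(k=700.0, h=0.12, v=1.7, d=1.25)
"""Reference Kuramoto operating point (coupling, homotopic fraction,
velocity m/s, fixed delay ms) at which the model performs best on group-level
DTI/EEG data; data-specific, exposed as a named preset."""
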