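"""Source-sensor mapping: forward projection, LCMV and minimum-norm inverses.

EEG sensors see a linear mixture of cortical source activity through the
leadfield (forward model) G. Comparing modeled and empirical connectivity can
be done in sensor space, by projecting model activity through G, or in source
space, by inverting the mixing with a spatial filter. Both directions are
implemented here, together with the leadfield-only baseline: the sensor-space
FC predicted by volume-conduction mixing of *independent* sources, which by
itself explains most sensor-space coherence structure.

The inverse operators follow scikit-learn transformer conventions: they are
constructed with their hyperparameters, ``fit`` estimates the data-dependent
quantities (sensor covariance, spatial filters) storing them in
trailing-underscore attributes, and ``transform`` maps sensor samples to
source samples. ``lcmv_reconstruct`` / ``mne_reconstruct`` are thin
functional wrappers in the domain (channels x time) orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class Leadfield:
    """Gain structure mapping unit dipole moments to sensor signals.

    ``G`` is the free-orientation gain tensor (n_sensors, N, 3); ``G_fixed``
    the (n_sensors, N) gain matrix after fixing each source's dipole
    orientation; ``orientations`` the (N, 3) unit vectors used for fixing.
    At least one of G / G_fixed must be present.
    """

    G: np.ndarray = None
    G_fixed: np.ndarray = None
    orientations: np.ndarray = None

    def __post_init__(self):
        if self.G is None and self.G_fixed is None:
            raise ValueError("need G and/or G_fixed")
        for M in (self.G, self.G_fixed):
            if M is not None:
                if not np.all(np.isfinite(M)):
                    raise ValueError("leadfield must be finite")
                flat = M.reshape(M.shape[0], -1)
                if np.any(np.all(flat == 0, axis=1)):
                    raise ValueError("leadfield has an all-zero sensor row")
        if self.G_fixed is None:
            if self.orientations is None:
                raise ValueError("fixing orientations requires orientation vectors")
            u = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(u, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("orientations must be unit norm")
            self.G_fixed = np.einsum("sni,ni->sn", self.G, u)

    @property
    def n_sensors(self) -> int:
        return self.G_fixed.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G_fixed.shape[1]


@dataclass
class SensorTimeSeries:
    """Multichannel sensor recording, n_sensors x T at sample_rate Hz."""

    data: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sensor data must be finite")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]


def forward_project(source: np.ndarray, G_fixed: np.ndarray) -> np.ndarray:
    """Project source activity or covariance into sensor space.

    An (N, T) time-series matrix maps to G X; an (N, N) symmetric covariance
    maps to G C G^T. The two cases are disambiguated by shape and symmetry.
    """
    G = np.asarray(G_fixed, dtype=float)
    X = np.asarray(source, dtype=float)
    if X.ndim != 2 or X.shape[0] != G.shape[1]:
        raise ValueError(
            f"source has {X.shape} but leadfield expects {G.shape[1]} sources"
        )
    if X.shape[0] == X.shape[1] and np.allclose(X, X.T):
        return G @ X @ G.T
    return G @ X


def leadfield_fc_baseline(G_fixed: np.ndarray) -> np.ndarray:
    """Sensor FC predicted by volume conduction alone.

    Propagating identity source covariance through the leadfield gives
    C = G G^T; correlation-normalizing C yields the sensor-space FC pattern
    produced purely by the mixing matrix, with no source coupling at all.
    """
    G = np.asarray(G_fixed, dtype=float)
    C = G @ G.T
    d = np.diag(C).copy()
    if np.any(d <= 0):
        warnings.warn("zero-variance sensor in leadfield baseline")
        d = np.where(d > 0, d, 1.0)
    return np.abs(C / np.sqrt(np.outer(d, d)))


class LCMVBeamformer(BaseEstimator, TransformerMixin):
    """Linearly constrained minimum-variance spatial filter.

    Reconstructs each source with unit gain while minimizing total output
    variance (and thereby temporal correlation leakage from other sources).
    The sensor covariance C is estimated from the data over a single window
    and regularized by diagonal loading, C + reg_fraction * mean(diag(C)) I.
    With a free-orientation leadfield the per-source orientation is chosen to
    maximize output power via the generalized eigenvalue problem on the
    3-axis gain block; the unit-gain weights are
    w = (g^T C^-1 g)^-1 C^-1 g.

    Follows sklearn conventions: X is (n_samples, n_sensors) in ``fit`` and
    ``transform``; fitted attributes carry a trailing underscore
    (``weights_`` is (N, n_sensors), ``orientations_`` (N, 3) or None).
    """

    def __init__(self, leadfield: Leadfield, reg_fraction: float = 0.05):
        self.leadfield = leadfield
        self.reg_fraction = reg_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.leadfield.n_sensors:
            raise ValueError("X must be (n_samples, n_sensors)")
        if self.reg_fraction < 0:
            raise ValueError("reg_fraction must be nonnegative")
        n_sens = X.shape[1]
        if X.shape[0] < n_sens:
            warnings.warn("fewer samples than sensors: covariance is rank-deficient")
        C = (X.T @ X) / X.shape[0]
        C = C + self.reg_fraction * np.mean(np.diag(C)) * np.eye(n_sens)
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"regularized sensor covariance is singular: {err}"
            ) from err

        lf = self.leadfield
        n_src = lf.n_sources
        W = np.empty((n_src, n_sens))
        orientations = None
        if lf.G is not None:
            orientations = np.empty((n_src, 3))
            for j in range(n_src):
                L = lf.G[:, j, :]  # (n_sensors, 3)
                if np.linalg.matrix_rank(L) < 3:
                    warnings.warn(
                        f"rank-deficient gain block for source {j}; "
                        "falling back to dominant singular vector"
                    )
                    u = np.linalg.svd(L)[2][0]
                else:
                    # output power 1/(u^T M u): maximize by the smallest eigenvector
                    M = L.T @ Cinv @ L
                    w_eig, v_eig = np.linalg.eigh(M)
                    u = v_eig[:, 0]
                orientations[j] = u
                g = L @ u
                cg = Cinv @ g
                W[j] = cg / (g @ cg)
        else:
            for j in range(n_src):
                g = lf.G_fixed[:, j]
                cg = Cinv @ g
                W[j] = cg / (g @ cg)

        self.covariance_ = C
        self.weights_ = W
        self.orientations_ = orientations
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.weights_.T


class MinimumNormEstimate(BaseEstimator, TransformerMixin):
    """Tikhonov-regularized minimum-norm inverse.

    Recovers source activity by minimizing overall source energy subject to
    fitting the data: W = G^T (G G^T + lambda I)^-1 with
    lambda = trace(G G^T) / (n_sensors * snr^2). Unlike the beamformer the
    operator is data-independent, so ``fit`` only assembles W. sklearn
    orientation: X is (n_samples, n_sensors).
    """

    def __init__(self, leadfield: Leadfield, snr: float = 3.0):
        self.leadfield = leadfield
        self.snr = snr

    def fit(self, X=None, y=None):
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        G = self.leadfield.G_fixed
        n_sens = G.shape[0]
        gram = G @ G.T
        lam = np.trace(gram) / (n_sens * self.snr**2)
        self.lambda_ = lam
        self.weights_ = G.T @ np.linalg.inv(gram + lam * np.eye(n_sens))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.weights_.T


def lcmv_reconstruct(
    X: SensorTimeSeries, G: Leadfield, reg_fraction: float = 0.05
) -> np.ndarray:
    """LCMV source reconstruction; returns (N, T) source estimates."""
    bf = LCMVBeamformer(G, reg_fraction=reg_fraction).fit(X.data.T)
    return bf.transform(X.data.T).T


def mne_reconstruct(X: SensorTimeSeries, G: Leadfield, snr: float = 3.0) -> np.ndarray:
    """Minimum-norm source reconstruction; returns (N, T) source estimates."""
    inv = MinimumNormEstimate(G, snr=snr).fit()
    return inv.transform(X.data.T).T
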