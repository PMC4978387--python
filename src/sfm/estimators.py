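"""scikit-learn-style estimators tying the modeling pipeline together.

``StructureFunctionModel`` is the package's central fit object: constructed
with a raw connectome, ROI geometry, a model family (SAR or delayed
Kuramoto) and a parameter grid, its ``fit(fc_emp)`` rebuilds the structural
connectome for every homotopic fraction h, evaluates the model FC at every
grid point, and stores the performance surface, the argmax parameters and
the local (total-least-squares) error analysis in trailing-underscore
attributes. ``ConnectomePreprocessor`` exposes the preprocessing step as a
transformer so the stages compose with sklearn pipelines.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectome import RawConnectome, build_structural_connectome
from .evaluation import FitResult, global_performance, local_error, node_error
from .models import (
    KuramotoParams,
    SARParams,
    UnstableCouplingError,
    phases_to_signals,
    sar_correlation,
    simulate_kuramoto,
)
from .signals import compute_fc_metric, fc_from_sar, to_analytic

_AXIS_ORDER = ("k", "h", "v", "d")


class ConnectomePreprocessor(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`sfm.connectome.build_structural_connectome`.

    ``transform`` maps a :class:`RawConnectome` to a
    :class:`StructuralConnectome` with the configured normalization,
    fiber-length weighting, homotopic augmentation and input normalization.
    """

    def __init__(
        self,
        geometry=None,
        size_norm: str = "product",
        length_weighting: bool = False,
        h: float = 0.1,
        input_norm: bool = True,
    ):
        self.geometry = geometry
        self.size_norm = size_norm
        self.length_weighting = length_weighting
        self.h = h
        self.input_norm = input_norm

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: RawConnectome):
        return build_structural_connectome(
            X,
            geometry=self.geometry,
            size_norm=self.size_norm,
            length_weighting=self.length_weighting,
            h=self.h,
            input_norm=self.input_norm,
        )


def default_grid(model: str = "sar") -> dict:
    """Default (k, h) search grid; the SAR coupling must stay below 1/rho(S)."""
    if model == "sar":
        return {"k": np.arange(0.05, 1.0, 0.05), "h": np.arange(0.0, 0.21, 0.05)}
    return {"k": np.array([100.0, 300.0, 700.0, 1500.0]), "h": np.array([0.0, 0.1, 0.2])}


class StructureFunctionModel(BaseEstimator):
    """Grid-search fit of a structure-based FC model to an empirical FC matrix.

    Parameters
    ----------
    raw : RawConnectome
    geometry : ROIGeometry
    model : {'sar', 'kuramoto'}
    grid : dict mapping 'k', 'h' (and for Kuramoto optionally 'v', 'd') to
        1-D value arrays; defaults to :func:`default_grid`.
    size_norm, length_weighting, input_norm : preprocessing configuration,
        applied when rebuilding the structural connectome at each h.
    sigma : SAR noise scale (the correlation is independent of it).
    metric : FC metric for the Kuramoto simulation path.
    kuramoto : dict of fixed Kuramoto parameters (omega, dt, duration,
        burn_in, sample_rate, noise_sd, seed).
    band_center, bandwidth : analysis band for the Kuramoto path, Hz.

    Attributes (after ``fit``)
    --------------------------
    performance_ : ndarray with one axis per grid parameter (NaN where the
        SAR coupling is unstable).
    best_params_, best_r_, fc_model_, residuals_, node_error_, result_.
    """

    def __init__(
        self,
        raw=None,
        geometry=None,
        model: str = "sar",
        grid: dict = None,
        size_norm: str = "product",
        length_weighting: bool = False,
        input_norm: bool = True,
        sigma: float = 1.0,
        metric: str = "coh",
        kuramoto: dict = None,
        band_center: float = 8.0,
        bandwidth: float = 4.0,
        space: str = "source",
        leadfield=None,
        weights=None,
    ):
        self.raw = raw
        self.geometry = geometry
        self.model = model
        self.grid = grid
        self.size_norm = size_norm
        self.length_weighting = length_weighting
        self.input_norm = input_norm
        self.sigma = sigma
        self.metric = metric
        self.kuramoto = kuramoto
        self.band_center = band_center
        self.bandwidth = bandwidth
        self.space = space
        self.leadfield = leadfield
        self.weights = weights

    def _mixing(self):
        """Linear operator applied to model sources before the comparison.

        'source': none (raw model FC vs reconstructed empirical FC, the
        reference comparison); 'sensor': the leadfield G (forward-projected
        model vs sensor-space empirical FC); 'reconstructed': the resolution
        operator R = W G, i.e. the model is passed through the *same*
        observation-plus-inverse path as the data, which removes
        leakage-induced bias from parameter fits.
        """
        if self.space == "source":
            return None
        if self.leadfield is None:
            raise ValueError(f"{self.space}-space comparison requires a leadfield")
        if self.space == "sensor":
            return self.leadfield.G_fixed
        if self.space == "reconstructed":
            if self.weights is None:
                raise ValueError(
                    "reconstructed-space comparison requires inverse weights"
                )
            return np.asarray(self.weights) @ self.leadfield.G_fixed
        raise ValueError("space must be 'source', 'sensor' or 'reconstructed'")

    # -- model FC at one grid point ------------------------------------
    def _model_fc(self, S, point: dict):
        M = self._mixing()
        if self.model == "sar":
            res = sar_correlation(S, SARParams(k=point["k"], sigma=self.sigma))
            if M is None:
                return fc_from_sar(res.correlation)
            cov = M @ res.covariance @ M.T
            d = np.sqrt(np.diag(cov))
            return np.abs(cov / np.outer(d, d))
        fixed = dict(self.kuramoto or {})
        fixed.update({k: v for k, v in point.items() if k in ("k", "v", "d")})
        params = KuramotoParams(**fixed)
        traj = simulate_kuramoto(S, self.geometry, params)
        x = phases_to_signals(traj)
        if M is not None:
            x = M @ x
        aset = to_analytic(x, traj.sample_rate, self.band_center, self.bandwidth)
        return compute_fc_metric(aset, self.metric)

    def fit(self, X, y=None):
        """Evaluate the grid against the empirical FC matrix X and locate the argmax."""
        if self.model not in ("sar", "kuramoto"):
            raise ValueError("model must be 'sar' or 'kuramoto'")
        fc_emp = np.asarray(X, dtype=float)
        grid = self.grid if self.grid is not None else default_grid(self.model)
        axes = [a for a in _AXIS_ORDER if a in grid]
        if set(grid) - set(axes):
            raise ValueError(f"unknown grid axes {set(grid) - set(axes)}")
        values = [np.atleast_1d(np.asarray(grid[a], dtype=float)) for a in axes]
        if any(len(v) == 0 for v in values) or not axes:
            raise ValueError("empty parameter grid")
        shape = tuple(len(v) for v in values)

        # cache the rebuilt connectome per h (it does not depend on k/v/d)
        s_cache: dict = {}

        def connectome_for(h: float):
            if h not in s_cache:
                s_cache[h] = build_structural_connectome(
                    self.raw,
                    geometry=self.geometry,
                    size_norm=self.size_norm,
                    length_weighting=self.length_weighting,
                    h=h,
                    input_norm=self.input_norm,
                )
            return s_cache[h]

        perf = np.full(shape, np.nan)
        n_unstable = 0
        for idx in itertools.product(*(range(s) for s in shape)):
            point = {a: values[i][idx[i]] for i, a in enumerate(axes)}
            S = connectome_for(point.get("h", 0.0))
            try:
                fc_model = self._model_fc(S, point)
                perf[idx] = global_performance(fc_model, fc_emp)
            except UnstableCouplingError:
                n_unstable += 1

        if np.all(np.isnan(perf)):
            raise UnstableCouplingError("every grid point is unstable")

        # first occurrence in C order = smallest k, then smallest h, ...
        flat_best = np.nanargmax(perf)
        best_idx = np.unravel_index(flat_best, shape)
        best_params = {a: float(values[i][best_idx[i]]) for i, a in enumerate(axes)}
        best_r = float(perf[best_idx])

        S_best = connectome_for(best_params.get("h", 0.0))
        fc_model = self._model_fc(S_best, best_params)
        residuals = local_error(fc_model, fc_emp)

        self.performance_ = perf
        self.best_params_ = best_params
        self.best_r_ = best_r
        self.fc_model_ = fc_model
        self.connectome_ = S_best
        self.residuals_ = residuals
        self.node_error_ = node_error(residuals, fc_emp.shape[0])
        self.n_unstable_ = n_unstable
        self.result_ = FitResult(
            grid_axes={a: values[i] for i, a in enumerate(axes)},
            performance=perf,
            best_params=best_params,
            best_r=best_r,
            fc_model=fc_model,
            residuals=residuals,
            node_error=self.node_error_,
            n_unstable=n_unstable,
            meta={"model": self.model, "metric": self.metric},
        )
        return self

    def predict(self, X=None):
        """Return the model FC at the best-fitting parameters."""
        return self.fc_model_

    def score(self, X, y=None):
        """Global performance of the fitted model FC against X."""
        return global_performance(self.fc_model_, np.asarray(X, dtype=float))
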