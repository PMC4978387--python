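"""Model-fit evaluation: global correlation, local TLS error, graph metrics.

The match between modeled and empirical functional connectivity is scored as
the Pearson correlation over all unique region pairs (the strict upper
triangle; n = N(N-1)/2, i.e. 2145 pairs for 66 regions). Variance explained
is 100 r^2, and the additional variance a model captures beyond the raw
structural matrix is 100 (r_model^2 - r_sc^2) / (1 - r_sc^2).

Local model error is defined per connection from the total-least-squares
(orthogonal) fit: both FC vectors are z-transformed, the first principal
axis of the 2-D point cloud is the TLS line, and the signed orthogonal
distance of each point to that line is the residual (positive when the
empirical FC exceeds the modeled FC). Node-level error averages |residual|
over a node's incident edges and is related to per-node graph measures:
betweenness centrality, strength, eigenvector centrality and the weighted
clustering coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats


def _upper(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    return M[np.triu_indices(M.shape[0], k=1)]


def global_performance(fc_model: np.ndarray, fc_emp: np.ndarray) -> float:
    """Pearson correlation between modeled and empirical pairwise couplings.

    Computed over the strict upper triangle only (both matrices are
    symmetric). Raises if either vector has zero variance.
    """
    a, b = _upper(fc_model), _upper(fc_emp)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same size")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("global performance undefined: zero variance input")
    return float(np.corrcoef(a, b)[0, 1])


def performance_pvalue(r: float, n_edges: int) -> float:
    """Two-sided p-value for a Pearson r by the usual t-approximation.

    Treats the n_edges pairs as independent, which network edges are not;
    the value is therefore optimistic and reported as-is, uncorrected.
    """
    if n_edges < 3:
        return float("nan")
    t = r * np.sqrt((n_edges - 2) / max(1e-300, 1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n_edges - 2))


def variance_explained(r: float) -> float:
    """Shared variance in percent: 100 r^2."""
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    return 100.0 * r**2


def additional_variance(r_model: float, r_sc: float) -> float:
    """Percent of the variance unexplained by SC alone that the model captures.

    100 (r_model^2 - r_sc^2) / (1 - r_sc^2).
    """
    if abs(r_model) > 1 or abs(r_sc) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    if abs(r_sc) == 1:
        raise ValueError("additional variance undefined when |r_sc| = 1")
    return 100.0 * (r_model**2 - r_sc**2) / (1.0 - r_sc**2)


def local_error(fc_model: np.ndarray, fc_emp: np.ndarray) -> np.ndarray:
    """Signed orthogonal (total-least-squares) residual per connection.

    Both upper-triangle vectors are standardized to zero mean and unit
    variance; the TLS line is the first principal axis of the 2-D cloud;
    each point's residual is its signed orthogonal distance to the line,
    positive when the empirical value exceeds the modeled one
    (under-predicted edge). The model error is |residual|.
    """
    x, y = _upper(fc_model), _upper(fc_emp)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("local error undefined for constant input")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    pts = np.column_stack([x, y])
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]  # first principal axis
    normal = np.array([-axis[1], axis[0]])
    if normal[1] < 0:  # positive residual <=> empirical above the line
        normal = -normal
    return pts @ normal  # cloud is centered, so centroid residual is 0


def node_error(residuals: np.ndarray, n_rois: int) -> np.ndarray:
    """Mean absolute residual over each node's incident edges."""
    iu = np.triu_indices(n_rois, k=1)
    err = np.zeros(n_rois)
    cnt = np.zeros(n_rois)
    absres = np.abs(residuals)
    for e, (i, j) in enumerate(zip(*iu)):
        err[i] += absres[e]
        err[j] += absres[e]
        cnt[i] += 1
        cnt[j] += 1
    return err / np.maximum(cnt, 1)


def error_vs_edge_distance(residuals: np.ndarray, distances: np.ndarray):
    """Correlation of log model error with inter-ROI distance.

    Edges with exactly zero residual are excluded before taking the log
    (their count is reported in the result). Returns (r, p, n_used).
    """
    res = np.abs(np.asarray(residuals, dtype=float))
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        d = _upper(d)
    keep = res > 0
    n_excluded = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable edges for the distance regression")
    if n_excluded:
        warnings.warn(f"{n_excluded} zero-residual edge(s) excluded before log")
    r, p = stats.pearsonr(np.log(res[keep]), d[keep])
    return float(r), float(p), int(keep.sum())


def partial_global_performance(
    fc_model: np.ndarray, fc_emp: np.ndarray, distance: np.ndarray
) -> float:
    """Correlation between model and empirical FC after regressing out distance.

    Both upper-triangle FC vectors are OLS-regressed on distance (with an
    intercept) and the Pearson correlation of the residuals is returned.
    """
    a, b = _upper(fc_model), _upper(fc_emp)
    d = np.asarray(distance, dtype=float)
    if d.ndim == 2:
        d = _upper(d)
    if np.std(d) == 0:
        warnings.warn("constant distance vector: partial r equals plain r")
        return global_performance(fc_model, fc_emp)
    X = np.column_stack([np.ones_like(d), d])
    res_a = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
    res_b = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
    if np.std(res_a) == 0 or np.std(res_b) == 0:
        raise ValueError("partial correlation undefined: residuals have zero variance")
    return float(np.corrcoef(res_a, res_b)[0, 1])


def node_metrics(S: np.ndarray, betweenness_distance: str = "inverse") -> dict:
    """Per-node graph measures of a weighted symmetric connectivity matrix.

    Returns a dict of length-N arrays:

    - ``betweenness``: fraction of all shortest paths through each node,
      with edge length 1/weight by default (``betweenness_distance`` may be
      'inverse' or 'unit');
    - ``strength``: sum of connection strengths (row sum);
    - ``eigenvector_centrality``: principal eigenvector of S, nonnegative,
      unit norm;
    - ``clustering``: Onnela-style weighted clustering coefficient
      (geometric mean of normalized triangle weights).

    A disconnected graph is flagged; betweenness is then per-component.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not np.allclose(S, S.T) or np.any(S < 0):
        raise ValueError("S must be symmetric and nonnegative")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(S, k=1))
    for i, j in zip(ii, jj):
        w = S[i, j]
        G.add_edge(int(i), int(j), weight=w, length=1.0 / w)
    if not nx.is_connected(G):
        warnings.warn("graph is disconnected: betweenness computed per component")

    weight_key = "length" if betweenness_distance == "inverse" else None
    btw = nx.betweenness_centrality(G, weight=weight_key, normalized=True)

    eigvals, eigvecs = np.linalg.eigh(S)
    v = eigvecs[:, np.argmax(eigvals)]
    v = np.abs(v)  # Perron vector of a nonnegative matrix
    v = v / np.linalg.norm(v)

    clust = nx.clustering(G, weight="weight")
    return {
        "betweenness": np.array([btw[i] for i in range(n)]),
        "strength": S.sum(axis=1),
        "eigenvector_centrality": v,
        "clustering": np.array([clust[i] for i in range(n)]),
    }


@dataclass
class FitResult:
    """Outcome of a parameter grid search plus local-error analysis.

    ``performance`` has one axis per entry of ``grid_axes`` (NaN at unstable
    grid points); ``best_params`` / ``best_r`` locate the argmax with ties
    broken toward the smallest parameter values; ``residuals`` are the
    per-edge signed TLS residuals at the best point and ``node_error`` their
    per-node mean magnitudes.
    """

    grid_axes: dict
    performance: np.ndarray
    best_params: dict
    best_r: float
    fc_model: np.ndarray = None
    residuals: np.ndarray = None
    node_error: np.ndarray = None
    n_unstable: int = 0
    meta: dict = field(default_factory=dict)


def grid_search(
    model_spec: dict,
    raw,
    geometry,
    fc_emp: np.ndarray,
    grid: dict,
) -> FitResult:
    """Exhaustive parameter search maximizing the global performance.

    ``model_spec`` selects and configures the model, e.g.
    ``{"model": "sar", "size_norm": "product", "input_norm": True}`` or
    ``{"model": "kuramoto", ...}``; ``grid`` maps parameter names ('k', 'h'
    and, for Kuramoto, 'v', 'd') to value arrays. The structural connectome
    is rebuilt for every h. Thin wrapper over
    :class:`sfm.estimators.StructureFunctionModel`.
    """
    from .estimators import StructureFunctionModel

    spec = dict(model_spec)
    model = spec.pop("model", "sar")
    est = StructureFunctionModel(
        raw=raw, geometry=geometry, model=model, grid=grid, **spec
    )
    est.fit(fc_emp)
    return est.result_
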