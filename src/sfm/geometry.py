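"""ROI geometry: centers, sizes, distances and homotopic pairing.

Cortical parcellations used for whole-brain connectomics (e.g. the 66-region
Desikan-Killiany cortical atlas) come with per-region geometry that the
modeling pipeline needs at several stages: Euclidean distances between region
centers (for distance regressions and leadfield construction), mean fiber
distances along tracts (for conduction delays), region sizes (for streamline
count normalization) and the pairing of mirror-symmetric (homotopic) regions
across hemispheres (for homotopic augmentation of the structural connectome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ROIGeometry:
    """Geometric description of a cortical parcellation.

    Parameters
    ----------
    centers : (N, 3) array
        ROI center coordinates in mm.
    sizes : (N,) array
        ROI sizes (voxel counts or mm^3), strictly positive.
    euclid_dist : (N, N) array
        Euclidean distance between ROI centers, mm.
    fiber_dist : (N, N) array
        Mean fiber (tract) distance between ROIs, mm. Entrywise >= the
        Euclidean distance wherever a connection exists.
    hemisphere : (N,) array of str
        Hemisphere label per ROI ('L' or 'R').
    homotopic : (N,) int array
        Index of each ROI's homotopic partner, or -1 when unpaired. Must be
        an involution across hemispheres.
    labels : list of str, optional
        ROI names; autogenerated if omitted.
    """

    centers: np.ndarray
    sizes: np.ndarray
    euclid_dist: np.ndarray
    fiber_dist: np.ndarray
    hemisphere: np.ndarray
    homotopic: np.ndarray
    labels: list = field(default=None)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.euclid_dist = np.asarray(self.euclid_dist, dtype=float)
        self.fiber_dist = np.asarray(self.fiber_dist, dtype=float)
        self.homotopic = np.asarray(self.homotopic, dtype=int)
        n = self.n_rois
        if self.centers.shape != (n, 3):
            raise ValueError("centers must be (N, 3)")
        if np.any(self.sizes <= 0):
            raise ValueError("ROI sizes must be strictly positive")
        for name in ("euclid_dist", "fiber_dist"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be (N, N)")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if self.labels is None:
            self.labels = [f"roi{i:03d}" for i in range(n)]
        self._check_homotopic()

    @property
    def n_rois(self) -> int:
        return len(self.sizes)

    def _check_homotopic(self):
        hom = self.homotopic
        for i, j in enumerate(hom):
            if j < 0:
                continue
            if hom[j] != i:
                raise ValueError("homotopic pairing must be an involution")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError("homotopic partners must lie in opposite hemispheres")

    def homotopic_pairs(self) -> list:
        """Return each homotopic pair (i, j) once, with i < j."""
        return [(i, int(j)) for i, j in enumerate(self.homotopic) if 0 <= i < j]
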