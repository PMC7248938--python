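"""Projection of per-locus statistics onto the cortical surface.

MPC is a nonlinear statistic of the observed signals, so linear inverse
operators do not apply; instead each mesh vertex takes an inverse-distance
weighted average of the values at its k nearest sensor loci (k = 3 by
default, plain 1/d weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .synthetic import CorticalMesh, SensorArray

__all__ = ["CorticalMap", "nearest_loci", "idw_project", "project_map"]


@dataclass(frozen=True)
class CorticalMap:
    """Per-vertex values over shifts (or time), tied to a labeled mesh."""

    mesh: CorticalMesh
    values: np.ndarray   # (V, S)
    times: np.ndarray    # (S,) shift or epoch time, s
    source: str = "msa"


def nearest_loci(vertex, array: SensorArray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k loci nearest a point, sorted by ascending Euclidean distance.

    Ties are broken deterministically by locus index (stable sort).
    """
    if not 1 <= k <= array.n_loci:
        raise ValueError("need 1 <= k <= number of loci")
    d = np.linalg.norm(array.locus_positions - np.asarray(vertex, dtype=float),
                       axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return order, d[order]


def _idw_weights(vertices: np.ndarray, array: SensorArray, k: int,
                 power: float) -> np.ndarray:
    """(V, L) row-stochastic weight matrix over each vertex's k nearest loci."""
    D = cdist(vertices, array.locus_positions)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    W = np.zeros_like(D)
    rows = np.arange(vertices.shape[0])[:, None]
    dk = D[rows, order]
    zero_rows = dk[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = 1.0 / dk**power
    # a vertex coincident with a locus takes that locus's value exactly
    w[zero_rows] = 0.0
    w[zero_rows, 0] = 1.0
    W[rows, order] = w / w.sum(axis=1, keepdims=True)
    return W


def idw_project(locus_values, array: SensorArray, mesh: CorticalMesh,
                k: int = 3, power: float = 1.0) -> np.ndarray:
    """Inverse-distance weighted per-vertex values for one shift.

    vertex value = sum(w_i v_i) / sum(w_i) with w_i = 1/d_i^power over the k
    nearest loci. Weights normalize, so the result obeys the maximum
    principle: it never leaves the range of the contributing locus values.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    if not 1 <= k <= array.n_loci:
        raise ValueError("need 1 <= k <= number of loci")
    v = np.asarray(locus_values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("locus values must be finite")
    W = _idw_weights(mesh.vertices, array, k, power)
    return W @ v


def project_map(values: np.ndarray, times, array: SensorArray,
                mesh: CorticalMesh, k: int = 3, power: float = 1.0,
                source: str = "msa") -> CorticalMap:
    """Project a loci x shifts matrix onto the mesh, one shift at a time.

    The geometry-only IDW weights are computed once and reused per shift.
    """
    if power <= 0:
        raise ValueError("power must be > 0")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("locus values must be finite; mask degenerate loci first")
    W = _idw_weights(mesh.vertices, array, k, power)
    return CorticalMap(mesh=mesh, values=W @ values,
                       times=np.asarray(times, dtype=float), source=source)
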