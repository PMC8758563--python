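"""Spatial weight matrices: contiguity, inverse distance, row standardisation.

The packaged China scheme is queen-style land-border contiguity among the
31 provincial units plus the HaiNan-GuangDong sea link, so no unit is an
island; its row-standardised form is the default W for the Moran, Gi* and
spatial-panel stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpatialWeightMatrix",
    "build_contiguity",
    "row_standardize",
    "inverse_distance_weights",
    "china_contiguity",
    "grid_contiguity",
]

log = logging.getLogger(__name__)


@dataclass
class SpatialWeightMatrix:
    """Labelled n x n nonnegative weight matrix with standardisation state."""

    labels: list
    w: np.ndarray
    standardized: str = "none"  # none | row

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.labels)
        if self.w.shape != (n, n):
            raise ValueError(f"weight matrix must be {n}x{n}")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def with_self_weights(self) -> "SpatialWeightMatrix":
        """Star variant: add unit self-weights (for the Gi* statistic)."""
        w = self.w.copy()
        np.fill_diagonal(w, 1.0)
        return SpatialWeightMatrix(self.labels, w, standardized="none")

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.labels, columns=self.labels)

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.w)
        return pd.DataFrame({
            "from": [self.labels[a] for a in i],
            "to": [self.labels[b] for b in j],
            "weight": self.w[i, j],
        })


def build_contiguity(edges, labels) -> SpatialWeightMatrix:
    """Binary symmetric contiguity matrix from an undirected edge list.

    ``edges`` is an iterable of (label, label) pairs or a path to a
    two-column whitespace-separated text file (``#`` comments allowed).
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "read_text") or hasattr(edges, "open"):
        pairs = []
        text = edges.read_text() if hasattr(edges, "read_text") else open(edges).read()
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            a, b = line.split()[:2]
            pairs.append((a, b))
        edges = pairs
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for a, b in edges:
        if a not in idx or b not in idx:
            unknown = a if a not in idx else b
            raise KeyError(f"edge references unknown label {unknown!r}")
        if a == b:
            continue
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
    return SpatialWeightMatrix(list(labels), w)


def china_contiguity(standardize: bool = True) -> SpatialWeightMatrix:
    """The packaged 31-province contiguity matrix (row-standardised by default)."""
    path = resources.files("healthprod.data").joinpath("china_adjacency.txt")
    from .panel import CHINA_REGIONS
    labels = list(CHINA_REGIONS)
    W = build_contiguity(path, labels)
    return row_standardize(W) if standardize else W


def grid_contiguity(rows: int, cols: int, rule: str = "rook") -> SpatialWeightMatrix:
    """Regular lattice contiguity (rook or queen), for simulations and tests."""
    labels = [(r, c) for r in range(rows) for c in range(cols)]
    idx = {lab: i for i, lab in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if rule == "queen":
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for (r, c) in labels:
        for dr, dc in steps:
            nb = (r + dr, c + dc)
            if nb in idx:
                w[idx[(r, c)], idx[nb]] = 1.0
    return SpatialWeightMatrix(labels, w)


def row_standardize(W: SpatialWeightMatrix) -> SpatialWeightMatrix:
    """Divide each nonzero row by its sum; island rows stay zero (warned)."""
    w = W.w.copy()
    sums = w.sum(axis=1)
    islands = np.where(sums == 0)[0]
    for i in islands:
        log.warning("unit %r has no neighbours (island row left zero)",
                    W.labels[i])
        warnings.warn(f"island unit {W.labels[i]!r}: row left zero", stacklevel=2)
    nz = sums > 0
    w[nz] = w[nz] / sums[nz, None]
    return SpatialWeightMatrix(W.labels, w, standardized="row")


def inverse_distance_weights(coords, cutoff: float = np.inf) -> SpatialWeightMatrix:
    """w_ij = 1/d_ij for pairs within ``cutoff``, zero diagonal.

    ``coords`` is a DataFrame with columns (label, x, y) or a mapping
    label -> (x, y).  Coincident points are rejected (infinite weight).
    """
    if isinstance(coords, pd.DataFrame):
        labels = list(coords.iloc[:, 0])
        pts = coords.iloc[:, 1:3].to_numpy(dtype=float)
    else:
        labels = list(coords)
        pts = np.asarray([coords[k] for k in labels], dtype=float)
    n = len(labels)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident points give infinite inverse-distance weight")
    w = np.zeros((n, n))
    mask = off & (d <= cutoff)
    w[mask] = 1.0 / d[mask]
    if np.any(w.sum(axis=1) == 0):
        log.warning("cutoff %.3g leaves island units", cutoff)
    return SpatialWeightMatrix(labels, w)
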