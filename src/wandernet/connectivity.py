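"""Whole-brain functional connectivity containers and edge-vector plumbing.

Functional connectivity (FC) is the pairwise Pearson correlation between
regional BOLD time series.  Downstream network inference works edge-wise, so
an N x N symmetric correlation matrix is flattened to a vector of the
E = N(N-1)/2 upper-triangle edges in row-major order; a stack of scans is
then a scans x E matrix aligned with per-scan metadata (subject, day, run).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: metadata columns that identify one scan
SCAN_KEYS = ["subject_id", "day", "run"]


def edge_count(n_nodes: int) -> int:
    """Number of distinct node pairs (undirected, no self-loops)."""
    if n_nodes < 2:
        raise InvalidParameterError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: upper triangle (i < j), row-major.

    Returns arrays ``(ii, jj)`` such that edge ``e`` connects nodes
    ``ii[e]`` and ``jj[e]`` (0-based).  This is the bijection used by
    :func:`vectorize` / :func:`devectorize` and by every edge matrix in the
    package.
    """
    return np.triu_indices(n_nodes, k=1)


def n_nodes_from_edges(n_edges: int) -> int:
    """Invert E = N(N-1)/2; error when E is not a triangular number."""
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n * (n - 1) // 2 != n_edges:
        raise InvalidParameterError(
            f"{n_edges} is not a triangular number N(N-1)/2 for any integer N"
        )
    return n


def pearson_matrix(ts: np.ndarray, region_names=None) -> np.ndarray:
    """Pairwise Pearson correlation matrix of regional time series.

    Parameters
    ----------
    ts : ndarray, shape (volumes, regions)
        One column per region.
    region_names : sequence of str, optional
        Used to name the offending region in error messages.

    Returns
    -------
    ndarray, shape (regions, regions)
        Symmetric, unit diagonal.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise InvalidParameterError("time series must be 2-D (volumes x regions)")
    if ts.shape[0] < 3:
        raise InvalidParameterError(
            f"need at least 3 volumes to correlate, got {ts.shape[0]}"
        )
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = region_names[bad] if region_names is not None else f"column {bad}"
        raise DegenerateInputError(
            f"region {name!r} has a constant time series; correlation undefined"
        )
    c = np.corrcoef(ts, rowvar=False)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


def vectorize(matrix: np.ndarray, *, rtol: float = 1e-8) -> np.ndarray:
    """Flatten a square symmetric matrix to its canonical edge vector."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidParameterError(f"expected a square matrix, got shape {m.shape}")
    if not np.allclose(m, m.T, rtol=rtol, atol=1e-10):
        raise InvalidParameterError("matrix is not symmetric")
    ii, jj = edge_index(m.shape[0])
    return m[ii, jj].copy()


def devectorize(vector: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector (diagonal set to 1)."""
    v = np.asarray(vector, dtype=float).ravel()
    if n_nodes is None:
        n_nodes = n_nodes_from_edges(v.size)
    elif edge_count(n_nodes) != v.size:
        raise InvalidParameterError(
            f"edge vector of length {v.size} does not match n_nodes={n_nodes}"
        )
    m = np.zeros((n_nodes, n_nodes))
    ii, jj = edge_index(n_nodes)
    m[ii, jj] = v
    m[jj, ii] = v
    np.fill_diagonal(m, 1.0)
    return m


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher variance-stabilizing transform arctanh(r).

    Values with |r| >= 1 are clipped to +/-(1 - 1e-7) with a warning.  Off
    by default in the pipeline, which models raw Pearson R.
    """
    r = np.asarray(r, dtype=float)
    lim = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlations with |r| >= 1 clipped to +/-(1 - 1e-7) before arctanh",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -lim, lim)
    return np.arctanh(r)


@dataclass
class ROITimeSeriesSet:
    """Per-scan regional time series with scan metadata.

    Attributes
    ----------
    series : list of ndarray, each (volumes, regions)
    meta : DataFrame with columns subject_id, day, run (one row per scan)
    region_names : list of str
    """

    series: list
    meta: pd.DataFrame
    region_names: list

    def __post_init__(self):
        if len(self.series) != len(self.meta):
            raise InvalidParameterError("metadata rows must match number of scans")
        n_regions = {s.shape[1] for s in self.series}
        if len(n_regions) > 1:
            raise InvalidParameterError("all scans must share the region count")
        for s in self.series:
            if s.shape[0] < 10:
                raise InvalidParameterError("each scan needs at least 10 volumes")


@dataclass
class ConnectivityStack:
    """Vectorized connectivity for a set of scans.

    Attributes
    ----------
    edge_matrix : ndarray, shape (scans, E)
        Row ``s`` holds scan ``s``'s upper-triangle edge values in the
        canonical row-major order of :func:`edge_index`.
    meta : DataFrame
        One row per scan, columns ``subject_id, day, run``, aligned with
        ``edge_matrix`` rows.
    node_table : DataFrame
        One row per region: ``label, hemisphere, x, y, z`` (MNI mm).
    """

    edge_matrix: np.ndarray
    meta: pd.DataFrame
    node_table: pd.DataFrame
    n_nodes: int = field(default=0)

    def __post_init__(self):
        self.edge_matrix = np.asarray(self.edge_matrix, dtype=float)
        if self.edge_matrix.ndim != 2:
            raise InvalidParameterError("edge_matrix must be 2-D (scans x edges)")
        if len(self.meta) != self.edge_matrix.shape[0]:
            raise InvalidParameterError("metadata rows must match edge_matrix rows")
        if not self.n_nodes:
            self.n_nodes = n_nodes_from_edges(self.edge_matrix.shape[1])
        elif edge_count(self.n_nodes) != self.edge_matrix.shape[1]:
            raise InvalidParameterError("n_nodes inconsistent with edge count")
        if len(self.node_table) != self.n_nodes:
            raise InvalidParameterError(
                f"node_table has {len(self.node_table)} rows, expected {self.n_nodes}"
            )
        missing = [k for k in SCAN_KEYS if k not in self.meta.columns]
        if missing:
            raise InvalidParameterError(f"metadata lacks columns {missing}")

    @property
    def n_scans(self) -> int:
        return self.edge_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_matrix.shape[1]

    def matrix(self, scan: int) -> np.ndarray:
        """Symmetric matrix for one scan (diagonal restored as 1)."""
        return devectorize(self.edge_matrix[scan], self.n_nodes)


def build_stack(
    matrices,
    metadata: pd.DataFrame,
    node_table: pd.DataFrame,
    questionnaire=None,
    scans_per_subject: int = 4,
) -> ConnectivityStack:
    """Assemble a :class:`ConnectivityStack` from per-scan inputs.

    Parameters
    ----------
    matrices : sequence of square matrices, or an :class:`ROITimeSeriesSet`
        Time series are converted with :func:`pearson_matrix`.
    metadata : DataFrame with subject_id, day, run (ignored for a time-series
        set, which carries its own metadata).
    questionnaire : MultiBlockTable, optional
        When given, scans are inner-joined 1:1 with questionnaire blocks on
        (subject, day, run); subjects missing on either side are dropped.
    scans_per_subject : int
        Subjects without exactly this many scans are excluded (logged), the
        inclusion rule of a balanced repeated-measures permutation design.
    """
    if isinstance(matrices, ROITimeSeriesSet):
        metadata = matrices.meta
        names = matrices.region_names
        matrices = [pearson_matrix(s, names) for s in matrices.series]
    matrices = list(matrices)
    if not matrices:
        raise InvalidParameterError("no scans provided")
    if len(matrices) != len(metadata):
        raise InvalidParameterError("metadata rows must match number of scans")
    n = matrices[0].shape[0]
    if any(m.shape != (n, n) for m in matrices):
        raise InvalidParameterError("all scans must share the node count")

    meta = metadata.reset_index(drop=True).copy()
    dup = meta.duplicated(subset=SCAN_KEYS)
    if dup.any():
        raise InvalidParameterError(
            f"duplicate (subject, day, run) rows: {meta.loc[dup, SCAN_KEYS].values.tolist()}"
        )

    counts = meta.groupby("subject_id").size()
    complete = set(counts.index[counts == scans_per_subject])
    dropped = sorted(set(counts.index) - complete)
    if dropped:
        logger.warning(
            "excluding %d subject(s) without all %d usable scans: %s",
            len(dropped), scans_per_subject, dropped,
        )
    if questionnaire is not None:
        q_subjects = set(questionnaire.subject_ids)
        lost = sorted(complete - q_subjects)
        if lost:
            logger.warning("excluding subject(s) without questionnaire rows: %s", lost)
        complete &= q_subjects
    if not complete:
        raise DegenerateInputError("no subject has a complete set of scans")

    keep = meta.index[meta["subject_id"].isin(complete)]
    meta = meta.loc[keep].sort_values(SCAN_KEYS, kind="stable")
    edges = np.vstack([vectorize(matrices[i]) for i in meta.index])
    return ConnectivityStack(
        edge_matrix=edges,
        meta=meta.reset_index(drop=True),
        node_table=node_table.reset_index(drop=True),
        n_nodes=n,
    )
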