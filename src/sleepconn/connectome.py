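"""Functional-connectome construction from parcellated node time series.

Starts where image-space preprocessing ends: per-run T x N node time
series plus rigid-body motion parameters.  The run-level pipeline is

    confound regression -> temporal Gaussian smoothing -> Fisher-z connectome

with framewise displacement (FD) computed from the motion parameters and a
strict exclusion of runs whose mean FD is at or above 0.15 mm.

Confounds follow the standard infant-fMRI cleaning recipe: linear and
quadratic drifts, mean CSF / white-matter / gray-matter signals, and a
24-parameter motion model (6 rigid-body parameters, their temporal
derivatives, and the squares of both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "NodeTimeSeries",
    "ConfoundSet",
    "Connectome",
    "compute_fd",
    "build_confounds",
    "nuisance_regress",
    "temporal_smooth",
    "build_connectome",
    "preprocess_run",
    "edge_pairs",
    "n_edges",
    "FISHER_Z_CLIP",
]

#: correlations are clipped to +/-(1 - FISHER_Z_CLIP) before atanh
FISHER_Z_CLIP = 1e-7

#: assumed head radius (mm) converting rotation differences to displacement
HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class NodeTimeSeries:
    """Per-run parcellated signal: n_volumes x n_nodes."""

    run_id: str
    data: np.ndarray
    tr: float
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("node time series must be 2-D (volumes x nodes)")
        if data.shape[0] < 10:
            raise ValueError("need at least 10 volumes")
        if not np.all(np.isfinite(data)):
            raise ValueError("node time series must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "data", data)
        if self.node_ids is None:
            object.__setattr__(
                self, "node_ids",
                tuple(f"node{i:03d}" for i in range(data.shape[1])))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


CONFOUND_NAMES = (
    ["intercept", "drift_linear", "drift_quadratic", "csf", "wm", "gm"]
    + [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"dmotion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"motion_{ax}_sq" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"dmotion_{ax}_sq" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
)


@dataclass(frozen=True)
class ConfoundSet:
    """Nuisance design matrix: intercept + 2 drifts + 3 tissue means + 24
    motion regressors = 30 columns, in the fixed CONFOUND_NAMES order."""

    design: np.ndarray
    names: tuple[str, ...] = tuple(CONFOUND_NAMES)


def compute_fd(motion: np.ndarray, head_radius: float = HEAD_RADIUS_MM) -> tuple[np.ndarray, float]:
    """Framewise displacement from 6 rigid-body parameters.

    ``fd_t = sum |d translations| + head_radius * sum |d rotations|`` over
    backward differences (translations mm, rotations rad).  Returns the
    per-transition series (length T-1) and its mean.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least two volumes to compute FD")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    return fd, float(fd.mean())


def build_confounds(motion: np.ndarray, tissue_means: np.ndarray,
                    n_volumes: int) -> ConfoundSet:
    """Assemble the 30-column nuisance design.

    `tissue_means` is (n_volumes, 3) ordered csf, wm, gm.  Motion temporal
    derivatives are backward differences with the first frame set to 0.
    """
    motion = np.asarray(motion, dtype=float)
    tissue = np.asarray(tissue_means, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError(f"motion shape {motion.shape} != ({n_volumes}, 6)")
    if tissue.shape != (n_volumes, 3):
        raise ValueError(f"tissue_means shape {tissue.shape} != ({n_volumes}, 3)")
    t = np.arange(n_volumes, dtype=float)
    dmotion = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    design = np.column_stack([
        np.ones(n_volumes), t, t ** 2, tissue,
        motion, dmotion, motion ** 2, dmotion ** 2,
    ])
    assert design.shape == (n_volumes, 30)
    return ConfoundSet(design)


def nuisance_regress(ts: NodeTimeSeries, confounds: ConfoundSet) -> NodeTimeSeries:
    """Residualize every node series against the confound design (OLS).

    All-zero confound columns (e.g. a motionless run) are dropped first;
    remaining rank deficiency raises with the offending column names.
    """
    X = confounds.design
    if X.shape[0] != ts.n_volumes:
        raise ValueError("confound design and time series disagree on n_volumes")
    keep = np.ptp(X, axis=0) > 0
    keep[0] = True  # intercept
    Xk = X[:, keep]
    names = [n for n, k in zip(confounds.names, keep) if k]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # name the columns involved in the dependency via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(Xk, pivoting=True, mode="economic")
        bad = sorted(names[i] for i in piv[rank:])
        raise np.linalg.LinAlgError(
            f"confound design is rank deficient (rank {rank} of {Xk.shape[1]}); "
            f"dependent columns: {', '.join(bad)}"
        )
    beta, *_ = np.linalg.lstsq(Xk, ts.data, rcond=None)
    resid = ts.data - Xk @ beta
    return NodeTimeSeries(ts.run_id, resid, ts.tr, ts.node_ids)


def temporal_smooth(ts: NodeTimeSeries, cutoff_hz: float = 0.12) -> NodeTimeSeries:
    """Temporal Gaussian smoothing with a half-amplitude cutoff.

    The kernel sigma is chosen so the Gaussian transfer function
    ``|H(f)| = exp(-2 pi^2 sigma^2 f^2)`` equals 0.5 at `cutoff_hz`
    (sigma = sqrt(ln 2) / (sqrt 2 * pi * f_c) ~ 1.56 s at 0.12 Hz);
    truncation at +/-4 sigma, reflection at the edges.  DC gain is 1, so
    constant series pass through unchanged.
    """
    nyquist = 0.5 / ts.tr
    if not (0 < cutoff_hz <= nyquist):
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist} Hz]")
    sigma_s = np.sqrt(np.log(2.0)) / (np.sqrt(2.0) * np.pi * cutoff_hz)
    smoothed = gaussian_filter1d(ts.data, sigma_s / ts.tr, axis=0,
                                 mode="reflect", truncate=4.0)
    return NodeTimeSeries(ts.run_id, smoothed, ts.tr, ts.node_ids)


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle (i < j) node index pairs."""
    return np.triu_indices(n_nodes, k=1)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


@dataclass(frozen=True)
class Connectome:
    """Symmetric n_nodes x n_nodes Fisher-z matrix.

    The canonical edge vectorization is the row-major upper triangle
    (i < j), length n(n-1)/2; `edge_vector`/`from_edge_vector` round-trip
    exactly.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectome matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValueError("connectome entries must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def edge_vector(self) -> np.ndarray:
        i, j = edge_pairs(self.n_nodes)
        return self.matrix[i, j]

    @staticmethod
    def from_edge_vector(edges: np.ndarray, n_nodes: int,
                         diagonal: float = 0.0) -> "Connectome":
        edges = np.asarray(edges, dtype=float)
        if edges.size != n_edges(n_nodes):
            raise ValueError("edge vector length does not match node count")
        m = np.full((n_nodes, n_nodes), diagonal, dtype=float)
        i, j = edge_pairs(n_nodes)
        m[i, j] = edges
        m[j, i] = edges
        return Connectome(m)


def build_connectome(ts: NodeTimeSeries) -> Connectome:
    """Pairwise Pearson correlations, Fisher z-transformed.

    r is clipped to +/-(1 - 1e-7) before atanh so duplicated nodes stay
    finite; the diagonal is set to 0 in z units.
    """
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.node_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant node series: {', '.join(bad)}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip(r, -(1 - FISHER_Z_CLIP), 1 - FISHER_Z_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return Connectome(z)


def preprocess_run(ts: NodeTimeSeries, motion: np.ndarray,
                   tissue_means: np.ndarray, cutoff_hz: float = 0.12) -> Connectome:
    """Fixed-order run pipeline: confounds -> regression -> smoothing -> connectome."""
    confounds = build_confounds(motion, tissue_means, ts.n_volumes)
    cleaned = nuisance_regress(ts, confounds)
    smoothed = temporal_smooth(cleaned, cutoff_hz)
    return build_connectome(smoothed)
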