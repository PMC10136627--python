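"""Time-varying phase-locking networks gated by microstate labels.

The phase-locking value between channels a and b at sample t is

    PLV_ab(t) = | (1/N) sum_k exp(i (phi_a(t,k) - phi_b(t,k))) |

over the N trials k, with instantaneous phases from the analytic
(Hilbert) signal of the band-limited data. Averaging PLV_ab(t) over the
samples carrying one microstate label yields a per-state channel x
channel network, summarised by the mean clustering coefficient Cp
(local information processing) and the characteristic path length Lp
(global integration).

The analytic signal is unreliable near the epoch edges, so a
configurable fraction of samples at each end is excluded from the
gated averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal as _signal
from scipy.sparse.csgraph import shortest_path

from msconn.microstate import Segmentation
from msconn.preprocess import EpochedData

__all__ = [
    "instantaneous_phase",
    "plv_timecourse",
    "plv_matrix_timecourse",
    "microstate_gated_plv",
    "clustering_coefficient",
    "characteristic_path_length",
    "graph_metrics",
    "PLVNetwork",
    "GraphMetrics",
]


@dataclass
class PhaseTensor:
    """Instantaneous phases (radians, (-pi, pi]): trials x channels x samples."""

    phase: np.ndarray
    valid: np.ndarray  # per-sample reliability mask (edge effects)
    sampling_rate: float


@dataclass
class PLVNetwork:
    """Symmetric channel x channel PLV adjacency for one microstate class."""

    adjacency: np.ndarray
    microstate: int
    n_trials: int
    n_samples: int  # gated samples averaged over; 0 marks an empty network

    @property
    def empty(self) -> bool:
        return self.n_samples == 0


@dataclass
class GraphMetrics:
    cp_per_node: np.ndarray
    cp: float
    lp: float
    n_finite_pairs: int
    mode: str


def instantaneous_phase(
    epochs: EpochedData | np.ndarray,
    edge_trim: float = 0.05,
    sampling_rate: float | None = None,
) -> PhaseTensor:
    """Per-trial, per-channel instantaneous phase via the Hilbert transform.

    ``edge_trim`` flags the first and last fraction of samples as
    unreliable (analytic-signal edge artifacts); downstream gated
    averages skip them.
    """
    if isinstance(epochs, EpochedData):
        data, sampling_rate = epochs.data, epochs.sampling_rate
    else:
        data = np.asarray(epochs, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw arrays")
    if data.size == 0:
        raise ValueError("empty epochs")
    if not (0 <= edge_trim < 0.5):
        raise ValueError("edge_trim must be in [0, 0.5)")
    flat = np.ptp(data, axis=-1) == 0
    if flat.any():
        raise ValueError(
            "constant (e.g. all-zero) channel encountered; phase is undefined"
        )
    analytic = _signal.hilbert(data, axis=-1)
    phase = np.angle(analytic)
    n = data.shape[-1]
    trim = int(np.floor(edge_trim * n))
    valid = np.ones(n, dtype=bool)
    if trim:
        valid[:trim] = False
        valid[-trim:] = False
    return PhaseTensor(phase=phase, valid=valid, sampling_rate=float(sampling_rate))


def plv_timecourse(phase: PhaseTensor | np.ndarray, channel_pair: tuple[int, int]) -> np.ndarray:
    """PLV over time for one channel pair.

    The modulus of the trial-mean unit phasor of the phase difference;
    1 for perfectly locked phases, ~N^{-1/2} for unrelated ones.
    """
    p = phase.phase if isinstance(phase, PhaseTensor) else np.asarray(phase, dtype=float)
    if p.ndim != 3:
        raise ValueError("phase must be trials x channels x samples")
    a, b = channel_pair
    diff = p[:, a, :] - p[:, b, :]
    return np.abs(np.exp(1j * diff).mean(axis=0))


def plv_matrix_timecourse(phase: PhaseTensor | np.ndarray) -> np.ndarray:
    """All-pairs PLV: channels x channels x samples (diagonal 1)."""
    p = phase.phase if isinstance(phase, PhaseTensor) else np.asarray(phase, dtype=float)
    if p.ndim != 3:
        raise ValueError("phase must be trials x channels x samples")
    n_trials = p.shape[0]
    z = np.exp(1j * p)  # trials x channels x samples
    # mean_k z_a z_b* per sample
    acc = np.einsum("kat,kbt->abt", z, np.conj(z)) / n_trials
    return np.abs(acc)


def microstate_gated_plv(
    plv: np.ndarray,
    segmentation: Segmentation | np.ndarray,
    n_trials: int = 0,
    valid: np.ndarray | None = None,
    n_classes: int | None = None,
) -> dict[int, PLVNetwork]:
    """Average the PLV time course within each microstate's samples.

    ``plv`` is channels x channels x samples; the segmentation labels
    must share that time axis. A class with no (valid) labelled samples
    yields an empty-network marker (``n_samples == 0``).
    """
    labels = segmentation.labels if isinstance(segmentation, Segmentation) else np.asarray(segmentation)
    if plv.ndim != 3:
        raise ValueError("plv must be channels x channels x samples")
    if plv.shape[2] != len(labels):
        raise ValueError(
            f"time-axis mismatch: plv has {plv.shape[2]} samples, segmentation {len(labels)}"
        )
    if valid is None:
        valid = np.ones(len(labels), dtype=bool)
    if n_classes is None:
        if isinstance(segmentation, Segmentation) and segmentation.class_labels:
            n_classes = len(segmentation.class_labels)
        else:
            n_classes = int(labels.max()) + 1
    n_ch = plv.shape[0]
    out: dict[int, PLVNetwork] = {}
    for cls in range(n_classes):
        mask = (labels == cls) & valid
        n_samp = int(mask.sum())
        if n_samp == 0:
            adj = np.zeros((n_ch, n_ch))
        else:
            adj = plv[:, :, mask].mean(axis=2)
            np.fill_diagonal(adj, 0.0)
            adj = (adj + adj.T) / 2.0
        out[cls] = PLVNetwork(adjacency=adj, microstate=cls, n_trials=n_trials, n_samples=n_samp)
    return out


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if (adj < 0).any():
        raise ValueError("negative edge weights are not allowed")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def threshold_proportional(adjacency: np.ndarray, sparsity: float) -> np.ndarray:
    """Binarize, keeping the ``sparsity`` proportion of strongest edges."""
    adj = _check_adjacency(adjacency)
    iu = np.triu_indices_from(adj, k=1)
    weights = adj[iu]
    n_keep = int(round(sparsity * len(weights)))
    if n_keep <= 0:
        return np.zeros_like(adj)
    cutoff = np.sort(weights)[::-1][n_keep - 1]
    binary = np.where((adj >= cutoff) & (adj > 0), 1.0, 0.0)
    np.fill_diagonal(binary, 0.0)
    return binary


def clustering_coefficient(
    adjacency: np.ndarray, mode: str = "weighted", sparsity: float | None = None
) -> tuple[np.ndarray, float]:
    """Per-node and mean clustering coefficient Cp.

    Weighted mode uses the geometric-mean triangle formula on weights
    normalized by the maximum weight (Onnela); binary mode thresholds
    first (proportional sparsity) and counts triangle fractions.
    """
    adj = _check_adjacency(adjacency)
    if mode == "binary":
        adj = threshold_proportional(adj, sparsity if sparsity is not None else 0.2)
        graph = nx.from_numpy_array(adj)
        cc = nx.clustering(graph)
    elif mode == "weighted":
        graph = nx.from_numpy_array(adj)
        cc = nx.clustering(graph, weight="weight")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    per_node = np.array([cc[i] for i in range(adj.shape[0])])
    return per_node, float(per_node.mean())


def characteristic_path_length(
    adjacency: np.ndarray, mode: str = "weighted", sparsity: float | None = None
) -> tuple[float, int]:
    """Characteristic path length Lp.

    Distances are 1/weight (weighted) or 1 on the thresholded graph
    (binary); Lp is the mean shortest-path distance over ordered node
    pairs with a finite distance, whose count is also returned.
    """
    adj = _check_adjacency(adjacency)
    if adj.shape[0] < 2:
        raise ValueError("path length needs at least 2 nodes")
    if mode == "binary":
        adj = threshold_proportional(adj, sparsity if sparsity is not None else 0.2)
        dist_in = adj  # unit distances on existing edges
    elif mode == "weighted":
        with np.errstate(divide="ignore"):
            dist_in = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dmat = shortest_path(dist_in, method="D", directed=False)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(dmat) & off
    n_finite = int(finite.sum())
    lp = float(dmat[finite].mean()) if n_finite else float("inf")
    return lp, n_finite


def graph_metrics(
    adjacency: np.ndarray, mode: str = "weighted", sparsity: float | None = None
) -> GraphMetrics:
    """Cp and Lp of one PLV network."""
    per_node, cp = clustering_coefficient(adjacency, mode=mode, sparsity=sparsity)
    lp, n_finite = characteristic_path_length(adjacency, mode=mode, sparsity=sparsity)
    return GraphMetrics(cp_per_node=per_node, cp=cp, lp=lp, n_finite_pairs=n_finite, mode=mode)
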