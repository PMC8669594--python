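"""Phase-locking-value (PLV) functional connectivity between ROIs.

Instantaneous phases come from the analytic signal (Hilbert transform) of
the band-limited source traces, computed over the whole padded epoch so
that transform edge effects stay outside the analysis windows.  For a pair
of phase series the single-trial PLV over a window of N samples is
``|mean_n exp(j * dphi_n)|``: 1 for perfect (or constant-lag) locking,
about ``sqrt(pi / (4N))`` for independent phases.  A 1-s window sliding in
0.1-s steps yields a windows x 24 x 24 tensor; single-trial matrices are
averaged across the trials of a condition.  Edges below the PLV threshold
(default 0.65) are discarded to suppress spurious connections, giving a
weighted undirected brain graph per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.signal as sps

from .atlas import ROI_LABELS
from .inverse import SourceEpochs

PLV_WINDOW_S = 1.0
PLV_STEP_S = 0.1
PLV_THRESHOLD = 0.65
EDGE_FRACTION = 0.05


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase (radians) of the analytic signal of a band-limited real signal.

    Raises on an all-zero signal, whose phase is undefined.
    """
    x = np.asarray(x, float)
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.angle(sps.hilbert(x, axis=axis))


def edge_mask(n_samples: int, fraction: float = EDGE_FRACTION) -> np.ndarray:
    """Boolean mask, True where the Hilbert phase is edge-reliable (the first
    and last ``fraction`` of samples are flagged False)."""
    k = int(np.ceil(fraction * n_samples))
    m = np.ones(n_samples, bool)
    if k:
        m[:k] = m[-k:] = False
    return m


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase-locking value of two equal-length phase windows."""
    phase_x = np.asarray(phase_x, float)
    phase_y = np.asarray(phase_y, float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase windows must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


@dataclass
class PLVTensor:
    """Windowed pairwise PLV: ``values`` is windows x n_rois x n_rois."""

    values: np.ndarray
    window_centers: np.ndarray
    window_s: float
    step_s: float
    roi_labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self):
        w, a, b = self.values.shape
        if a != b or a != len(self.roi_labels):
            raise ValueError("PLV tensor must be windows x rois x rois")
        if w != self.window_centers.size:
            raise ValueError("window centers must match window count")

    def at_time(self, t: float) -> np.ndarray:
        """PLV matrix of the window whose centre is nearest to ``t``."""
        return self.values[int(np.argmin(np.abs(self.window_centers - t)))]


def plv_matrix(
    smrcp: SourceEpochs,
    window_s: float = PLV_WINDOW_S,
    step_s: float = PLV_STEP_S,
    interval: tuple[float, float] | None = None,
) -> PLVTensor:
    """Sliding-window PLV between all ROI pairs, averaged across trials.

    Phases are taken on the full epoch; windows tile ``interval`` (default:
    the whole epoch) left to right: ``floor((L - window) / step) + 1``
    windows for an interval of length ``L``.
    """
    t0, t1 = interval if interval is not None else (smrcp.time[0], smrcp.time[-1] + 1 / smrcp.rate)
    n_win_samp = int(round(window_s * smrcp.rate))
    step_samp = int(round(step_s * smrcp.rate))
    first = int(round((t0 - smrcp.time[0]) * smrcp.rate))
    total = int(round((t1 - t0) * smrcp.rate))
    if total < n_win_samp:
        raise ValueError("interval shorter than one PLV window")
    n_windows = (total - n_win_samp) // step_samp + 1

    z = np.exp(1j * instantaneous_phase(smrcp.data, axis=2))
    values = np.empty((n_windows, z.shape[1], z.shape[1]))
    centers = np.empty(n_windows)
    for w in range(n_windows):
        a = first + w * step_samp
        seg = z[:, :, a : a + n_win_samp]
        m = np.abs(seg @ seg.conj().transpose(0, 2, 1)) / n_win_samp
        values[w] = m.mean(axis=0)
        centers[w] = smrcp.time[0] + (a + n_win_samp / 2) / smrcp.rate
    values = 0.5 * (values + values.transpose(0, 2, 1))  # enforce exact symmetry
    idx = np.arange(values.shape[1])
    values[:, idx, idx] = 1.0
    return PLVTensor(
        values=values,
        window_centers=centers,
        window_s=window_s,
        step_s=step_s,
        roi_labels=smrcp.roi_labels,
    )


def threshold_graph(
    matrix: np.ndarray,
    threshold: float = PLV_THRESHOLD,
    roi_labels: tuple[str, ...] = ROI_LABELS,
) -> nx.Graph:
    """Undirected weighted graph keeping edges with PLV >= threshold.

    All nodes are retained (isolated nodes included); self-loops never
    enter.  Raises on an asymmetric matrix.
    """
    m = np.asarray(matrix, float)
    if m.shape != (len(roi_labels), len(roi_labels)):
        raise ValueError("matrix does not match ROI count")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(roi_labels)
    n = len(roi_labels)
    for i in range(n):
        for j in range(i + 1, n):
            if m[i, j] >= threshold:
                g.add_edge(roi_labels[i], roi_labels[j], weight=float(m[i, j]))
    return g
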