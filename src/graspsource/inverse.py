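"""sLORETA source estimation and ROI aggregation.

The inverse operator is the regularised minimum-norm kernel
``K = L^T (L L^T + lambda C)^-1`` standardised by the diagonal of the
resolution matrix ``R = K L``: the estimate for source ``i`` is
``(K x)_i / sqrt(R_ii)``.  The regularisation follows the common power-SNR
rule ``lambda = trace(L L^T) / (n_channels * snr^2)`` with ``snr = 3`` by
default, and ``C`` is the sensor noise covariance estimated from rest data
with a small diagonal loading.  Standardisation gives sLORETA its
zero-localisation-error property for single noiseless sources.

Source estimates are averaged (signed arithmetic mean) within each of the
24 atlas ROIs, yielding source-space MRCPs ("sMRCP").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .atlas import ROI_LABELS
from .preprocess import EpochSet
from .synthdata import Leadfield


@dataclass
class NoiseCovariance:
    """Symmetric positive-definite sensor covariance (uV^2)."""

    matrix: np.ndarray
    loading: float

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T):
            raise ValueError("covariance must be symmetric")


@dataclass
class InverseOperator:
    """Standardised sLORETA kernel: ``sources = kernel @ sensors``."""

    kernel: np.ndarray  # n_sources x n_channels, rows already standardised
    source_rois: tuple[str, ...]
    lam: float

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[1]


@dataclass
class SourceEpochs:
    """Trials x 24 ROIs x samples of source-space MRCP amplitude."""

    data: np.ndarray
    roi_labels: tuple[str, ...]
    labels: np.ndarray
    time: np.ndarray
    rate: float

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[1] != len(self.roi_labels):
            raise ValueError("data must be trials x ROIs x samples")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if self.time.size != self.data.shape[2]:
            raise ValueError("time axis must match sample count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def roi(self, label: str) -> np.ndarray:
        return self.data[:, self.roi_labels.index(label), :]

    def condition(self, task: str) -> "SourceEpochs":
        keep = self.labels == task
        return replace(self, data=self.data[keep], labels=self.labels[keep])


def estimate_noise_cov(rest: np.ndarray, loading: float = 1e-6) -> NoiseCovariance:
    """Sample covariance of preprocessed rest data plus diagonal loading.

    The loading ``eps * trace / n_channels`` guarantees positive
    definiteness even for rank-deficient rest segments.
    """
    x = np.asarray(rest, float)
    if x.ndim != 2:
        raise ValueError("rest data must be channels x samples")
    if x.shape[1] < 2:
        raise ValueError("rest segment too short")
    c = np.cov(x)
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("rest data has zero variance; cannot estimate covariance")
    c = c + loading * tr / c.shape[0] * np.eye(c.shape[0])
    return NoiseCovariance(matrix=c, loading=loading)


def sloreta_operator(
    leadfield: Leadfield, cov: NoiseCovariance, snr: float = 3.0
) -> InverseOperator:
    """Standardised sLORETA inverse operator.

    Scale invariant: scaling the leadfield and the data by the same factor
    leaves the standardised estimates unchanged.
    """
    G = leadfield.gain
    if cov.matrix.shape[0] != G.shape[0]:
        raise ValueError("covariance does not match leadfield channel count")
    gram = G @ G.T
    lam = np.trace(gram) / (G.shape[0] * snr**2)
    m = gram + lam * cov.matrix
    K = np.linalg.solve(m, G).T  # = G^T m^-1
    resolution_diag = np.einsum("ij,ji->i", K, G)
    norm = np.sqrt(np.clip(resolution_diag, 1e-300, None))
    return InverseOperator(
        kernel=K / norm[:, None], source_rois=leadfield.source_rois, lam=lam
    )


def localize(op: InverseOperator, sensor_vec: np.ndarray) -> int:
    """Index of the source with maximal standardised power for one sample."""
    est = op.kernel @ np.asarray(sensor_vec, float)
    return int(np.argmax(est**2))


def apply_inverse(
    epochs: EpochSet, op: InverseOperator, roi_labels: tuple[str, ...] = ROI_LABELS
) -> SourceEpochs:
    """Project epochs to source space and average sources within each ROI.

    The ROI trace is the signed arithmetic mean over its sources, preserving
    MRCP polarity.  Raises if any requested ROI has no sources.
    """
    if epochs.n_channels != op.n_channels:
        raise ValueError("epoch channel count does not match inverse operator")
    rois = np.asarray(op.source_rois)
    groups = []
    for r in roi_labels:
        idx = np.flatnonzero(rois == r)
        if idx.size == 0:
            raise ValueError(f"ROI {r!r} has no sources in the operator")
        groups.append(idx)
    # averaging commutes with the linear kernel: pre-average kernel rows
    roi_kernel = np.stack([op.kernel[idx].mean(axis=0) for idx in groups])
    data = np.einsum("rc,tcs->trs", roi_kernel, epochs.data)
    return SourceEpochs(
        data=data,
        roi_labels=tuple(roi_labels),
        labels=np.asarray(epochs.labels),
        time=epochs.time,
        rate=epochs.rate,
    )
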