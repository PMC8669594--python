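"""HDF5 containers and graph export for the pipeline's data objects.

Recordings, epoch sets, source epochs, leadfields and PLV tensors round-trip
through single HDF5 files; event tables use TSV (see :mod:`.events`); brain
graphs export to GEXF or GraphML with ROI labels, module ids and edge
weights.  Continuous EEG in EDF can be read through ``mne`` when that
package is installed (optional; the synthetic pipeline never requires it).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import PLVTensor
from .inverse import SourceEpochs
from .preprocess import EpochSet
from .synthdata import Leadfield, Recording

def _str_array(values):
    return np.array([str(v).encode("utf-8") for v in values])


def save_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=rec.eeg, compression="gzip")
        f.create_dataset("button", data=rec.button, compression="gzip")
        f.create_dataset("force", data=rec.force, compression="gzip")
        f.attrs["rate"] = rec.rate
        f.attrs["session"] = rec.session
        f.create_dataset("ch_names", data=_str_array(rec.ch_names))
        g = f.create_group("cues")
        for col in ("trial", "task", "cue_t", "go_t"):
            data = rec.cues[col].to_numpy()
            if data.dtype.kind in "OU":
                data = _str_array(data)
            g.create_dataset(col, data=data)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        cues = pd.DataFrame(
            {
                col: (
                    [s.decode() for s in f["cues"][col][()]]
                    if f["cues"][col].dtype.kind in "OS"
                    else f["cues"][col][()]
                )
                for col in ("trial", "task", "cue_t", "go_t")
            }
        )
        return Recording(
            eeg=f["eeg"][()],
            button=f["button"][()],
            force=f["force"][()],
            rate=float(f.attrs["rate"]),
            ch_names=tuple(s.decode() for s in f["ch_names"][()]),
            cues=cues,
            session=int(f.attrs["session"]),
        )


def save_epochs(ep: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip")
        f.create_dataset("labels", data=_str_array(ep.labels))
        f.create_dataset("time", data=ep.time)
        f.create_dataset("mask", data=_str_array(ep.reject_mask))
        f.attrs["rate"] = ep.rate
        f.attrs["troi"] = ep.troi


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=np.array([s.decode() for s in f["labels"][()]]),
            time=f["time"][()],
            rate=float(f.attrs["rate"]),
            reject_mask=np.array([s.decode() for s in f["mask"][()]], dtype=object),
            troi=tuple(f.attrs["troi"]),
        )


def save_sources(se: SourceEpochs, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=se.data, compression="gzip")
        f.create_dataset("roi_labels", data=_str_array(se.roi_labels))
        f.create_dataset("labels", data=_str_array(se.labels))
        f.create_dataset("time", data=se.time)
        f.attrs["rate"] = se.rate


def load_sources(path) -> SourceEpochs:
    with h5py.File(path, "r") as f:
        return SourceEpochs(
            data=f["data"][()],
            roi_labels=tuple(s.decode() for s in f["roi_labels"][()]),
            labels=np.array([s.decode() for s in f["labels"][()]]),
            time=f["time"][()],
            rate=float(f.attrs["rate"]),
        )


def save_leadfield(lf: Leadfield, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("source_rois", data=_str_array(lf.source_rois))
        f.create_dataset("ch_names", data=_str_array(lf.ch_names))


def load_leadfield(path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(
            gain=f["gain"][()],
            source_rois=tuple(s.decode() for s in f["source_rois"][()]),
            ch_names=tuple(s.decode() for s in f["ch_names"][()]),
        )


def save_plv(t: PLVTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=t.values, compression="gzip")
        f.create_dataset("centers", data=t.window_centers)
        f.create_dataset("roi_labels", data=_str_array(t.roi_labels))
        f.attrs["window_s"] = t.window_s
        f.attrs["step_s"] = t.step_s


def load_plv(path) -> PLVTensor:
    with h5py.File(path, "r") as f:
        return PLVTensor(
            values=f["values"][()],
            window_centers=f["centers"][()],
            window_s=float(f.attrs["window_s"]),
            step_s=float(f.attrs["step_s"]),
            roi_labels=tuple(s.decode() for s in f["roi_labels"][()]),
        )


def export_graph(g: nx.Graph, path, modules: dict | None = None) -> None:
    """Write a brain graph as GEXF or GraphML (chosen by file extension)."""
    g = g.copy()
    if modules:
        nx.set_node_attributes(g, modules, "module")
    nx.set_node_attributes(g, {n: str(n) for n in g.nodes}, "roi")
    path = Path(path)
    if path.suffix == ".gexf":
        nx.write_gexf(g, path)
    elif path.suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError("graph export supports .gexf and .graphml")


def read_raw_edf(path):
    """Load a continuous EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' package") from e
    return mne.io.read_raw_edf(path, preload=True, verbose="error")
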