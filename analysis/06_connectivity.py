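"""Phase-locking-value networks per condition.

Sliding 1-s / 0.1-s-step PLV over the tROI for each condition, thresholded
at 0.65; stores the tensors and exports the 1.4-s graphs (grasp peak) as
GEXF with Louvain module labels.
"""

from graspsource import connectivity as conn
from graspsource import io, netmetrics, preprocess

from common import RESULTS, analysis_config


def main():
    smrcp = io.load_sources(RESULTS / "smrcp.h5")
    cfg = analysis_config()
    for task in cfg.tasks:
        tensor = conn.plv_matrix(smrcp.condition(task), interval=preprocess.TROI)
        io.save_plv(tensor, RESULTS / f"plv_{task}.h5")
        g = conn.threshold_graph(tensor.at_time(1.4), roi_labels=tensor.roi_labels)
        _, modules = netmetrics.modularity_partition(g, seed=cfg.seed)
        io.export_graph(g, RESULTS / f"network_{task}_1.4s.gexf", modules=modules)
        print(
            f"{task:12s} 1.4 s: {g.number_of_edges():3d} edges >= 0.65, "
            f"{len(set(modules.values()))} modules"
        )


if __name__ == "__main__":
    main()
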